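"""Runtime configuration.

All numeric conventions that downstream results depend on (distance cutoffs,
pairing score constants, classification length windows) live here so that a
single YAML file can reproduce or alter a database build.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


def _packaged(name: str) -> str:
    return str(resources.files("abparse").joinpath("data").joinpath(name))


@dataclass
class AlignmentConfig:
    """Scoring for the PDB-seq -> FASTA-seq alignment used to build Filled-seqs.

    End gaps are always free: the observed sequence is expected to be an
    (internally gapped) subsequence of the deposited entity sequence, so the
    gap penalties are deliberately mild relative to the mismatch penalty.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -2.0
    gap_extend: float = -0.1
    min_identity: float = 0.8  # below this the Filled-seq falls back to the PDB-seq


@dataclass
class DetectorConfig:
    backend: str = "motif"          # name of the registered sequence detector
    min_domain_length: int = 70     # shorter sequences are non-Ab outright


@dataclass
class StructuralFilterConfig:
    """Domain-similarity filter that demotes misfolded antibody-sequence chains."""

    enabled: bool = True
    threshold: float = 0.4
    vh_reference: str = field(default_factory=lambda: _packaged("vh_reference_synthetic.cif"))
    vl_reference: str = field(default_factory=lambda: _packaged("vl_reference_synthetic.cif"))


@dataclass
class PairingConfig:
    """Candidate filtering and scoring for heavy-light pairing.

    ``cutoff_*`` are minimum interface-residue counts (summed over both
    chains) for a pair to be considered at all. Single-domain pairings need
    only a modest contact patch; two tethered VH-VL chains must bury a much
    larger interface to count as a genuine pairing.
    """

    interface_cutoff_A: float = 5.0
    cutoff_hc_lc: int = 20
    cutoff_hc_hlc: int = 20
    cutoff_lc_hlc: int = 20
    cutoff_hlc_hlc: int = 80
    dummy_penalty: int = -100
    reward_scale: int = 3


@dataclass
class ClassifyConfig:
    # closed [lo, hi] windows on Filled-seq length
    single_domain_window: tuple[int, int] = (95, 150)   # VH / VHH / VL
    fab_window: tuple[int, int] = (190, 260)            # FabH / FabL
    scfv_window: tuple[int, int] = (190, 290)           # scFv / VHVL
    scfv_radius_A: float = 20.0
    scfv_keywords: tuple[str, ...] = ("scfv", "single", "fv")
    vhh_keywords: tuple[str, ...] = ("nanobody", "vhh", "single-domain")
    camelid_species: tuple[str, ...] = (
        "lama glama",
        "vicugna pacos",
        "camelus dromedarius",
        "camelus bactrianus",
        "ginglymostoma cirratum",
    )
    # matched against the 12 residues following the framework-2 tryptophan;
    # hydrophilic hallmark of VL-interface-free single domains
    vhh_fr2_regex: str = r".{7}ER"


@dataclass
class AAIConfig:
    min_interface: int = 10
    min_cdr_interface: int = 5
    min_cdr_ratio: float = 0.25


@dataclass
class SummaryConfig:
    all_models: bool = False  # default: first model only, model count recorded


@dataclass
class Config:
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    structural_filter: StructuralFilterConfig = field(default_factory=StructuralFilterConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    aai: AAIConfig = field(default_factory=AAIConfig)
    summary: SummaryConfig = field(default_factory=SummaryConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            for key, value in (values or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                current = getattr(sub, key)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(sub, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        Path(path).write_text(yaml.safe_dump(plain(self), sort_keys=False))


DEFAULT_CONFIG = Config()
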