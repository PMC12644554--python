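"""Antibody-antigen interaction (AAI) identification.

A candidate antigen chain (any non-antibody protein, peptide, DNA or RNA
chain of the same model) is accepted as a true antigen of an antibody —
a heavy-light pair or a single antibody chain — when all three criteria
hold (all inclusive):

1. total interface residues across both sides >= 10;
2. CDR residues at the interface >= 5;
3. CDR residues as a fraction of antibody-side interface residues >= 0.25.

The CDR requirement separates functional epitope engagement from
crystal-packing or constant-domain contacts. All accepted antigen chains of
one antibody are grouped into a single interaction record whose aggregate
statistics are computed against the union of the antigen chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ab_detect import AbAnnotation
from .config import AAIConfig
from .interface_geometry import InterfaceResult, interface_residues
from .structure_io import ChainStructure


@dataclass
class ScreenResult:
    accepted: bool
    n_interface: int
    n_cdr_interface: int
    cdr_ratio: float
    reason: str = ""
    interfaces: list[InterfaceResult] = field(default_factory=list)


@dataclass
class AAIRecord:
    heavy_key: str | None
    light_key: str | None
    antigen_chains: list[ChainStructure]
    n_interface: int
    n_cdr_interface: int
    cdr_ratio: float
    # per (antibody chain, antigen chain) interface, in antigen-major order
    per_antigen: list[InterfaceResult] = field(default_factory=list)


def cdr_seq_indices(chain: ChainStructure, annotation: AbAnnotation) -> set[int]:
    """Structure residue indices (seq_index) falling inside CDR spans.

    Detector CDR spans live on the Filled-seq; they are shifted to FASTA
    coordinates with the chain's filled_start and intersected with the
    PDB->FASTA residue map.
    """
    if not annotation.cdr_spans:
        return set()
    spans_fasta = [
        (lo + chain.filled_start - 1, hi + chain.filled_start - 1)
        for _, (lo, hi) in annotation.cdr_spans
    ]
    out: set[int] = set()
    if chain.map_pdb_to_fasta is None:
        # no entity sequence: Filled-seq == PDB-seq, spans apply directly
        for lo, hi in ((lo, hi) for _, (lo, hi) in annotation.cdr_spans):
            out.update(range(lo, hi + 1))
        return {i for i in out if 1 <= i <= chain.n_residues}
    for seq_index, fasta_pos in enumerate(chain.map_pdb_to_fasta, start=1):
        if fasta_pos is None:
            continue
        if any(lo <= fasta_pos <= hi for lo, hi in spans_fasta):
            out.add(seq_index)
    return out


def screen_antigen(
    ab_chains: list[tuple[ChainStructure, AbAnnotation]],
    candidate: ChainStructure,
    config: AAIConfig | None = None,
    cutoff_A: float = 5.0,
) -> ScreenResult:
    """Apply the three acceptance criteria to one candidate antigen chain.

    ``ab_chains`` is the antibody side: both chains of a pair or a single
    chain, each with its annotation. Statistics are returned whether or not
    the candidate is accepted.
    """
    cfg = config or AAIConfig()
    if not any(r.heavy_atoms for r in candidate.residues):
        return ScreenResult(False, 0, 0, 0.0, reason="candidate has no heavy atoms")

    ab_side: set[tuple[str, int]] = set()
    ag_side: set[int] = set()
    cdr_side: set[tuple[str, int]] = set()
    interfaces: list[InterfaceResult] = []
    for chain, ann in ab_chains:
        iface = interface_residues(chain, candidate, cutoff_A=cutoff_A)
        interfaces.append(iface)
        cdrs = cdr_seq_indices(chain, ann)
        for idx in iface.residues_a:
            ab_side.add((chain.chain_id, idx))
            if idx in cdrs:
                cdr_side.add((chain.chain_id, idx))
        ag_side.update(iface.residues_b)

    n_interface = len(ab_side) + len(ag_side)
    n_cdr = len(cdr_side)
    ratio = n_cdr / len(ab_side) if ab_side else 0.0
    accepted = (
        n_interface >= cfg.min_interface
        and n_cdr >= cfg.min_cdr_interface
        and ratio >= cfg.min_cdr_ratio
    )
    reason = "" if accepted else "below acceptance thresholds"
    return ScreenResult(accepted, n_interface, n_cdr, ratio, reason, interfaces)


def group_antigens(
    heavy_key: str | None,
    light_key: str | None,
    ab_chains: list[tuple[ChainStructure, AbAnnotation]],
    accepted: list[ChainStructure],
    config: AAIConfig | None = None,
    cutoff_A: float = 5.0,
) -> AAIRecord | None:
    """Merge all accepted antigen chains of one antibody into one record.

    Aggregate statistics are recomputed against the union of antigen chains;
    an antibody with no accepted antigen yields ``None`` (an antibody-only
    entry). Results do not depend on the order in which candidates were
    screened.
    """
    if not accepted:
        return None
    accepted = sorted(accepted, key=lambda c: c.chain_id)
    ab_side: set[tuple[str, int]] = set()
    ag_side: set[tuple[str, int]] = set()
    cdr_side: set[tuple[str, int]] = set()
    per_antigen: list[InterfaceResult] = []
    for ag in accepted:
        for chain, ann in ab_chains:
            cdrs = cdr_seq_indices(chain, ann)
            iface = interface_residues(chain, ag, cutoff_A=cutoff_A)
            per_antigen.append(iface)
            for idx in iface.residues_a:
                ab_side.add((chain.chain_id, idx))
                if idx in cdrs:
                    cdr_side.add((chain.chain_id, idx))
            ag_side.update((ag.chain_id, idx) for idx in iface.residues_b)
    n_interface = len(ab_side) + len(ag_side)
    ratio = len(cdr_side) / len(ab_side) if ab_side else 0.0
    return AAIRecord(
        heavy_key=heavy_key,
        light_key=light_key,
        antigen_chains=accepted,
        n_interface=n_interface,
        n_cdr_interface=len(cdr_side),
        cdr_ratio=ratio,
        per_antigen=per_antigen,
    )
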