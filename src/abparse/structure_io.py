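"""Parsing of per-entry mmCIF + FASTA inputs into the entity/chain/residue model.

Three sequence views of one chain are distinguished throughout the package:

* FASTA-seq — the full deposited entity sequence (every chain of an entity
  shares it);
* PDB-seq — the one-letter sequence of residues that actually have a
  representative atom (Cα for amino acids, C1' for nucleotides) in the
  coordinate file;
* Filled-seq — the fragment of the FASTA-seq spanning the first to the last
  observed residue, i.e. the PDB-seq with internal missing residues restored.

The Filled-seq is obtained by aligning the PDB-seq to the FASTA-seq with free
end gaps and mild gap penalties (see :class:`abparse.config.AlignmentConfig`).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
from Bio import Align

from .config import AlignmentConfig, Config, DEFAULT_CONFIG

logger = logging.getLogger(__name__)

PROTEIN_REPRESENTATIVE = "CA"
NUCLEIC_REPRESENTATIVE = "C1'"


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class Residue:
    """One residue with resolved coordinates.

    ``seq_index`` is the 1-based ordinal among residues of the chain that
    carry a representative atom; it is the chain-internal coordinate used for
    interface statistics. Alternate locations are resolved at parse time
    (highest occupancy, ties by altloc code), and hydrogens are never stored.
    """

    name: str
    seq_index: int
    auth_number: int
    insertion_code: str
    heavy_atoms: list[tuple[str, float, float, float]]


@dataclass
class EntityRecord:
    """One polymer entity as described by the per-entry FASTA file."""

    entity_id: str
    sequence: str
    chain_ids: list[str]
    molecule_name: str = ""
    species: str = ""
    polymer_kind: str = "protein"  # protein | dna | rna | other

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"entity {self.entity_id}: empty sequence")
        if not self.chain_ids:
            raise ValueError(f"entity {self.entity_id}: no chain ids")
        if len(set(self.chain_ids)) != len(self.chain_ids):
            raise ValueError(f"entity {self.entity_id}: duplicate chain ids")


@dataclass
class ChainStructure:
    """One chain of one model, with its three sequence views."""

    chain_id: str
    model_id: int
    entity_id: str
    residues: list[Residue]
    pdb_seq: str = ""
    filled_seq: str = ""
    # 1-based FASTA position per PDB-seq residue (None entries for residues
    # absent from the entity sequence); None when no entity sequence could be
    # associated with the chain
    map_pdb_to_fasta: list[int | None] | None = None
    filled_start: int = 0  # 1-based FASTA position of filled_seq[0]
    entity_metadata_available: bool = True
    polymer_kind: str = "protein"

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def heavy_atom_coords(self):
        import numpy as np

        return np.array(
            [(x, y, z) for r in self.residues for (_, x, y, z) in r.heavy_atoms],
            dtype=float,
        )

    def representative_coords(self):
        """Coordinates of the representative atom (Cα / C1') per residue."""
        import numpy as np

        rep = NUCLEIC_REPRESENTATIVE if self.polymer_kind in ("dna", "rna") else PROTEIN_REPRESENTATIVE
        out = []
        for r in self.residues:
            for name, x, y, z in r.heavy_atoms:
                if name == rep:
                    out.append((x, y, z))
                    break
        return np.array(out, dtype=float)


@dataclass
class EntryMetadata:
    pdb_id: str = ""
    title: str = "N.A."
    method: str = "N.A."
    resolution: str = "N.A."
    r_free: str = "N.A."
    r_work: str = "N.A."
    deposition_date: str = "N.A."
    n_models: int = 1


# --- one-letter codes -------------------------------------------------------

def one_letter(residue_name: str) -> str:
    """Map a residue name to a one-letter code.

    Nonstandard residues map to their standard parent where one is tabulated
    (MSE -> M); anything unknown becomes ``X``.
    """
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


# --- FASTA (RCSB per-entry dialect) ----------------------------------------

_CHAIN_TOKEN = re.compile(r"([^,\s\[\]]+)(?:\s*\[auth\s+([^\]]+)\])?")


def _parse_chain_field(text: str) -> list[str]:
    """Parse ``Chains A[auth H], B[auth L]`` giving author IDs precedence."""
    text = re.sub(r"^Chains?\s+", "", text.strip())
    ids = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = _CHAIN_TOKEN.match(part)
        if m:
            ids.append(m.group(2) or m.group(1))
    return ids


def _guess_polymer_kind(sequence: str) -> str:
    letters = set(sequence.upper())
    if letters <= set("ACGTUN"):
        return "rna" if "U" in letters else "dna"
    return "protein"


def read_entry_fasta(path: str | Path) -> tuple[str, list[EntityRecord]]:
    """Read an RCSB per-entry FASTA file into :class:`EntityRecord` objects.

    Header dialect: ``>PDBID_ENTITY|Chains A, B|molecule name|species``.
    Returns the (lowercased) entry id and one record per entity.
    """
    records: list[EntityRecord] = []
    pdb_id = ""
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        nonlocal pdb_id
        if header is None:
            return
        fields = header.split("|")
        ident = fields[0].strip()
        entity_id = ident.split("_", 1)[1] if "_" in ident else ident
        pdb_id = pdb_id or ident.split("_", 1)[0].lower()
        chain_ids = _parse_chain_field(fields[1]) if len(fields) > 1 else []
        molecule = fields[2].strip() if len(fields) > 2 else ""
        species = fields[3].strip() if len(fields) > 3 else ""
        sequence = "".join(seq_parts).strip().upper()
        if not sequence or not chain_ids:
            raise ParseError(f"{path}: malformed FASTA record {ident!r}")
        records.append(
            EntityRecord(
                entity_id=entity_id,
                sequence=sequence,
                chain_ids=chain_ids,
                molecule_name=molecule,
                species=species,
                polymer_kind=_guess_polymer_kind(sequence),
            )
        )

    text = Path(path).read_text()
    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:]
            seq_parts = []
        elif line.strip():
            seq_parts.append(line.strip())
    flush()
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return pdb_id, records


# --- mmCIF ------------------------------------------------------------------

def _pick_altlocs(residue: gemmi.Residue) -> list[tuple[str, float, float, float]]:
    """Resolve alternate locations: keep the highest-occupancy conformer per
    atom name, ties broken by the alphabetically first altloc code. Hydrogens
    and deuteriums are dropped."""
    best: dict[str, tuple[float, str, tuple[str, float, float, float]]] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        key = atom.name
        entry = (-(atom.occ or 0.0), atom.altloc or "", (atom.name, atom.pos.x, atom.pos.y, atom.pos.z))
        if key not in best or entry[:2] < best[key][:2]:
            best[key] = entry
    return [v[2] for v in sorted(best.values(), key=lambda v: v[2][0])]


def _kind_from_polymer_type(pt: gemmi.PolymerType) -> str:
    PT = gemmi.PolymerType
    if pt in (PT.PeptideL, PT.PeptideD):
        return "protein"
    if pt == PT.Dna:
        return "dna"
    if pt == PT.Rna:
        return "rna"
    return "other"


def _read_metadata(doc_block: gemmi.cif.Block, pdb_id: str, n_models: int) -> EntryMetadata:
    def item(tag: str) -> str:
        val = doc_block.find_value(tag)
        if val is None:
            return "N.A."
        val = gemmi.cif.as_string(val).strip()
        return val if val and val not in (".", "?") else "N.A."

    resolution = item("_refine.ls_d_res_high")
    if resolution == "N.A.":
        resolution = item("_em_3d_reconstruction.resolution")
    return EntryMetadata(
        pdb_id=pdb_id,
        title=item("_struct.title"),
        method=item("_exptl.method"),
        resolution=resolution,
        r_free=item("_refine.ls_R_factor_R_free"),
        r_work=item("_refine.ls_R_factor_R_work"),
        deposition_date=item("_pdbx_database_status.recvd_initial_deposition_date"),
        n_models=n_models,
    )


def parse_entry(
    mmcif_path: str | Path,
    fasta_path: str | Path,
    config: Config = DEFAULT_CONFIG,
) -> tuple[list[EntityRecord], dict[int, list[ChainStructure]], EntryMetadata]:
    """Parse one entry into entities and per-model chain structures.

    Waters, ions, cofactors and other non-polymer molecules are dropped.
    Multi-model files (NMR ensembles) yield one chain set per model; chains
    from different models are never merged.

    Raises :class:`ParseError` when either file is unreadable; a chain that
    appears in the mmCIF but not in the FASTA chain lists is processed with
    ``entity_metadata_available=False`` after a warning.
    """
    fasta_id, entities = read_entry_fasta(fasta_path)
    try:
        st = gemmi.read_structure(str(mmcif_path))
        doc = gemmi.cif.read(str(mmcif_path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"cannot parse mmCIF file {mmcif_path}: {exc}") from exc

    pdb_id = (st.name or Path(str(mmcif_path)).stem).lower()
    if fasta_id and pdb_id and fasta_id.lower() != pdb_id.lower():
        warnings.warn(
            f"entry id mismatch between mmCIF ({pdb_id}) and FASTA ({fasta_id})",
            stacklevel=2,
        )

    st.setup_entities()

    chain_to_entity: dict[str, EntityRecord] = {}
    for ent in entities:
        for cid in ent.chain_ids:
            chain_to_entity[cid] = ent

    # polymer kind per label entity from the mmCIF, for chains missing FASTA info
    cif_kind: dict[str, str] = {}
    for ent in st.entities:
        cif_kind[ent.name] = _kind_from_polymer_type(ent.polymer_type)

    models: dict[int, list[ChainStructure]] = {}
    for model_no, model in enumerate(st, start=1):
        chains: list[ChainStructure] = []
        for chain in model:
            residues: list[Residue] = []
            sub_entity = ""
            for res in chain:
                if res.entity_type != gemmi.EntityType.Polymer:
                    continue
                if res.is_water():
                    continue
                atoms = _pick_altlocs(res)
                if not atoms:
                    continue
                sub_entity = sub_entity or res.subchain
                residues.append(
                    Residue(
                        name=res.name,
                        seq_index=0,  # assigned below
                        auth_number=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        heavy_atoms=atoms,
                    )
                )
            if not residues:
                continue
            entity = chain_to_entity.get(chain.name)
            kind = entity.polymer_kind if entity else "protein"
            rep = NUCLEIC_REPRESENTATIVE if kind in ("dna", "rna") else PROTEIN_REPRESENTATIVE
            kept = [r for r in residues if any(a[0] == rep for a in r.heavy_atoms)]
            if not kept:
                logger.warning(
                    "chain %s model %d: no residues with a representative atom; excluded",
                    chain.name,
                    model_no,
                )
                continue
            for i, r in enumerate(kept, start=1):
                r.seq_index = i
            cs = ChainStructure(
                chain_id=chain.name,
                model_id=model_no,
                entity_id=entity.entity_id if entity else "",
                residues=kept,
                polymer_kind=kind,
            )
            cs.pdb_seq = extract_pdb_seq(cs)
            if entity is None:
                warnings.warn(
                    f"chain {chain.name} has no matching FASTA entity; "
                    "entity metadata marked unavailable",
                    stacklevel=2,
                )
                cs.entity_metadata_available = False
                cs.filled_seq = cs.pdb_seq
                cs.filled_start = 1
            else:
                filled, index_map, start = build_filled_seq(
                    cs.pdb_seq, entity.sequence, config.alignment
                )
                cs.filled_seq = filled
                cs.map_pdb_to_fasta = index_map
                cs.filled_start = start
            chains.append(cs)
        if chains:
            models[model_no] = chains

    if not models:
        raise ParseError(f"{mmcif_path}: no polymer chains with coordinates")
    metadata = _read_metadata(block, pdb_id, n_models=len(models))
    return entities, models, metadata


def extract_pdb_seq(chain: ChainStructure) -> str:
    """One-letter sequence over the chain's residues with coordinates."""
    return "".join(one_letter(r.name) for r in chain.residues)


# --- Filled-seq construction ------------------------------------------------

def _make_aligner(cfg: AlignmentConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_internal_gap_score = cfg.gap_open
    aligner.extend_internal_gap_score = cfg.gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def build_filled_seq(
    pdb_seq: str,
    fasta_seq: str,
    cfg: AlignmentConfig | None = None,
) -> tuple[str, list[int | None] | None, int]:
    """Align the PDB-seq to the FASTA-seq and restore internal gaps.

    Returns ``(filled_seq, index_map, filled_start)`` where ``index_map``
    gives the 1-based FASTA position of every PDB-seq residue and
    ``filled_start`` the 1-based FASTA position of the first Filled-seq
    residue. When the alignment identity over aligned columns drops below
    the configured minimum, a warning is issued and the Filled-seq falls
    back to the PDB-seq (``index_map`` is then ``None``).
    """
    if not pdb_seq or not fasta_seq:
        raise ValueError("both sequences must be non-empty")
    cfg = cfg or AlignmentConfig()
    aligner = _make_aligner(cfg)
    alignment = aligner.align(fasta_seq, pdb_seq)[0]

    index_map: list[int | None] = [None] * len(pdb_seq)
    matches = 0
    aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            index_map[q0 + k] = t0 + k + 1
            aligned_cols += 1
            if fasta_seq[t0 + k] == pdb_seq[q0 + k]:
                matches += 1

    if aligned_cols == 0 or matches / aligned_cols < cfg.min_identity:
        warnings.warn(
            f"PDB-seq/FASTA-seq alignment identity "
            f"{matches / aligned_cols if aligned_cols else 0.0:.2f} below "
            f"{cfg.min_identity}; Filled-seq falls back to PDB-seq",
            stacklevel=2,
        )
        return pdb_seq, None, 1

    aligned_positions = [p for p in index_map if p is not None]
    first, last = aligned_positions[0], aligned_positions[-1]
    filled = fasta_seq[first - 1 : last]
    # PDB residues not aligned to an entity-sequence letter (insertions, e.g.
    # expression tags) keep a None entry so positions stay residue-parallel.
    return filled, index_map, first
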