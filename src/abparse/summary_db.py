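"""Per-entry summary rows, the database summary file, and incremental updates.

The summary is a UTF-8, LF-terminated TSV with a versioned header. One row
describes one antibody entry (a heavy-light pair or a single antibody chain)
of one model. Missing text fields carry the sentinel ``N.A.``; missing
numeric fields carry ``0``: an unpaired heavy chain has ``N.A.``/0 in every
light-chain field, and an antibody without antigen has ``N.A.``/0 in the
antigen block.

Incremental updates are driven by content checksums kept in a JSON manifest
next to the summary: rows of unchanged entries are carried over
byte-identically, removed entries disappear, modified and new entries are
recomputed. A failure while recomputing one entry keeps its old rows and is
reported, without aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .ab_detect import assign_subgroup
from .affinity import AffinityRecord
from .config import Config, DEFAULT_CONFIG
from .interface_geometry import mean_radius
from .pipeline import EntryResult, process_entry
from .structure_io import ChainStructure, EntityRecord

logger = logging.getLogger(__name__)

FORMAT_VERSION = "abparse_summary_v1"

# the column registry: 43 attributes covering the antibody block, the antigen
# block and the entry-level metadata. Changing this list requires a version
# bump. For a single-chain two-domain antibody (scFv/VHVL) the chain lives in
# the heavy block and its light-domain CDRs in the L-CDR columns.
COLUMNS = (
    "pdb_id",            # 1
    "model_id",          # 2
    "ab_type",           # 3  rendered label, e.g. FabH:FabL
    "h_chain_id",        # 4
    "h_species",         # 5
    "h_molecule",        # 6
    "h_fasta_len",       # 7
    "h_pdb_len",         # 8
    "h_filled_len",      # 9
    "h_subgroup",        # 10 V-gene subgroup (external adapter; N.A. built-in)
    "cdr_h1_seq",        # 11
    "cdr_h2_seq",        # 12
    "cdr_h3_seq",        # 13
    "h_radius",          # 14 mean radius, Å
    "l_chain_id",        # 15
    "l_species",         # 16
    "l_molecule",        # 17
    "l_fasta_len",       # 18
    "l_pdb_len",         # 19
    "l_filled_len",      # 20
    "l_subgroup",        # 21
    "cdr_l1_seq",        # 22
    "cdr_l2_seq",        # 23
    "cdr_l3_seq",        # 24
    "l_radius",          # 25
    "n_hl_interface",    # 26
    "ag_chain_ids",      # 27 semicolon-joined
    "ag_kinds",          # 28
    "ag_species",        # 29
    "ag_molecules",      # 30
    "n_ab_ag_interface", # 31
    "n_cdr_interface",   # 32
    "cdr_ratio",         # 33
    "kd_nM",             # 34
    "pkd",               # 35
    "affinity_method",   # 36
    "temperature_K",     # 37
    "exp_method",        # 38
    "resolution",        # 39
    "r_free",            # 40
    "r_work",            # 41
    "deposition_date",   # 42
    "title",             # 43
)

NA = "N.A."


@dataclass
class SummaryEntry:
    values: dict[str, str]

    def line(self) -> str:
        return "\t".join(self.values[c] for c in COLUMNS)

    @classmethod
    def from_line(cls, line: str) -> "SummaryEntry":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(COLUMNS):
            raise ValueError(f"summary row has {len(parts)} fields, expected {len(COLUMNS)}")
        return cls(dict(zip(COLUMNS, parts)))


def _cdr_seq(chain: ChainStructure | None, ann, label: str) -> str:
    if chain is None or ann is None:
        return NA
    for lab, (lo, hi) in ann.cdr_spans:
        if lab == label:
            return chain.filled_seq[lo - 1 : hi]
    return NA


def _chain_block(
    chain: ChainStructure | None,
    ann,
    entities: list[EntityRecord],
    side: str,
) -> dict[str, str]:
    p = side  # 'h' or 'l'
    if chain is None:
        return {
            f"{p}_chain_id": NA, f"{p}_species": NA, f"{p}_molecule": NA,
            f"{p}_fasta_len": "0", f"{p}_pdb_len": "0", f"{p}_filled_len": "0",
            f"{p}_subgroup": NA,
            f"cdr_{p}1_seq": NA, f"cdr_{p}2_seq": NA, f"cdr_{p}3_seq": NA,
            f"{p}_radius": "0",
        }
    entity = next((e for e in entities if e.entity_id == chain.entity_id), None)
    return {
        f"{p}_chain_id": chain.chain_id,
        f"{p}_species": entity.species if entity and entity.species else NA,
        f"{p}_molecule": entity.molecule_name if entity and entity.molecule_name else NA,
        f"{p}_fasta_len": str(len(entity.sequence)) if entity else "0",
        f"{p}_pdb_len": str(len(chain.pdb_seq)),
        f"{p}_filled_len": str(len(chain.filled_seq)),
        f"{p}_subgroup": assign_subgroup(
            chain.filled_seq, ann.chain_type if ann is not None else ""
        ),
        f"cdr_{p}1_seq": _cdr_seq(chain, ann, f"{p.upper()}1"),
        f"cdr_{p}2_seq": _cdr_seq(chain, ann, f"{p.upper()}2"),
        f"cdr_{p}3_seq": _cdr_seq(chain, ann, f"{p.upper()}3"),
        f"{p}_radius": f"{mean_radius(chain):.2f}",
    }


def build_entry(
    result: EntryResult,
    affinity: dict[tuple[str, str, str], AffinityRecord] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> list[SummaryEntry]:
    """Summary rows for one processed entry, in deterministic order
    (model, heavy chain id, light chain id)."""
    rows: list[SummaryEntry] = []
    meta = result.metadata
    for model in result.models:
        for entry in model.entries:
            values: dict[str, str] = {
                "pdb_id": result.pdb_id,
                "model_id": str(model.model_id),
                "ab_type": entry.type_call.label,
                "n_hl_interface": str(entry.n_hl_interface),
                "exp_method": meta.method,
                "resolution": meta.resolution,
                "r_free": meta.r_free,
                "r_work": meta.r_work,
                "deposition_date": meta.deposition_date,
                "title": meta.title,
            }
            values.update(_chain_block(entry.heavy, entry.heavy_annotation, result.entities, "h"))
            light_ann = entry.light_annotation
            values.update(_chain_block(entry.light, light_ann, result.entities, "l"))
            if entry.light is None and entry.heavy_annotation is not None:
                # single-chain VH-VL constructs keep their light-domain CDRs
                for lab in ("L1", "L2", "L3"):
                    seq = _cdr_seq(entry.heavy, entry.heavy_annotation, lab)
                    values[f"cdr_l{lab[1]}_seq"] = seq

            aai = entry.aai
            if aai is None:
                values.update({
                    "ag_chain_ids": NA, "ag_kinds": NA, "ag_species": NA,
                    "ag_molecules": NA, "n_ab_ag_interface": "0",
                    "n_cdr_interface": "0", "cdr_ratio": "0",
                })
            else:
                ents = {e.entity_id: e for e in result.entities}
                ag_entities = [ents.get(c.entity_id) for c in aai.antigen_chains]
                values.update({
                    "ag_chain_ids": ";".join(c.chain_id for c in aai.antigen_chains),
                    "ag_kinds": ";".join(c.polymer_kind for c in aai.antigen_chains),
                    "ag_species": ";".join(
                        (e.species if e and e.species else NA) for e in ag_entities
                    ),
                    "ag_molecules": ";".join(
                        (e.molecule_name if e and e.molecule_name else NA) for e in ag_entities
                    ),
                    "n_ab_ag_interface": str(aai.n_interface),
                    "n_cdr_interface": str(aai.n_cdr_interface),
                    "cdr_ratio": f"{aai.cdr_ratio:.3f}",
                })

            key = (result.pdb_id.lower(), values["h_chain_id"], values["l_chain_id"])
            rec = (affinity or {}).get(key)
            if rec is None:
                values.update({"kd_nM": "0", "pkd": "0", "affinity_method": NA,
                               "temperature_K": NA})
            else:
                values.update({
                    "kd_nM": f"{rec.kd_nM:.6g}",
                    "pkd": f"{rec.pkd:.3f}",
                    "affinity_method": rec.method + ("*" if rec.mixed_methods else ""),
                    "temperature_K": rec.temperature_K,
                })
            rows.append(SummaryEntry(values))
    rows.sort(key=lambda r: (
        int(r.values["model_id"]), r.values["h_chain_id"], r.values["l_chain_id"]
    ))
    return rows


def write_antibody_structures(result: EntryResult, out_dir: str | Path) -> list[Path]:
    """Write one mmCIF per antibody entry (its chains plus accepted antigen
    chains) under ``out_dir``; returns the written paths."""
    import gemmi

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for model in result.models:
        for entry in model.entries:
            chains = [c for c in (entry.heavy, entry.light) if c is not None]
            if entry.aai:
                chains.extend(entry.aai.antigen_chains)
            st = gemmi.Structure()
            st.name = result.pdb_id.upper()
            gm = gemmi.Model(model.model_id)
            for chain in chains:
                gc = gemmi.Chain(chain.chain_id)
                for res in chain.residues:
                    gr = gemmi.Residue()
                    gr.name = res.name
                    gr.seqid = gemmi.SeqId(res.auth_number, res.insertion_code or " ")
                    for name, x, y, z in res.heavy_atoms:
                        atom = gemmi.Atom()
                        atom.name = name
                        atom.pos = gemmi.Position(x, y, z)
                        atom.element = gemmi.Element(name[0])
                        atom.occ = 1.0
                        gr.add_atom(atom)
                    gc.add_residue(gr)
                gm.add_chain(gc)
            st.add_model(gm)
            st.setup_entities()
            h, l = entry.key
            path = out / f"{result.pdb_id}_m{model.model_id}_{h}_{l}.cif"
            path.write_text(st.make_mmcif_document().as_string())
            written.append(path)
    return written


# --- summary file I/O ---------------------------------------------------------

def write_summary(path: str | Path, rows: list[SummaryEntry]) -> None:
    lines = [f"#{FORMAT_VERSION}", "\t".join(COLUMNS)]
    lines.extend(r.line() for r in rows)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_summary(path: str | Path) -> list[SummaryEntry]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != f"#{FORMAT_VERSION}":
        raise ValueError(f"{path}: not a {FORMAT_VERSION} summary file")
    if lines[1].split("\t") != list(COLUMNS):
        raise ValueError(f"{path}: column header does not match registry")
    return [SummaryEntry.from_line(line) for line in lines[2:] if line]


# --- database build / update --------------------------------------------------

def discover_entries(input_dir: str | Path) -> dict[str, tuple[Path, Path]]:
    """Map pdb_id -> (mmCIF path, FASTA path) for complete input pairs."""
    root = Path(input_dir)
    out: dict[str, tuple[Path, Path]] = {}
    for cif in sorted(root.glob("*.cif")):
        fasta = cif.with_suffix(".fasta")
        if fasta.exists():
            out[cif.stem.lower()] = (cif, fasta)
        else:
            logger.warning("no FASTA next to %s; entry skipped", cif)
    return out


def entry_checksum(cif_path: Path, fasta_path: Path) -> str:
    h = hashlib.sha256()
    h.update(cif_path.read_bytes())
    h.update(b"\0")
    h.update(fasta_path.read_bytes())
    return h.hexdigest()


@dataclass
class BuildReport:
    processed: list[str] = field(default_factory=list)
    skipped_unchanged: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)


def _compute_rows(
    pdb_id: str,
    paths: tuple[Path, Path],
    config: Config,
    affinity: dict | None,
) -> list[SummaryEntry]:
    result = process_entry(paths[0], paths[1], config)
    return build_entry(result, affinity, config)


def build_database(
    input_dir: str | Path,
    summary_path: str | Path,
    config: Config = DEFAULT_CONFIG,
    affinity: dict | None = None,
) -> BuildReport:
    """Full rebuild: process every entry in input_dir and write summary +
    checksum manifest."""
    report = BuildReport()
    rows: list[SummaryEntry] = []
    manifest: dict[str, str] = {}
    for pdb_id, paths in discover_entries(input_dir).items():
        try:
            rows.extend(_compute_rows(pdb_id, paths, config, affinity))
        except Exception as exc:
            logger.error("entry %s failed: %s", pdb_id, exc)
            report.errors[pdb_id] = str(exc)
            continue
        manifest[pdb_id] = entry_checksum(*paths)
        report.processed.append(pdb_id)
    write_summary(summary_path, rows)
    _write_manifest(summary_path, manifest)
    return report


def _manifest_path(summary_path: str | Path) -> Path:
    return Path(str(summary_path) + ".manifest.json")


def _write_manifest(summary_path: str | Path, manifest: dict[str, str]) -> None:
    _manifest_path(summary_path).write_text(json.dumps(manifest, indent=0, sort_keys=True))


def _read_manifest(summary_path: str | Path) -> dict[str, str]:
    p = _manifest_path(summary_path)
    return json.loads(p.read_text()) if p.exists() else {}


def update_database(
    summary_path: str | Path,
    input_dir: str | Path,
    config: Config = DEFAULT_CONFIG,
    affinity: dict | None = None,
) -> BuildReport:
    """Incremental update against the entry checksums in the manifest.

    Unchanged entries keep their existing rows byte-identically; removed
    entries lose theirs; modified/new entries are recomputed. An entry whose
    recomputation fails keeps its old rows and is listed in the report.
    """
    report = BuildReport()
    old_rows = read_summary(summary_path)
    old_manifest = _read_manifest(summary_path)
    entries = discover_entries(input_dir)

    by_pdb: dict[str, list[SummaryEntry]] = {}
    for row in old_rows:
        by_pdb.setdefault(row.values["pdb_id"].lower(), []).append(row)

    new_manifest: dict[str, str] = {}
    out_rows: list[SummaryEntry] = []
    for pdb_id in sorted(set(by_pdb) | set(entries)):
        if pdb_id not in entries:
            report.removed.append(pdb_id)
            continue
        checksum = entry_checksum(*entries[pdb_id])
        if old_manifest.get(pdb_id) == checksum and pdb_id in by_pdb:
            out_rows.extend(by_pdb[pdb_id])
            new_manifest[pdb_id] = checksum
            report.skipped_unchanged.append(pdb_id)
            continue
        try:
            out_rows.extend(_compute_rows(pdb_id, entries[pdb_id], config, affinity))
            new_manifest[pdb_id] = checksum
            report.processed.append(pdb_id)
        except Exception as exc:
            logger.error("entry %s failed; keeping previous rows: %s", pdb_id, exc)
            report.errors[pdb_id] = str(exc)
            out_rows.extend(by_pdb.get(pdb_id, []))
            if pdb_id in old_manifest:
                new_manifest[pdb_id] = old_manifest[pdb_id]
    write_summary(summary_path, out_rows)
    _write_manifest(summary_path, new_manifest)
    return report
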