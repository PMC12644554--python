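"""Synthetic structure + FASTA fixture generation with known ground truth.

Fixtures are geometric idealizations, not physically plausible proteins:
every computation in this package depends only on heavy-atom distances,
chain-internal residue indices, sequence lengths and framework sequence
motifs, so a fixture only has to control those exactly.

Layout scheme
-------------
* Each chain owns a "home" ball: a spherical-spiral Cα trace (consecutive
  points ~3.8 Å apart on a sphere) whose radius controls the chain's mean
  radius. Home balls of different chains are separated by 1 km-scale gaps
  (1000 Å), so no unintended inter-chain contacts exist.
* Antibody chains reuse the packaged reference-domain geometry for their
  variable domain, so they pass the structural domain filter by
  construction; constant domains and second variable domains occupy a
  second ball at a configurable offset (which sets scFv vs VHVL
  compactness).
* A designed contact between two chains is realized in a dedicated remote
  "meeting region": each designated residue receives one extra pseudo
  side-chain atom there, placed so that exactly the designated residue sets
  fall within 5 Å of the partner chain — interface counts and mean interface
  indices are therefore exact by construction and are re-verified by
  ``interface_geometry`` after generation.
* Missing-residue masks remove residues from the coordinates but never from
  the FASTA sequence.

Sequences embed the canonical variable-domain framework anchors (the two
conserved cysteines, the framework-2 tryptophan, the J-segment closing
motif) so the built-in motif detector types each chain as designed; filler
segments are drawn from an anchor-free alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

# --- sequence templates -------------------------------------------------------

# 110 aa synthetic heavy variable domain: C22 ... W36 ... C92 ... WGQG at 103
VH_TEMPLATE = (
    "EVQLVESGGGLVQPGGSLRLS"  # FR1 1-21
    "C"                      # 22
    "AASGFTFSDYAMS"          # 23-35 (CDR-H1 region)
    "W"                      # 36
    "VRQAPGKGLEWVS"          # 37-49
    "AISGSGGSTYYADSVK"       # 50-65 (CDR-H2 region)
    "GRFTISNSKNTLQMNSLRAEDTAVYY"  # 66-91 (FR3, ends with the canonical YYC context)
    "C"                      # 92
    "AK"                     # 93-94
    "DRGYGMDY"               # 95-102 (CDR-H3)
    "WGQG"                   # 103-106 J motif
    "TLVT"                   # 107-110
)

# VHH variant: framework-2 carries the hydrophilic hallmark (E44/R45 analog)
VHH_TEMPLATE = VH_TEMPLATE[:36] + "VRQAPGKEREFVS" + VH_TEMPLATE[49:]

# 108 aa synthetic light variable domain: C23 ... W35 ... C88 ... FGQG at 98
VL_TEMPLATE = (
    "DIQMTQSPSSLSASVGDRVTIT"  # FR1 1-22
    "C"                       # 23
    "RASQSISSYLN"             # 24-34 (CDR-L1 region)
    "W"                       # 35
    "YQQKPGKAPKLLI"           # 36-48
    "YAASSLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYY"  # 49-87
    "C"                       # 88
    "QQSYSTPLT"               # 89-97 (CDR-L3)
    "FGQG"                    # 98-101 J motif
    "TKVEIKR"                 # 102-108
)

SCFV_LINKER = "GGGGSGGGGSGGGGS"

# anchor-free filler alphabet: no C/W/F, so no spurious variable domains
_FILLER_ALPHABET = "ADEGHIKLNPQRSTV"
_NUC_ALPHABET = {"dna": "ACGT", "rna": "ACGU"}

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
NUC3 = {"dna": {"A": "DA", "C": "DC", "G": "DG", "T": "DT"},
        "rna": {"A": "A", "C": "C", "G": "G", "U": "U"}}


def filler(length: int, rng: np.random.Generator, alphabet: str = _FILLER_ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


# --- geometry -----------------------------------------------------------------

CA_STEP = 3.8


def spiral_points(n: int, radius: float) -> np.ndarray:
    """A spherical spiral of n points with ~CA_STEP arc spacing.

    Walks a spiral from pole to pole on a sphere, accumulating arc length;
    deterministic and compact (all points at ``radius`` from the center), so
    the trace doubles as a well-folded reference domain stand-in.
    """
    turns = max(3.0, math.sqrt(n))
    pts = []
    t = 0.0
    dt = 1e-4
    acc = CA_STEP  # emit the first point immediately
    while len(pts) < n:
        theta = math.pi * t
        phi = 2.0 * math.pi * turns * t
        if acc >= CA_STEP:
            pts.append((
                radius * math.sin(theta) * math.cos(phi),
                radius * math.sin(theta) * math.sin(phi),
                radius * math.cos(theta),
            ))
            acc = 0.0
        # arc length element of the spherical spiral
        dth = math.pi * dt
        dph = 2.0 * math.pi * turns * dt
        ds = radius * math.sqrt(dth ** 2 + (math.sin(theta) * dph) ** 2)
        acc += ds
        t += dt
        if t > 1.0:  # wrap with a slightly larger sphere if n outruns the spiral
            t = 0.0
            radius *= 1.15
    return np.asarray(pts)


def line_points(n: int) -> np.ndarray:
    """Extended (fibril-like) straight Cα trace."""
    return np.column_stack([CA_STEP * np.arange(n), np.zeros(n), np.zeros(n)])


# --- fixture specification ----------------------------------------------------

@dataclass
class ChainSpec:
    chain_id: str
    kind: str                     # HC | LC | HLC | antigen | decoy
    length: int = 0               # 0: template length
    missing: tuple[int, ...] = () # 1-based FASTA positions without coordinates
    layout: str = "compact"       # compact | extended
    vhh: bool = False             # heavy single-domain hallmark framework
    domain_gap_A: float = 18.0    # HLC domain-center separation (compactness)
    molecule_name: str = ""
    species: str = "Homo sapiens"
    polymer: str = "protein"      # protein | dna | rna


@dataclass
class ContactSpec:
    """Designed interface between two chains.

    ``indices_*`` are 1-based seq_index values (ordinals among residues with
    coordinates). Use :func:`indices_with_mean` to build a set with an exact
    target mean.
    """

    chain_a: str
    chain_b: str
    indices_a: tuple[int, ...]
    indices_b: tuple[int, ...]

    @property
    def n_total(self) -> int:
        return len(self.indices_a) + len(self.indices_b)


@dataclass
class FixtureSpec:
    pdb_id: str
    chains: list[ChainSpec]
    contacts: list[ContactSpec] = field(default_factory=list)
    seed: int = 0
    n_models: int = 1
    include_water: bool = False
    title: str = "synthetic fixture"


def indices_with_mean(n: int, mean: float, lo: int = 1, hi: int = 10**6) -> tuple[int, ...]:
    """n distinct 1-based indices with exactly the requested mean."""
    target = round(n * mean)
    if abs(target - n * mean) > 1e-9:
        raise ValueError(f"mean {mean} not realizable with {n} integer indices")
    base = (target - n * (n - 1) // 2) // n
    rem = target - (n * base + n * (n - 1) // 2)
    idx = [base + i + (1 if i >= n - rem else 0) for i in range(n)]
    if idx[0] < lo or idx[-1] > hi:
        raise ValueError(f"indices {idx[0]}..{idx[-1]} outside [{lo},{hi}]")
    return tuple(idx)


# --- sequence/geometry assembly ------------------------------------------------

def _chain_sequence(spec: ChainSpec, rng: np.random.Generator) -> str:
    if spec.polymer in ("dna", "rna"):
        length = spec.length or 60
        return filler(length, rng, _NUC_ALPHABET[spec.polymer])
    if spec.kind == "HC":
        core = VHH_TEMPLATE if spec.vhh else VH_TEMPLATE
    elif spec.kind in ("LC", "decoy"):
        core = VL_TEMPLATE
    elif spec.kind == "HLC":
        core = VH_TEMPLATE + SCFV_LINKER + VL_TEMPLATE
    else:  # antigen
        length = spec.length or 120
        return filler(length, rng)
    length = spec.length or len(core)
    if length < len(core):
        raise ValueError(f"{spec.chain_id}: length {length} shorter than template {len(core)}")
    return core + filler(length - len(core), rng)


def _chain_geometry(spec: ChainSpec, seq_len: int, origin: np.ndarray) -> np.ndarray:
    """Cα (or C1') positions for every FASTA position of the chain."""
    if spec.layout == "extended":
        return line_points(seq_len) + origin
    if spec.kind == "HC":
        head = spiral_points(min(110, seq_len), 14.0)
        rest = seq_len - len(head)
        parts = [head]
        if rest > 0:
            parts.append(spiral_points(rest, 13.0) + np.array([50.0, 0.0, 0.0]))
        return np.vstack(parts) + origin
    if spec.kind in ("LC", "decoy"):
        head = spiral_points(min(108, seq_len), 13.0)
        rest = seq_len - len(head)
        parts = [head]
        if rest > 0:
            parts.append(spiral_points(rest, 13.0) + np.array([50.0, 0.0, 0.0]))
        return np.vstack(parts) + origin
    if spec.kind == "HLC":
        # two domain balls with centers domain_gap_A apart; the gap sets the
        # chain's mean radius (~sqrt(r_domain^2 + gap^2/4)), i.e. scFv-like
        # compactness vs a loose VH-VL fusion
        gap = spec.domain_gap_A
        vh = spiral_points(110, 14.0)
        n_linker = min(len(SCFV_LINKER), max(0, seq_len - 110))
        linker = np.column_stack([
            gap * (np.arange(n_linker) + 1) / (n_linker + 1),
            np.zeros(n_linker),
            np.zeros(n_linker),
        ])
        rest = seq_len - 110 - n_linker
        parts = [vh]
        if n_linker:
            parts.append(linker)
        if rest > 0:
            parts.append(spiral_points(rest, 13.0) + np.array([gap, 0.0, 0.0]))
        return np.vstack(parts) + origin
    # antigen / nucleic: its own compact ball
    return spiral_points(seq_len, 12.0) + origin


def generate_fixture(spec: FixtureSpec) -> tuple[str, str, dict]:
    """Build (mmCIF text, FASTA text, ground-truth record) from a spec.

    Deterministic under ``spec.seed``; raises before writing anything when a
    contact is geometrically or combinatorially infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    by_id = {c.chain_id: c for c in spec.chains}
    if len(by_id) != len(spec.chains):
        raise ValueError("duplicate chain ids in fixture spec")
    for con in spec.contacts:
        if con.chain_a == con.chain_b:
            raise ValueError(f"chain {con.chain_a} cannot contact itself")
        for cid in (con.chain_a, con.chain_b):
            if cid not in by_id:
                raise ValueError(f"contact references unknown chain {cid}")

    sequences = {c.chain_id: _chain_sequence(c, rng) for c in spec.chains}

    # seq_index (ordinal among residues with coordinates) -> FASTA position
    present: dict[str, list[int]] = {}
    for c in spec.chains:
        seq = sequences[c.chain_id]
        missing = set(c.missing)
        bad = [p for p in missing if not 1 <= p <= len(seq)]
        if bad:
            raise ValueError(f"{c.chain_id}: missing positions {bad} out of range")
        present[c.chain_id] = [p for p in range(1, len(seq) + 1) if p not in missing]
        if not present[c.chain_id]:
            raise ValueError(f"{c.chain_id}: all residues masked out")

    for con in spec.contacts:
        for cid, idxs in ((con.chain_a, con.indices_a), (con.chain_b, con.indices_b)):
            if len(set(idxs)) != len(idxs):
                raise ValueError(f"contact {con.chain_a}-{con.chain_b}: duplicate indices")
            if not idxs or max(idxs) > len(present[cid]) or min(idxs) < 1:
                raise ValueError(
                    f"contact {con.chain_a}-{con.chain_b}: indices outside chain {cid}"
                )

    # per-chain coordinates at home balls 1000 Å apart
    coords: dict[str, np.ndarray] = {}
    for i, c in enumerate(spec.chains):
        origin = np.array([0.0, 1000.0 * i, 0.0])
        coords[c.chain_id] = _chain_geometry(c, len(sequences[c.chain_id]), origin)

    # contact pseudo-atoms in isolated meeting regions
    extra_atoms: dict[str, dict[int, list[tuple[str, np.ndarray]]]] = {
        c.chain_id: {} for c in spec.chains
    }
    for ci, con in enumerate(spec.contacts):
        z = 5000.0 + 1000.0 * ci
        na, nb = len(con.indices_a), len(con.indices_b)
        for k in range(max(na, nb)):
            ia = con.indices_a[k % na]
            ib = con.indices_b[k % nb]
            pa = np.array([12.0 * k, 0.0, z])
            pb = np.array([12.0 * k, 3.0, z])
            slot_a = extra_atoms[con.chain_a].setdefault(ia, [])
            slot_a.append((f"CB{len(slot_a) + 1}", pa))
            slot_b = extra_atoms[con.chain_b].setdefault(ib, [])
            slot_b.append((f"CB{len(slot_b) + 1}", pb))

    cif_text = _write_mmcif(spec, sequences, present, coords, extra_atoms)
    fasta_text = _write_fasta(spec, sequences)
    truth = {
        "pdb_id": spec.pdb_id,
        "seed": spec.seed,
        "chain_types": {c.chain_id: c.kind for c in spec.chains},
        "contacts": [
            {
                "chains": (con.chain_a, con.chain_b),
                "n_total": con.n_total,
                "mean_a": float(np.mean(con.indices_a)),
                "mean_b": float(np.mean(con.indices_b)),
                "indices_a": list(con.indices_a),
                "indices_b": list(con.indices_b),
            }
            for con in spec.contacts
        ],
    }
    return cif_text, fasta_text, truth


def _residue_name(letter: str, polymer: str) -> str:
    if polymer in ("dna", "rna"):
        return NUC3[polymer][letter]
    return AA3[letter]


def _write_mmcif(spec, sequences, present, coords, extra_atoms) -> str:
    st = gemmi.Structure()
    st.name = spec.pdb_id.upper()
    rep = {"protein": "CA", "dna": "C1'", "rna": "C1'"}
    for model_no in range(1, spec.n_models + 1):
        model = gemmi.Model(model_no)
        for c in spec.chains:
            chain = gemmi.Chain(c.chain_id)
            seq = sequences[c.chain_id]
            for seq_index, fasta_pos in enumerate(present[c.chain_id], start=1):
                res = gemmi.Residue()
                res.name = _residue_name(seq[fasta_pos - 1], c.polymer)
                res.seqid = gemmi.SeqId(fasta_pos, " ")
                atom = gemmi.Atom()
                atom.name = rep[c.polymer]
                x, y, z = coords[c.chain_id][fasta_pos - 1]
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element("C")
                atom.occ = 1.0
                res.add_atom(atom)
                for name, pos in extra_atoms[c.chain_id].get(seq_index, []):
                    a = gemmi.Atom()
                    a.name = name
                    a.pos = gemmi.Position(*pos)
                    a.element = gemmi.Element("C")
                    a.occ = 1.0
                    res.add_atom(a)
                chain.add_residue(res)
            model.add_chain(chain)
        if spec.include_water:
            wchain = gemmi.Chain("w")
            for i in range(3):
                res = gemmi.Residue()
                res.name = "HOH"
                res.seqid = gemmi.SeqId(i + 1, " ")
                atom = gemmi.Atom()
                atom.name = "O"
                atom.pos = gemmi.Position(-100.0 - 10 * i, -100.0, -100.0)
                atom.element = gemmi.Element("O")
                atom.occ = 1.0
                res.add_atom(atom)
                wchain.add_residue(res)
            model.add_chain(wchain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    block = doc.sole_block()
    block.set_pair("_struct.title", gemmi.cif.quote(spec.title))
    block.set_pair("_exptl.method", gemmi.cif.quote("SYNTHETIC"))
    return doc.as_string()


def _write_fasta(spec: FixtureSpec, sequences: dict[str, str]) -> str:
    lines = []
    for i, c in enumerate(spec.chains, start=1):
        molecule = c.molecule_name or f"synthetic {c.kind} chain"
        lines.append(f">{spec.pdb_id.upper()}_{i}|Chain {c.chain_id}|{molecule}|{c.species}")
        seq = sequences[c.chain_id]
        for j in range(0, len(seq), 80):
            lines.append(seq[j : j + 80])
    return "\n".join(lines) + "\n"


def write_fixture(spec: FixtureSpec, out_dir) -> tuple[str, str, dict]:
    """Generate and write ``<pdb_id>.cif`` / ``<pdb_id>.fasta``; returns paths
    plus the ground-truth record."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cif_text, fasta_text, truth = generate_fixture(spec)
    cif_path = out / f"{spec.pdb_id}.cif"
    fasta_path = out / f"{spec.pdb_id}.fasta"
    cif_path.write_text(cif_text)
    fasta_path.write_text(fasta_text)
    return str(cif_path), str(fasta_path), truth


# --- showcase analogues -------------------------------------------------------

def pairing_showcase_small(seed: int = 0) -> FixtureSpec:
    """Two-Fab complex whose interface-count table favors the swapped
    (incorrect) pairings: counts A-B 44, A-L 50, H-B 52, H-L 48, with true
    pairs A-B and H-L contacting through low (variable-domain) residue
    indices and the decoy cross-pairs through high (constant-domain) ones.
    A contact-count-only rule picks {A-L, H-B}; the mean-index penalty flips
    the solution to the designed truth."""
    mk = indices_with_mean
    return FixtureSpec(
        pdb_id="fab2",
        seed=seed,
        chains=[
            ChainSpec("A", "HC", length=220),
            ChainSpec("B", "LC", length=220),
            ChainSpec("H", "HC", length=220),
            ChainSpec("L", "LC", length=220),
        ],
        contacts=[
            ContactSpec("A", "B", mk(22, 45.0), mk(22, 45.0)),
            ContactSpec("H", "L", mk(24, 45.0), mk(24, 45.0)),
            ContactSpec("A", "L", mk(25, 170.0), mk(25, 170.0)),
            ContactSpec("H", "B", mk(26, 170.0), mk(26, 170.0)),
        ],
        title="two-Fab pairing showcase",
    )


SHOWCASE_SMALL_TRUE_PAIRS = {("A", "B"), ("H", "L")}
SHOWCASE_SMALL_COUNTS = {("A", "B"): 44, ("A", "L"): 50, ("H", "B"): 52, ("H", "L"): 48}


def pairing_showcase_large(seed: int = 0) -> FixtureSpec:
    """Four-Fab complex (heavy chains B, E, H, K; light chains A, D, G, J)
    with interface counts B-A 51, E-A 60, B-D 56, E-D 50, H-G 48, K-G 57,
    H-J 55, K-J 50. Contact counts alone select {E-A, B-D, K-G, H-J}; the
    designed truth is {B-A, E-D, H-G, K-J}."""
    mk = indices_with_mean
    return FixtureSpec(
        pdb_id="fab4",
        seed=seed,
        chains=[
            ChainSpec("A", "LC", length=220),
            ChainSpec("B", "HC", length=220),
            ChainSpec("D", "LC", length=220),
            ChainSpec("E", "HC", length=220),
            ChainSpec("G", "LC", length=220),
            ChainSpec("H", "HC", length=220),
            ChainSpec("J", "LC", length=220),
            ChainSpec("K", "HC", length=220),
        ],
        contacts=[
            ContactSpec("B", "A", mk(26, 45.0), mk(25, 45.0)),
            ContactSpec("E", "A", mk(30, 170.0), mk(30, 170.0)),
            ContactSpec("B", "D", mk(28, 170.0), mk(28, 170.0)),
            ContactSpec("E", "D", mk(25, 45.0), mk(25, 45.0)),
            ContactSpec("H", "G", mk(24, 45.0), mk(24, 45.0)),
            ContactSpec("K", "G", mk(29, 170.0), mk(28, 170.0)),
            ContactSpec("H", "J", mk(28, 170.0), mk(27, 170.0)),
            ContactSpec("K", "J", mk(25, 45.0), mk(25, 45.0)),
        ],
        title="four-Fab pairing showcase",
    )


SHOWCASE_LARGE_TRUE_PAIRS = {("B", "A"), ("E", "D"), ("H", "G"), ("K", "J")}
SHOWCASE_LARGE_COUNTS = {
    ("B", "A"): 51, ("E", "A"): 60, ("B", "D"): 56, ("E", "D"): 50,
    ("H", "G"): 48, ("K", "G"): 57, ("H", "J"): 55, ("K", "J"): 50,
}


def reference_domain_cif(kind: str) -> str:
    """Synthetic compact reference variable domain (Cα trace) as mmCIF text.

    These are the packaged stand-ins for real high-resolution VH/VL reference
    domains; users with access to such structures can point the config at
    them instead.
    """
    if kind == "VH":
        seq, radius, name = VH_TEMPLATE, 14.0, "VHREF"
    elif kind == "VL":
        seq, radius, name = VL_TEMPLATE, 13.0, "VLREF"
    else:
        raise ValueError(kind)
    pts = spiral_points(len(seq), radius)
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i, letter in enumerate(seq, start=1):
        res = gemmi.Residue()
        res.name = AA3[letter]
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.pos = gemmi.Position(*pts[i - 1])
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_mmcif_document().as_string()
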