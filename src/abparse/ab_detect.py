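"""Antibody chain detection and the structural domain filter.

Sequence detection is pluggable: any callable mapping a sequence to an
:class:`AbAnnotation` can be registered (an adapter wrapping an external
annotation tool, for instance). The built-in default is a framework-motif
detector that anchors on the conserved features every immunoglobulin
variable domain shares:

* the two canonical framework cysteines (~position 22/23 and ~88/92) that
  form the intradomain disulfide;
* the framework-2 tryptophan following CDR1;
* the J-segment ``[FW]G.G`` motif closing CDR3 (``WG.G`` in heavy domains,
  ``FG.G`` in light domains).

A domain is called when all anchors occur with canonical spacing
tolerances; CDR spans are then derived from fixed offsets relative to the
anchors (an approximation of the classical numbering-based definitions,
adequate for interface bookkeeping but not a substitute for renumbering).

Misfolded chains of antibody sequence (e.g. light-chain amyloid fibrils)
are removed by a structural filter: a length-normalized superposition score
against a compact reference variable domain, with chains scoring below the
threshold (default 0.4) demoted to non-antibody.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import Config, DEFAULT_CONFIG, DetectorConfig
from .structure_io import ChainStructure

logger = logging.getLogger(__name__)

Span = tuple[int, int]  # 1-based closed interval


@dataclass
class AbAnnotation:
    """Detector verdict for one sequence."""

    chain_type: str  # HC | LC | HLC | non_Ab
    vh_span: Span | None = None
    vl_span: Span | None = None
    cdr_spans: list[tuple[str, Span]] = field(default_factory=list)
    detector_name: str = "motif"
    fasta_disagrees: bool = False  # set by resolve_type when the FASTA verdict differed

    @property
    def is_ab(self) -> bool:
        return self.chain_type in ("HC", "LC", "HLC")


@dataclass
class DomainSimilarity:
    score: float
    reference_id: str
    aligned_pairs: int


# --- built-in motif detector -------------------------------------------------

_J_MOTIF = re.compile(r"[FW]G.G")

# anchor spacing tolerances (positions relative to the first cysteine c1 and
# the framework-2 tryptophan w); broad enough for natural CDR length variation
_W_RANGE = (4, 24)        # w - c1
_C2_RANGE = (55, 85)      # c2 - c1
_J_RANGE = (2, 40)        # motif start - c2
_NTERM_PAD = 21           # framework-1 residues preceding c1
_CTERM_PAD = 7            # J-segment residues following the motif


@dataclass
class _Domain:
    kind: str  # H or L
    span: Span
    c1: int
    w: int
    c2: int
    j: int  # 1-based start of the [FW]G.G motif

    def cdrs(self) -> list[tuple[str, Span]]:
        n = "H" if self.kind == "H" else "L"
        cdr1 = (self.c1 + 4, self.w - 2)
        cdr2 = (self.w + 14, self.c2 - (29 if self.kind == "H" else 31))
        cdr3_start = self.c2 + (3 if self.kind == "H" else 1)
        cdr3 = (cdr3_start, self.j - 1)
        out = []
        for label, (lo, hi) in ((f"{n}1", cdr1), (f"{n}2", cdr2), (f"{n}3", cdr3)):
            if lo <= hi:
                out.append((label, (lo, hi)))
        return out


def _scan_domain(seq: str, start: int) -> _Domain | None:
    """Find the first variable domain at or after ``start`` (0-based)."""
    n = len(seq)
    for c1 in range(start, n):
        if seq[c1] != "C":
            continue
        for w in range(c1 + _W_RANGE[0], min(c1 + _W_RANGE[1] + 1, n)):
            if seq[w] != "W":
                continue
            for c2 in range(c1 + _C2_RANGE[0], min(c1 + _C2_RANGE[1] + 1, n)):
                if seq[c2] != "C":
                    continue
                m = _J_MOTIF.search(seq, c2 + _J_RANGE[0], min(c2 + _J_RANGE[1] + 4, n))
                if not m:
                    continue
                kind = "H" if seq[m.start()] == "W" else "L"
                span = (max(1, c1 + 1 - _NTERM_PAD), min(n, m.start() + 4 + _CTERM_PAD))
                return _Domain(
                    kind=kind,
                    span=span,
                    c1=c1 + 1,
                    w=w + 1,
                    c2=c2 + 1,
                    j=m.start() + 1,
                )
    return None


# framework-2 class motifs directly after the conserved tryptophan
_FR2_HEAVY = re.compile(r"[VIAG][RK]Q")
_FR2_LIGHT = re.compile(r"[YFL][QL][QH]")

_PARTIAL_MIN_LENGTH = 30  # floor for truncated-domain calls


def _scan_partial(seq: str) -> _Domain | None:
    """Single truncated-domain call for chains whose structure resolves only
    part of a variable domain.

    Two guarded patterns: a C-terminal fragment keeping CDR3 (second cysteine
    preceded by the FR3 Y/F, plus the J motif at CDR3 spacing) or an
    N-terminal fragment keeping CDR1 (first cysteine near the N-terminus,
    the FR2 tryptophan, and a heavy/light FR2 class motif). The guards keep
    the patterns rare in unrelated sequences; this scan is only consulted
    when the full entity sequence already showed a complete domain.
    """
    n = len(seq)
    # C-terminal fragment: ...Y[YF]C + CDR3 + [FW]G.G
    for c2 in range(n):
        if seq[c2] != "C" or c2 < 2:
            continue
        if "Y" not in seq[c2 - 2 : c2] and "F" not in seq[c2 - 2 : c2]:
            continue
        m = _J_MOTIF.search(seq, c2 + _J_RANGE[0], min(c2 + _J_RANGE[1] + 4, n))
        if not m:
            continue
        kind = "H" if seq[m.start()] == "W" else "L"
        dom = _Domain(
            kind=kind,
            span=(max(1, c2 + 1 - 70), min(n, m.start() + 4 + _CTERM_PAD)),
            c1=max(1, c2 + 1 - 70),
            w=0,
            c2=c2 + 1,
            j=m.start() + 1,
        )
        return dom
    # N-terminal fragment: C near the start + FR2 W + FR2 class motif
    for c1 in range(min(35, n)):
        if seq[c1] != "C":
            continue
        for w in range(c1 + _W_RANGE[0], min(c1 + _W_RANGE[1] + 1, n - 3)):
            if seq[w] != "W":
                continue
            tail = seq[w + 1 : w + 4]
            if _FR2_HEAVY.match(tail):
                kind = "H"
            elif _FR2_LIGHT.match(tail):
                kind = "L"
            else:
                continue
            return _Domain(
                kind=kind,
                span=(max(1, c1 + 1 - _NTERM_PAD), min(n, c1 + 1 + 88)),
                c1=c1 + 1,
                w=w + 1,
                c2=0,
                j=0,
            )
    return None


def _partial_cdrs(dom: _Domain, n: int) -> list[tuple[str, Span]]:
    lab = dom.kind
    out: list[tuple[str, Span]] = []
    if dom.c2 and dom.j:  # C-terminal fragment: CDR3 only
        start = dom.c2 + (3 if lab == "H" else 1)
        if start <= dom.j - 1:
            out.append((f"{lab}3", (start, dom.j - 1)))
    elif dom.w:  # N-terminal fragment: CDR1 and the start of CDR2
        if dom.c1 + 4 <= dom.w - 2:
            out.append((f"{lab}1", (dom.c1 + 4, dom.w - 2)))
        end2 = min(n, dom.w + (27 if lab == "H" else 21))
        if dom.w + 14 <= end2:
            out.append((f"{lab}2", (dom.w + 14, end2)))
    return out


def detect_ab(
    seq: str,
    config: DetectorConfig | None = None,
    allow_partial: bool = False,
) -> AbAnnotation:
    """Classify a sequence as HC, LC, HLC or non-antibody.

    Sequences shorter than the minimum variable-domain length are non-Ab
    immediately. At most two variable domains are called; a chain carrying
    both a heavy and a light domain (an scFv-style construct) is an HLC.

    With ``allow_partial`` (used when the full entity sequence is already
    known to carry a complete domain but the structure resolves only a
    fragment of it), a single truncated domain may be called from partial
    anchor evidence, down to a floor of 30 residues.
    """
    cfg = config or DetectorConfig()
    seq = seq.upper()
    floor = _PARTIAL_MIN_LENGTH if allow_partial else cfg.min_domain_length
    if len(seq) < floor:
        return AbAnnotation(chain_type="non_Ab")

    domains: list[_Domain] = []
    pos = 0
    while len(domains) < 2:
        dom = _scan_domain(seq, pos)
        if dom is None:
            break
        domains.append(dom)
        pos = dom.span[1]  # continue after this domain

    if not domains and allow_partial:
        dom = _scan_partial(seq)
        if dom is not None:
            cdrs = _partial_cdrs(dom, len(seq))
            if dom.kind == "H":
                return AbAnnotation("HC", vh_span=dom.span, cdr_spans=cdrs)
            return AbAnnotation("LC", vl_span=dom.span, cdr_spans=cdrs)

    h = next((d for d in domains if d.kind == "H"), None)
    l = next((d for d in domains if d.kind == "L"), None)
    cdrs = [c for d in domains for c in d.cdrs()]
    if h and l:
        return AbAnnotation("HLC", vh_span=h.span, vl_span=l.span, cdr_spans=cdrs)
    if h:
        return AbAnnotation("HC", vh_span=h.span, cdr_spans=cdrs)
    if l:
        return AbAnnotation("LC", vl_span=l.span, cdr_spans=cdrs)
    return AbAnnotation("non_Ab")


def fr2_segment(seq: str, annotation: AbAnnotation) -> str:
    """The 12 residues following the framework-2 tryptophan of the heavy
    domain; used by the classifier's single-domain hallmark test."""
    if annotation.vh_span is None:
        return ""
    dom = _scan_domain(seq.upper(), annotation.vh_span[0] - 1)
    if dom is None or dom.kind != "H":
        return ""
    return seq[dom.w : dom.w + 12]


# --- detector registry --------------------------------------------------------

Detector = Callable[[str], AbAnnotation]

_DETECTORS: dict[str, Detector] = {}


def register_detector(name: str, fn: Detector) -> None:
    _DETECTORS[name] = fn


def get_detector(config: Config = DEFAULT_CONFIG) -> Detector:
    name = config.detector.backend
    if name == "motif":
        return lambda seq: detect_ab(seq, config.detector)
    try:
        return _DETECTORS[name]
    except KeyError:
        raise KeyError(f"no detector registered under {name!r}") from None


# --- V-gene subgroup (optional external adapter) -------------------------------

SubgroupAdapter = Callable[[str, str], str]  # (sequence, chain_type) -> label

_SUBGROUP_ADAPTER: SubgroupAdapter | None = None


def register_subgroup_adapter(fn: SubgroupAdapter) -> None:
    """Install an external germline V-gene subgroup assigner.

    There is no built-in fallback: subgroup assignment needs curated germline
    reference databases. Without an adapter every chain reports ``N.A.``.
    """
    global _SUBGROUP_ADAPTER
    _SUBGROUP_ADAPTER = fn


def assign_subgroup(seq: str, chain_type: str) -> str:
    """V-gene subgroup via the registered adapter; HLCs are excluded because
    their chimeric VH-VL nature misleads germline assignment."""
    if _SUBGROUP_ADAPTER is None or chain_type not in ("HC", "LC"):
        return "N.A."
    return _SUBGROUP_ADAPTER(seq, chain_type)


# --- verdict combination ------------------------------------------------------

def resolve_type(fasta_verdict: AbAnnotation, filled_verdict: AbAnnotation) -> AbAnnotation:
    """Combine the FASTA-seq and Filled-seq verdicts for one chain.

    The Filled-seq verdict wins because it reflects the residues actually
    present in the structure (an scFv construct whose light domain is
    disordered is, structurally, a heavy chain). The FASTA verdict is kept
    only as a disagreement flag.
    """
    result = AbAnnotation(
        chain_type=filled_verdict.chain_type,
        vh_span=filled_verdict.vh_span,
        vl_span=filled_verdict.vl_span,
        cdr_spans=list(filled_verdict.cdr_spans),
        detector_name=filled_verdict.detector_name,
    )
    result.fasta_disagrees = fasta_verdict.chain_type != filled_verdict.chain_type
    return result


# --- structural similarity ----------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R@P+t ≈ Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cq - R @ cp


def domain_similarity(
    query: ChainStructure,
    reference: ChainStructure,
    reference_id: str = "reference",
) -> DomainSimilarity:
    """Length-normalized structural similarity of two chains.

    Score = Σ 1/(1+(dᵢ/d₀)²) / L_ref with d₀ = 1.24·(L_ref−15)^⅓ − 1.8
    (floored at 0.5 Å), computed over a residue correspondence obtained by
    gapless threading of the query onto the reference: every sequence offset
    is tried as a seed, each seed is refined by iterated superposition on the
    residue pairs within a shrinking distance cap, and the best-scoring
    superposition wins. 1.0 is reached exactly for a rigid copy of the
    reference; unrelated conformations (e.g. an extended fibril against a
    compact domain) score far below the 0.4 filter threshold.
    """
    q = query.representative_coords()
    r = reference.representative_coords()
    if len(q) < 10 or len(r) < 10:
        raise ValueError("both chains need >= 10 residues with representative atoms")
    l_ref = len(r)
    if l_ref < 16:
        raise ValueError("reference shorter than 16 residues: d0 undefined")
    d0 = max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)

    best_score = 0.0
    best_pairs = 0
    min_overlap = min(10, len(q), l_ref)
    caps = (8.0, 6.0, 5.0, 4.0, 3.5, 3.0)
    for offset in range(-(len(q) - min_overlap), l_ref - min_overlap + 1):
        qi0 = max(0, -offset)
        ri0 = max(0, offset)
        span = min(len(q) - qi0, l_ref - ri0)
        if span < min_overlap:
            continue
        qs = q[qi0 : qi0 + span]
        rs = r[ri0 : ri0 + span]
        keep = np.arange(span)
        R, t = _kabsch(qs[keep], rs[keep])
        for cap in caps:
            for _ in range(20):
                d = np.linalg.norm(qs @ R.T + t - rs, axis=1)
                new_keep = np.nonzero(d <= cap)[0]
                if len(new_keep) < 3:
                    break
                if np.array_equal(new_keep, keep):
                    break
                keep = new_keep
                R, t = _kabsch(qs[keep], rs[keep])
            d = np.linalg.norm(qs @ R.T + t - rs, axis=1)
            score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)
            if score > best_score:
                best_score = score
                best_pairs = int(span)

    return DomainSimilarity(score=best_score, reference_id=reference_id, aligned_pairs=best_pairs)


def structural_filter(
    chains: list[tuple[ChainStructure, AbAnnotation]],
    vh_ref: ChainStructure | None,
    vl_ref: ChainStructure | None,
    threshold: float = 0.4,
) -> list[tuple[ChainStructure, AbAnnotation]]:
    """Demote antibody-typed chains lacking a folded variable domain.

    HC-typed chains are scored against the VH reference, LC-typed against the
    VL reference; chains scoring below the threshold become non_Ab. HLCs are
    checked against both references and demoted only when neither domain
    superposes. Chains typed non_Ab are never scored. With no references the
    filter is disabled with a warning.
    """
    if vh_ref is None and vl_ref is None:
        warnings.warn("structural filter disabled: no reference domains available",
                      stacklevel=2)
        return chains

    def score_vs(ref: ChainStructure | None, chain: ChainStructure, ref_id: str) -> float:
        if ref is None:
            return 1.0  # cannot check; do not demote on a missing reference
        try:
            return domain_similarity(chain, ref, ref_id).score
        except ValueError:
            return 1.0

    out: list[tuple[ChainStructure, AbAnnotation]] = []
    for chain, ann in chains:
        if not ann.is_ab:
            out.append((chain, ann))
            continue
        if ann.chain_type == "HC":
            best = score_vs(vh_ref, chain, "VH_ref")
        elif ann.chain_type == "LC":
            best = score_vs(vl_ref, chain, "VL_ref")
        else:  # HLC: either folded domain suffices
            best = max(score_vs(vh_ref, chain, "VH_ref"), score_vs(vl_ref, chain, "VL_ref"))
        if best < threshold:
            logger.info(
                "chain %s (model %d) typed %s but domain similarity %.3f < %.2f; demoted",
                chain.chain_id, chain.model_id, ann.chain_type, best, threshold,
            )
            out.append((chain, AbAnnotation("non_Ab", detector_name=ann.detector_name)))
        else:
            out.append((chain, ann))
    return out


def load_reference_chain(path: str) -> ChainStructure | None:
    """Load a single-chain reference coordinate file (mmCIF, Cα trace is
    enough). Returns None, with a warning, when the file is missing."""
    import gemmi

    try:
        st = gemmi.read_structure(path)
    except Exception:
        warnings.warn(f"reference structure {path!r} missing or unreadable; "
                      "structural filter will be disabled for its type", stacklevel=2)
        return None
    from .structure_io import Residue, extract_pdb_seq

    model = st[0]
    chain = model[0]
    residues = []
    idx = 0
    for res in chain:
        atoms = [(a.name, a.pos.x, a.pos.y, a.pos.z) for a in res if not a.is_hydrogen()]
        if not any(a[0] == "CA" for a in atoms):
            continue
        idx += 1
        residues.append(Residue(res.name, idx, res.seqid.num, "", atoms))
    if not residues:
        return None
    cs = ChainStructure(chain_id=chain.name, model_id=1, entity_id="", residues=residues)
    cs.pdb_seq = extract_pdb_seq(cs)
    cs.filled_seq = cs.pdb_seq
    return cs
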