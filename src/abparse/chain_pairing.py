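"""Heavy-light chain pairing by greedy construction plus local-search refinement.

Candidate pairs are the type combinations that can form a functional Fv:
HC-LC, HC-HLC, LC-HLC and HLC-HLC (never HC-HC or LC-LC, so homodimers
decompose into monomer entries). A candidate survives only if its interface
residue count meets the per-combination minimum.

Each pair is scored

    score = 3 * N_interface - floor((MI_H + MI_L) / 2)

where MI is the mean chain-internal index of a chain's interface residues:
contacts through the N-terminal variable domains (low indices) are rewarded,
constant-domain or lattice contacts (high indices) are penalized. Every
unpaired chain is carried as a pair with a dummy partner at a fixed score of
-100, which lets a modest genuine pairing beat leaving both chains single
while keeping junk pairings out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

from .ab_detect import AbAnnotation
from .config import PairingConfig
from .interface_geometry import interface_residues
from .structure_io import ChainStructure

logger = logging.getLogger(__name__)

DUMMY = "<dummy>"

_ALLOWED = {
    frozenset(("HC", "LC")),
    frozenset(("HC", "HLC")),
    frozenset(("LC", "HLC")),
    frozenset(("HLC",)),  # HLC-HLC
}


@dataclass(frozen=True)
class HLPair:
    heavy_key: str
    light_key: str  # DUMMY for placeholder pairs
    n_interface: int
    mean_index_h: float
    mean_index_l: float
    score: int

    @property
    def is_dummy(self) -> bool:
        return self.light_key == DUMMY

    @property
    def chains(self) -> tuple[str, ...]:
        return (self.heavy_key,) if self.is_dummy else (self.heavy_key, self.light_key)


@dataclass
class PairingSolution:
    pairs: list[HLPair]            # selected real pairs
    unpaired: list[str]            # chains carried by dummy pairs
    total_score: int

    def real_pairs(self) -> set[tuple[str, str]]:
        return {(p.heavy_key, p.light_key) for p in self.pairs}

    def canonical(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.real_pairs()))


def make_dummy(chain_key: str, config: PairingConfig | None = None) -> HLPair:
    cfg = config or PairingConfig()
    return HLPair(chain_key, DUMMY, 0, 0.0, 0.0, cfg.dummy_penalty)


def score_pair(
    n_interface: int,
    mean_index_h: float,
    mean_index_l: float,
    config: PairingConfig | None = None,
) -> int:
    """Score of a real candidate pair; raises if the pair has no interface."""
    cfg = config or PairingConfig()
    if n_interface <= 0:
        raise ValueError("real pair with zero interface residues should have been filtered")
    return cfg.reward_scale * n_interface - math.floor((mean_index_h + mean_index_l) / 2.0)


def _cutoff_for(types: frozenset[str], cfg: PairingConfig) -> int:
    if types == frozenset(("HC", "LC")):
        return cfg.cutoff_hc_lc
    if types == frozenset(("HC", "HLC")):
        return cfg.cutoff_hc_hlc
    if types == frozenset(("LC", "HLC")):
        return cfg.cutoff_lc_hlc
    return cfg.cutoff_hlc_hlc


def _roles(
    a: tuple[ChainStructure, AbAnnotation],
    b: tuple[ChainStructure, AbAnnotation],
) -> tuple[tuple[ChainStructure, AbAnnotation], tuple[ChainStructure, AbAnnotation]]:
    """Assign the heavy/light slots of a candidate pair.

    The VH-carrying chain takes the heavy slot; between two HLCs (or two
    chains of the same type) the lexicographically smaller chain id does.
    """
    ta, tb = a[1].chain_type, b[1].chain_type
    if ta == tb:
        return (a, b) if a[0].chain_id <= b[0].chain_id else (b, a)
    order = {"HC": 0, "HLC": 1, "LC": 2}
    return (a, b) if order[ta] < order[tb] else (b, a)


def enumerate_candidates(
    ab_chains: list[tuple[ChainStructure, AbAnnotation]],
    config: PairingConfig | None = None,
) -> list[HLPair]:
    """All scored candidate pairs among one model's antibody chains.

    Pairs are formed within and between entities; a pair is kept iff its
    interface residue count (summed over both chains) meets the cutoff for
    its type combination.
    """
    cfg = config or PairingConfig()
    candidates: list[HLPair] = []
    for a, b in combinations(ab_chains, 2):
        types = frozenset((a[1].chain_type, b[1].chain_type))
        if types not in _ALLOWED:
            continue
        (hc, _), (lc, _) = _roles(a, b)
        iface = interface_residues(hc, lc, cutoff_A=cfg.interface_cutoff_A)
        if iface.n_total < _cutoff_for(types, cfg) or iface.n_total == 0:
            continue
        mi_h = iface.mean_index_a if iface.mean_index_a is not None else 0.0
        mi_l = iface.mean_index_b if iface.mean_index_b is not None else 0.0
        candidates.append(
            HLPair(
                heavy_key=hc.chain_id,
                light_key=lc.chain_id,
                n_interface=iface.n_total,
                mean_index_h=mi_h,
                mean_index_l=mi_l,
                score=score_pair(iface.n_total, mi_h, mi_l, cfg),
            )
        )
    return candidates


def _rank_key(pair: HLPair) -> tuple:
    return (-pair.score, pair.heavy_key, "" if pair.is_dummy else pair.light_key)


def greedy_pairing(
    candidates: list[HLPair],
    chain_keys: list[str],
    config: PairingConfig | None = None,
) -> tuple[PairingSolution, list[HLPair]]:
    """Greedy construction of an initial pairing.

    Every chain is first given a placeholder dummy pair; all pairs (real and
    dummy) are ranked by score, ties broken lexicographically, and selected
    top-down subject to each chain being used once. Returns the solution and
    the pool of unused real candidates.
    """
    cfg = config or PairingConfig()
    all_pairs = list(candidates) + [make_dummy(k, cfg) for k in chain_keys]
    all_pairs.sort(key=_rank_key)
    used: set[str] = set()
    selected: list[HLPair] = []
    for pair in all_pairs:
        if any(c in used for c in pair.chains):
            continue
        logger.debug("greedy: select %s-%s score %d", pair.heavy_key, pair.light_key, pair.score)
        selected.append(pair)
        used.update(pair.chains)
        if len(used) == len(chain_keys):
            break
    pool = [p for p in candidates if p not in selected]
    real = [p for p in selected if not p.is_dummy]
    unpaired = sorted(set(chain_keys) - {c for p in real for c in p.chains})
    total = sum(p.score for p in real) + cfg.dummy_penalty * len(unpaired)
    return PairingSolution(real, unpaired, total), pool


def refine_pairing(
    solution: PairingSolution,
    pool: list[HLPair],
    chain_keys: list[str],
    config: PairingConfig | None = None,
) -> PairingSolution:
    """Local-search refinement of a greedy solution.

    Each move forces one unused candidate into the solution: the selected
    pairs it conflicts with are removed, and the remainder is re-completed
    greedily from the rest of the pool (displaced chains that cannot be
    re-paired fall back to dummy pairs). A move is accepted only when the
    total score strictly increases; substituted pairs return to the pool.
    Terminates because the total is strictly increasing and bounded above.
    """
    cfg = config or PairingConfig()
    current_pairs = list(solution.pairs)
    current_total = solution.total_score
    pool = sorted(pool, key=_rank_key)

    def total_of(pairs: list[HLPair]) -> int:
        covered = {c for p in pairs for c in p.chains}
        return sum(p.score for p in pairs) + cfg.dummy_penalty * (len(chain_keys) - len(covered))

    improved = True
    while improved:
        improved = False
        for cand in pool:
            new_pairs = [p for p in current_pairs if not (set(p.chains) & set(cand.chains))]
            new_pairs.append(cand)
            used = {c for p in new_pairs for c in p.chains}
            for q in pool:
                if q is cand or (set(q.chains) & used):
                    continue
                if q.score <= 2 * cfg.dummy_penalty:
                    continue  # worse than leaving both chains unpaired
                new_pairs.append(q)
                used |= set(q.chains)
            new_total = total_of(new_pairs)
            if new_total > current_total:
                logger.debug(
                    "refine: force %s-%s in, total %d -> %d",
                    cand.heavy_key, cand.light_key, current_total, new_total,
                )
                removed = [p for p in current_pairs if p not in new_pairs]
                pool = sorted([p for p in pool if p not in new_pairs] + removed, key=_rank_key)
                current_pairs = new_pairs
                current_total = new_total
                improved = True
                break

    covered = {c for p in current_pairs for c in p.chains}
    unpaired = sorted(set(chain_keys) - covered)
    return PairingSolution(sorted(current_pairs, key=_rank_key), unpaired, current_total)


def pair_chains(
    ab_chains: list[tuple[ChainStructure, AbAnnotation]],
    config: PairingConfig | None = None,
) -> PairingSolution:
    """Full pairing pipeline for one model: enumerate, greedy, refine."""
    cfg = config or PairingConfig()
    keys = [c.chain_id for c, _ in ab_chains]
    candidates = enumerate_candidates(ab_chains, cfg)
    greedy, pool = greedy_pairing(candidates, keys, cfg)
    return refine_pairing(greedy, pool, keys, cfg)


def optimal_pairing_bruteforce(
    candidates: list[HLPair],
    chain_keys: list[str],
    config: PairingConfig | None = None,
) -> PairingSolution:
    """Exhaustive matching oracle for small instances (≤ 10 chains).

    Enumerates every matching (each chain in at most one real pair, dummies
    for the rest) and returns the maximum-total-score solution; ties are
    broken by the lexicographically smallest sorted tuple of real pairs, so
    an all-dummy solution wins a tie against any real pairing.
    """
    cfg = config or PairingConfig()
    if len(chain_keys) > 10:
        raise ValueError("brute force limited to 10 chains")

    best: tuple[int, tuple, PairingSolution] | None = None

    def recurse(idx: int, used: set[str], chosen: list[HLPair]) -> None:
        nonlocal best
        if idx == len(candidates):
            unpaired = sorted(set(chain_keys) - used)
            total = sum(p.score for p in chosen) + cfg.dummy_penalty * len(unpaired)
            sol = PairingSolution(list(chosen), unpaired, total)
            key = (-total, sol.canonical())
            if best is None or key < (-best[0], best[1]):
                best = (total, sol.canonical(), sol)
            return
        recurse(idx + 1, used, chosen)  # skip candidate idx
        cand = candidates[idx]
        if not (set(cand.chains) & used):
            chosen.append(cand)
            recurse(idx + 1, used | set(cand.chains), chosen)
            chosen.pop()

    recurse(0, set(), [])
    assert best is not None
    return best[2]


def random_pairing_instance(rng, max_chains: int = 8) -> tuple[list[HLPair], list[str]]:
    """Random abstract pairing instance for optimizer studies.

    Chain types are drawn HC/LC/HLC; each allowed pair becomes a candidate
    with probability 0.7, with interface counts in the 20-80 range observed
    for real Fv interfaces and mean interface indices spanning variable- to
    constant-domain territory (20-200).
    """
    n = int(rng.integers(2, max_chains + 1))
    types = [("HC", "LC", "HLC")[i] for i in rng.choice(3, size=n, p=(0.4, 0.4, 0.2))]
    keys = [chr(65 + i) for i in range(n)]
    candidates: list[HLPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((types[i], types[j])) not in _ALLOWED:
                continue
            if rng.random() >= 0.7:
                continue
            n_iface = int(rng.integers(20, 81))
            mi_h = float(rng.integers(20, 201))
            mi_l = float(rng.integers(20, 201))
            candidates.append(
                HLPair(keys[i], keys[j], n_iface, mi_h, mi_l, score_pair(n_iface, mi_h, mi_l))
            )
    return candidates, keys
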