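"""Curated binding-affinity table: parsing, normalization and aggregation.

Affinity data is maintained separately from structure parsing (it is
literature-curated) and merged into summary rows by (pdb_id, heavy chain,
light chain). Dissociation constants are stored in nM; pK_D is the negative
decadic log of K_D in molar units, i.e. pK_D = 9 - log10(K_D[nM]).

When one interaction carries several measurements, ITC records take
priority over every other technique; within the chosen method set the
geometric mean is reported (K_D spans orders of magnitude, so the geometric
mean — the arithmetic mean in pK_D space — is the natural aggregate).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from collections import Counter
from pathlib import Path

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("SPR", "BLI", "ITC", "ELISA", "KinExA", "SET", "flow", "interferometry", "other")


@dataclass
class AffinityRecord:
    pdb_id: str
    heavy_chain: str
    light_chain: str
    antigen_chains: str
    kd_nM: float
    method: str
    temperature_K: str  # numeric string or "N.A."
    reference: str = ""
    mixed_methods: bool = False  # set on aggregates built across method ties

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError(f"non-positive K_D: {self.kd_nM}")

    @property
    def pkd(self) -> float:
        return 9.0 - math.log10(self.kd_nM)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.pdb_id.lower(), self.heavy_chain, self.light_chain)


def normalize_temperature(value: str) -> str:
    """Map free-text temperatures to Kelvin; room temperature is 298 K."""
    text = (value or "").strip()
    if not text or text.upper() in ("N.A.", "NA", "NONE"):
        return "N.A."
    if "room" in text.lower() or text.upper() == "RT":
        return "298"
    try:
        return f"{float(text):g}"
    except ValueError:
        return "N.A."


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read the tab-separated curated table.

    Columns: pdb_id, heavy_chain, light_chain, antigen_chains, kd_nM, method,
    temperature_K, reference. Records with a non-positive K_D are rejected
    with a warning and skipped.
    """
    records: list[AffinityRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            try:
                rec = AffinityRecord(
                    pdb_id=row["pdb_id"].strip().lower(),
                    heavy_chain=row.get("heavy_chain", "").strip(),
                    light_chain=row.get("light_chain", "").strip(),
                    antigen_chains=row.get("antigen_chains", "").strip(),
                    kd_nM=float(row["kd_nM"]),
                    method=row.get("method", "other").strip() or "other",
                    temperature_K=normalize_temperature(row.get("temperature_K", "")),
                    reference=row.get("reference", "").strip(),
                )
            except (ValueError, KeyError) as exc:
                logger.warning("skipping affinity row %r: %s", row, exc)
                continue
            records.append(rec)
    return records


def aggregate_affinity(records: list[AffinityRecord]) -> AffinityRecord:
    """Aggregate multiple measurements of one interaction.

    If any ITC record exists, only ITC records enter the aggregate (ITC is
    treated as the most accurate technique); otherwise records of the most
    frequent method are used (frequency ties broken alphabetically, and the
    aggregate is flagged as mixed). The aggregate K_D is the geometric mean;
    the temperature is passed through only when unanimous.
    """
    if not records:
        raise ValueError("no affinity records to aggregate")
    itc = [r for r in records if r.method.upper() == "ITC"]
    mixed = False
    if itc:
        chosen = itc
    else:
        counts = Counter(r.method for r in records)
        top = max(counts.values())
        winners = sorted(m for m, c in counts.items() if c == top)
        method = winners[0]
        mixed = len(counts) > 1
        chosen = [r for r in records if r.method == method]

    kd = math.exp(sum(math.log(r.kd_nM) for r in chosen) / len(chosen))
    temps = {r.temperature_K for r in chosen}
    temp = temps.pop() if len(temps) == 1 else "N.A."
    first = chosen[0]
    return AffinityRecord(
        pdb_id=first.pdb_id,
        heavy_chain=first.heavy_chain,
        light_chain=first.light_chain,
        antigen_chains=first.antigen_chains,
        kd_nM=kd,
        method=first.method,
        temperature_K=temp,
        reference="; ".join(sorted({r.reference for r in chosen if r.reference})),
        mixed_methods=mixed,
    )


def affinity_index(records: list[AffinityRecord]) -> dict[tuple[str, str, str], AffinityRecord]:
    """Aggregate a full table into a lookup keyed by (pdb, heavy, light)."""
    by_key: dict[tuple[str, str, str], list[AffinityRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.key, []).append(rec)
    return {key: aggregate_affinity(recs) for key, recs in by_key.items()}
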