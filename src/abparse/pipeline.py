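"""End-to-end processing of one structure entry.

parse -> detect antibody chains (FASTA + Filled-seq verdicts, combined) ->
structural domain filter -> heavy-light pairing -> chain-type classification
-> antigen screening and grouping. The result object carries everything the
summary writer needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .aai_identify import AAIRecord, group_antigens, screen_antigen
from .ab_classify import AbTypeCall, classify_chain, merge_pair_call
from .ab_detect import (
    AbAnnotation,
    get_detector,
    load_reference_chain,
    resolve_type,
    structural_filter,
)
from .chain_pairing import PairingSolution, pair_chains
from .config import Config, DEFAULT_CONFIG
from .interface_geometry import mean_radius
from .structure_io import ChainStructure, EntityRecord, EntryMetadata, parse_entry

logger = logging.getLogger(__name__)


@dataclass
class AbEntry:
    """One antibody entry of one model: a heavy-light pair or a single chain."""

    heavy: ChainStructure | None
    light: ChainStructure | None
    heavy_annotation: AbAnnotation | None
    light_annotation: AbAnnotation | None
    type_call: AbTypeCall
    n_hl_interface: int
    aai: AAIRecord | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (
            self.heavy.chain_id if self.heavy else "N.A.",
            self.light.chain_id if self.light else "N.A.",
        )


@dataclass
class ModelResult:
    model_id: int
    chains: list[ChainStructure]
    annotations: dict[str, AbAnnotation]
    solution: PairingSolution | None
    entries: list[AbEntry] = field(default_factory=list)


@dataclass
class EntryResult:
    pdb_id: str
    metadata: EntryMetadata
    entities: list[EntityRecord]
    models: list[ModelResult]

    @property
    def has_antibody(self) -> bool:
        return any(m.entries for m in self.models)


def _entity_of(chain: ChainStructure, entities: list[EntityRecord]) -> EntityRecord | None:
    for e in entities:
        if e.entity_id == chain.entity_id:
            return e
    return None


def _classify_entry_chain(
    chain: ChainStructure,
    ann: AbAnnotation,
    paired: bool,
    entities: list[EntityRecord],
    config: Config,
) -> AbTypeCall:
    entity = _entity_of(chain, entities)
    return classify_chain(
        ann,
        chain.filled_seq,
        paired=paired,
        molecule_name=entity.molecule_name if entity else "",
        species=entity.species if entity else "",
        radius_A=mean_radius(chain),
        cfg=config.classify,
    )


def process_entry(
    mmcif_path,
    fasta_path,
    config: Config = DEFAULT_CONFIG,
) -> EntryResult:
    """Run the full workflow on one mmCIF/FASTA pair."""
    entities, models, metadata = parse_entry(mmcif_path, fasta_path, config)
    detector = get_detector(config)

    # FASTA verdicts are per entity: every chain of an entity shares them
    fasta_verdicts: dict[str, AbAnnotation] = {}
    for ent in entities:
        if ent.polymer_kind == "protein":
            fasta_verdicts[ent.entity_id] = detector(ent.sequence)
        else:
            fasta_verdicts[ent.entity_id] = AbAnnotation("non_Ab")

    vh_ref = vl_ref = None
    if config.structural_filter.enabled:
        vh_ref = load_reference_chain(config.structural_filter.vh_reference)
        vl_ref = load_reference_chain(config.structural_filter.vl_reference)

    model_results: list[ModelResult] = []
    model_ids = sorted(models)
    if not config.summary.all_models:
        model_ids = model_ids[:1]
    for model_id in model_ids:
        chains = models[model_id]
        annotated: list[tuple[ChainStructure, AbAnnotation]] = []
        for chain in chains:
            if chain.polymer_kind != "protein":
                annotated.append((chain, AbAnnotation("non_Ab")))
                continue
            filled_verdict = detector(chain.filled_seq)
            fasta_verdict = fasta_verdicts.get(chain.entity_id, filled_verdict)
            if (
                not filled_verdict.is_ab
                and fasta_verdict.is_ab
                and config.detector.backend == "motif"
            ):
                # the entity carries a complete domain but the structure only
                # resolves a fragment of it: allow a truncated-domain call
                from .ab_detect import detect_ab

                filled_verdict = detect_ab(
                    chain.filled_seq, config.detector, allow_partial=True
                )
            annotated.append((chain, resolve_type(fasta_verdict, filled_verdict)))

        if config.structural_filter.enabled:
            annotated = structural_filter(
                annotated, vh_ref, vl_ref, config.structural_filter.threshold
            )
        annotations = {c.chain_id: a for c, a in annotated}
        ab_chains = [(c, a) for c, a in annotated if a.is_ab]
        result = ModelResult(
            model_id=model_id,
            chains=chains,
            annotations=annotations,
            solution=None,
        )
        if ab_chains:
            solution = pair_chains(ab_chains, config.pairing)
            result.solution = solution
            result.entries = _build_entries(solution, annotated, entities, config)
        model_results.append(result)

    return EntryResult(metadata.pdb_id, metadata, entities, model_results)


def _build_entries(
    solution: PairingSolution,
    annotated: list[tuple[ChainStructure, AbAnnotation]],
    entities: list[EntityRecord],
    config: Config,
) -> list[AbEntry]:
    chains = {c.chain_id: c for c, _ in annotated}
    anns = {c.chain_id: a for c, a in annotated}
    entries: list[AbEntry] = []

    for pair in sorted(solution.pairs, key=lambda p: (p.heavy_key, p.light_key)):
        h, l = chains[pair.heavy_key], chains[pair.light_key]
        call_h = _classify_entry_chain(h, anns[h.chain_id], True, entities, config)
        call_l = _classify_entry_chain(l, anns[l.chain_id], True, entities, config)
        entries.append(
            AbEntry(
                heavy=h,
                light=l,
                heavy_annotation=anns[h.chain_id],
                light_annotation=anns[l.chain_id],
                type_call=merge_pair_call(call_h, call_l),
                n_hl_interface=pair.n_interface,
            )
        )
    for key in solution.unpaired:
        chain = chains[key]
        ann = anns[key]
        call = _classify_entry_chain(chain, ann, False, entities, config)
        heavy_side = ann.chain_type in ("HC", "HLC")
        entries.append(
            AbEntry(
                heavy=chain if heavy_side else None,
                light=None if heavy_side else chain,
                heavy_annotation=ann if heavy_side else None,
                light_annotation=None if heavy_side else ann,
                type_call=call,
                n_hl_interface=0,
            )
        )

    # antigen screening: every other chain of the model is a candidate unless
    # it is part of the entry itself
    for entry in entries:
        ab_side = [
            (c, anns[c.chain_id])
            for c in (entry.heavy, entry.light)
            if c is not None
        ]
        own = {c.chain_id for c, _ in ab_side}
        accepted = []
        for cand, cand_ann in annotated:
            if cand.chain_id in own:
                continue
            if cand_ann.is_ab:
                # antibody chains of *other* entries can still be antigens
                # (anti-idiotype complexes); chains of this entry cannot
                pass
            res = screen_antigen(ab_side, cand, config.aai, config.pairing.interface_cutoff_A)
            if res.accepted:
                accepted.append(cand)
        entry.aai = group_antigens(
            entry.key[0] if entry.heavy else None,
            entry.key[1] if entry.light else None,
            ab_side,
            accepted,
            config.aai,
            config.pairing.interface_cutoff_A,
        )

    entries.sort(key=lambda e: (e.key[0], e.key[1]))
    return entries
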