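"""Chain-resolved antibody type classification.

Each antibody entry (a heavy-light pair or a single chain) is labelled with
chain-resolved types such as ``FabH:FabL``, ``VH:VL``, ``VHH`` or ``scFv``.
The classifier is a pure function of Filled-seq length, pairing context,
entity annotations (molecule name, species) and the chain's mean radius:

* length windows separate single variable domains (~110 aa) from Fab arms
  (~220 aa); chains below a window get a ``-`` suffix (incomplete domain),
  chains above it a ``+`` suffix (extra domains or fused regions);
* an unpaired heavy single domain is a VHH (nanobody) when the species is
  camelid/shark, the molecule name says so, or the framework-2 hallmark
  residues replace the VL-facing hydrophobic patch;
* a two-domain single chain (HLC) is an scFv when the molecule name carries
  an scFv-style keyword AND the chain is compact (mean radius ≤ 20 Å),
  otherwise a VHVL fusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .ab_detect import AbAnnotation, fr2_segment
from .config import ClassifyConfig


@dataclass
class AbTypeCall:
    heavy_type: str = "none"   # FabH, VH, VH+, VH-, VHH, VHH+, VHH-, none
    light_type: str = "none"   # FabL, VL, VL+, VL-, none
    hlc_type: str = "none"     # scFv, scFv+, scFv-, VHVL, VHVL+, VHVL-, none

    @property
    def label(self) -> str:
        return render_label(self)


def _suffix(length: int, window: tuple[int, int]) -> str:
    lo, hi = window
    if length < lo:
        return "-"
    if length > hi:
        return "+"
    return ""


def _is_vhh(
    seq: str,
    annotation: AbAnnotation,
    molecule_name: str,
    species: str,
    cfg: ClassifyConfig,
) -> bool:
    name = (molecule_name or "").lower()
    sp = (species or "").lower()
    if any(s in sp for s in cfg.camelid_species):
        return True
    if any(k in name for k in cfg.vhh_keywords):
        return True
    fr2 = fr2_segment(seq, annotation)
    return bool(fr2 and re.match(cfg.vhh_fr2_regex, fr2))


def classify_chain(
    annotation: AbAnnotation,
    filled_seq: str,
    paired: bool,
    molecule_name: str,
    species: str,
    radius_A: float,
    cfg: ClassifyConfig | None = None,
) -> AbTypeCall:
    """Type call for one antibody chain (one component of an entry label)."""
    cfg = cfg or ClassifyConfig()
    if not annotation.is_ab:
        raise ValueError("cannot classify a non-antibody chain")
    length = len(filled_seq)
    call = AbTypeCall()

    if annotation.chain_type == "HLC":
        name = (molecule_name or "").lower()
        is_scfv = (
            any(k in name for k in cfg.scfv_keywords) and radius_A <= cfg.scfv_radius_A
        )
        base = "scFv" if is_scfv else "VHVL"
        call.hlc_type = base + _suffix(length, cfg.scfv_window)
        return call

    in_fab = cfg.fab_window[0] <= length <= cfg.fab_window[1]
    if annotation.chain_type == "HC":
        if in_fab:
            call.heavy_type = "FabH"
        else:
            vhh = not paired and _is_vhh(filled_seq, annotation, molecule_name, species, cfg)
            base = "VHH" if vhh else "VH"
            call.heavy_type = base + _suffix(length, cfg.single_domain_window)
    else:  # LC; light chains never receive VHH-family types
        if in_fab:
            call.light_type = "FabL"
        else:
            call.light_type = "VL" + _suffix(length, cfg.single_domain_window)
    return call


def merge_pair_call(heavy: AbTypeCall, light: AbTypeCall) -> AbTypeCall:
    """Combine the two components of a paired entry into one call."""
    merged = AbTypeCall()
    merged.heavy_type = heavy.heavy_type if heavy.heavy_type != "none" else heavy.hlc_type
    merged.light_type = light.light_type if light.light_type != "none" else light.hlc_type
    return merged


def render_label(call: AbTypeCall) -> str:
    """Render an entry label: paired entries as ``H:L`` (heavy slot first),
    unpaired entries as the single component."""
    if call.hlc_type != "none":
        return call.hlc_type
    if call.heavy_type != "none" and call.light_type != "none":
        return f"{call.heavy_type}:{call.light_type}"
    if call.heavy_type != "none":
        return call.heavy_type
    if call.light_type != "none":
        return call.light_type
    return "N.A."
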