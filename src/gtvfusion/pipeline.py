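"""Standard GTV definitions and per-patient evaluation orchestration.

Seven GTV definitions are evaluated per patient: the four single-image-type
STAPLE fusions (T2w, DWI, DCE, PSMA-PET) and three union-then-STAPLE
combinations (bpMRI = T2w+DWI, mpMRI = T2w+DWI+DCE, PSMA-PET/mpMRI = all
four).  Individual-observer GTVs exist for the same seven definitions: the
observer's own delineation (single type) or the union of their delineations
across the combined types, cropped to the histopathology support.
"""

from __future__ import annotations

from .dataset import IMAGE_TYPES, DelineationSet
from .grid import BinaryMask, crop_to_support, mask_union
from .metrics import OverlapRecord, evaluate_case
from .staple import StapleParams, fuse_multi_modality, fuse_single_modality

__all__ = ["GTV_DEFINITIONS", "staple_gtvs", "individual_gtvs", "evaluate_patient"]

#: GTV name -> image types it combines, in reporting order.
GTV_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "T2w": ("T2w",),
    "DWI": ("DWI",),
    "DCE": ("DCE",),
    "PSMA-PET": ("PSMA-PET",),
    "bpMRI": ("T2w", "DWI"),
    "mpMRI": ("T2w", "DWI", "DCE"),
    "PSMA-PET/mpMRI": IMAGE_TYPES,
}


def staple_gtvs(
    dset: DelineationSet,
    params: StapleParams | None = None,
    definitions: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, BinaryMask]:
    """STAPLE GTV for every definition: single-type fusion or union-then-STAPLE."""
    params = params or StapleParams()
    definitions = definitions or GTV_DEFINITIONS
    out = {}
    for name, itypes in definitions.items():
        if len(itypes) == 1:
            out[name] = fuse_single_modality(dset, itypes[0], params)
        else:
            out[name] = fuse_multi_modality(dset, list(itypes), params)
    return out


def individual_gtvs(
    dset: DelineationSet,
    definitions: dict[str, tuple[str, ...]] | None = None,
) -> tuple[dict[str, BinaryMask], dict[str, str]]:
    """Per-observer GTVs for every definition.

    Returns masks keyed ``"<definition>|<observer>"`` plus the name->observer
    attribution map.
    """
    definitions = definitions or GTV_DEFINITIONS
    masks: dict[str, BinaryMask] = {}
    observer_of: dict[str, str] = {}
    for name, itypes in definitions.items():
        for obs in dset.observers:
            key = f"{name}|{obs}"
            union = mask_union([dset.mask_for(obs, t) for t in itypes])
            masks[key] = crop_to_support(union, dset.histo_support)
            observer_of[key] = obs
    return masks, observer_of


def evaluate_patient(
    dset: DelineationSet,
    margins_mm: list[float],
    params: StapleParams | None = None,
    include_individual: bool = True,
    definitions: dict[str, tuple[str, ...]] | None = None,
) -> list[OverlapRecord]:
    """All overlap records for one patient (STAPLE and, optionally, individual)."""
    definitions = definitions or GTV_DEFINITIONS
    gtvs = staple_gtvs(dset, params, definitions)
    sources = {name: "staple" for name in gtvs}
    observers: dict[str, str] = {}
    if include_individual:
        ind, observer_of = individual_gtvs(dset, definitions)
        gtvs = {**gtvs, **ind}
        sources.update({name: "individual" for name in ind})
        observers.update(observer_of)
    records = evaluate_case(
        dset, gtvs, dset.histo_lesion, margins_mm, sources=sources, observers=observers
    )
    # strip the observer suffix so summaries group individual GTVs by definition
    return [
        r if r.source == "staple" else OverlapRecord(**{**r.__dict__, "gtv_name": r.gtv_name.split("|")[0]})
        for r in records
    ]
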