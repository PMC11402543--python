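"""One patient's delineation data: observer x image-type GTV masks plus the
histopathology reference (lesion and support masks), all on one grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .grid import BinaryMask, GridMismatchError

__all__ = ["IMAGE_TYPES", "DelineationSet"]

#: The four image types each observer delineates, in reporting order.
IMAGE_TYPES = ("T2w", "DWI", "DCE", "PSMA-PET")


@dataclass
class DelineationSet:
    """All masks for one patient, co-registered on the reference grid.

    ``masks`` maps ``(observer_id, image_type)`` to the observer's GTV
    delineation for that image type.  ``histo_lesion`` is the ground-truth
    lesion mask (high-grade target region); ``histo_support`` marks where
    histopathology ground truth exists (whole-gland extent).
    ``truth_params`` optionally records the generating parameters of a
    synthetic patient (per-observer sensitivity/specificity, injected
    translations) for validation.
    """

    patient_id: str
    masks: dict[tuple[str, str], BinaryMask]
    histo_lesion: BinaryMask
    histo_support: BinaryMask
    truth_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.histo_lesion.grid
        if not grid.isclose(self.histo_support.grid):
            raise GridMismatchError("histo_lesion and histo_support must share one grid")
        for key, mask in self.masks.items():
            if not grid.isclose(mask.grid):
                raise GridMismatchError(f"mask {key} is not on the reference grid")

    @property
    def grid(self):
        return self.histo_lesion.grid

    @property
    def observers(self) -> list[str]:
        return sorted({obs for obs, _ in self.masks})

    @property
    def image_types(self) -> list[str]:
        seen = {itype for _, itype in self.masks}
        ordered = [t for t in IMAGE_TYPES if t in seen]
        return ordered + sorted(seen.difference(IMAGE_TYPES))

    def mask_for(self, observer: str, image_type: str) -> BinaryMask:
        try:
            return self.masks[(observer, image_type)]
        except KeyError:
            raise KeyError(
                f"patient {self.patient_id!r}: no delineation for observer "
                f"{observer!r} on image type {image_type!r}"
            ) from None
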