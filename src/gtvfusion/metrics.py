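"""Voxel-wise agreement between GTVs and the histopathology lesion.

Two metrics: the Dice similarity coefficient ``DSC = 2|A∩B| / (|A| + |B|)``
and lesion coverage, the voxel-wise sensitivity ``|GTV ∩ L| / |L|`` for
lesion mask ``L``.  Evaluation of a case applies an isotropic CTV margin to
the GTV, crops to the histopathology support, then measures both metrics
against the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import DelineationSet
from .grid import BinaryMask, GridMismatchError, crop_to_support

__all__ = ["UndefinedMetricError", "OverlapRecord", "dice", "lesion_coverage", "evaluate_case", "records_to_frame"]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs (e.g. both masks empty)."""


@dataclass(frozen=True)
class OverlapRecord:
    """One (patient, GTV definition, margin) evaluation row."""

    patient_id: str
    gtv_name: str
    source: str  # "staple" or "individual"
    margin_mm: float
    dsc: float
    coverage: float
    gtv_volume_ml: float
    lesion_volume_ml: float
    observer: str = ""  # set for source == "individual"


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid.isclose(b.grid):
        raise GridMismatchError("metrics require masks on one grid")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient, ``2|a∩b| / (|a|+|b|)``.

    Raises :class:`UndefinedMetricError` when both masks are empty.
    """
    _check_pair(a, b)
    total = a.count + b.count
    if total == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / total


def lesion_coverage(gtv: BinaryMask, lesion: BinaryMask) -> float:
    """Voxel-wise sensitivity ``|gtv ∩ lesion| / |lesion|``.

    Raises :class:`UndefinedMetricError` for an empty lesion.
    """
    _check_pair(gtv, lesion)
    denom = lesion.count
    if denom == 0:
        raise UndefinedMetricError("lesion coverage is undefined for an empty lesion")
    inter = int((gtv.values & lesion.values).sum())
    return inter / denom


def evaluate_case(
    patient: DelineationSet,
    gtvs: dict[str, BinaryMask],
    lesion: BinaryMask,
    margins_mm: list[float],
    sources: dict[str, str] | None = None,
    observers: dict[str, str] | None = None,
) -> list[OverlapRecord]:
    """Evaluate every (GTV, margin) combination for one patient.

    For each named GTV and each margin radius, the GTV is isotropically
    expanded (in physical mm), cropped to the patient's histopathology
    support, and compared with ``lesion`` by DSC and coverage.  ``sources``
    labels each GTV as ``"staple"`` or ``"individual"`` (default: staple);
    ``observers`` attributes individual GTVs to their observer.
    """
    from .alignment import expand_margin  # deferred: alignment imports metrics

    if lesion.count == 0:
        raise UndefinedMetricError("lesion must be nonempty")
    sources = sources or {}
    observers = observers or {}
    lesion_ml = lesion.volume_ml
    records = []
    for name, gtv in gtvs.items():
        source = sources.get(name, "staple")
        for margin in margins_mm:
            ctv = crop_to_support(expand_margin(gtv, margin), patient.histo_support)
            records.append(
                OverlapRecord(
                    patient_id=patient.patient_id,
                    gtv_name=name,
                    source=source,
                    margin_mm=float(margin),
                    dsc=dice(ctv, lesion),
                    coverage=lesion_coverage(ctv, lesion),
                    gtv_volume_ml=ctv.volume_ml,
                    lesion_volume_ml=lesion_ml,
                    observer=observers.get(name, ""),
                )
            )
    return records


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Tidy DataFrame with one row per patient x GTV x margin."""
    return pd.DataFrame.from_records([r.__dict__ for r in records])
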