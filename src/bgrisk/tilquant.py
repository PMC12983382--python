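"""Percentage stromal tumor-infiltrating lymphocytes (%stromal TILs) from annotation masks.

A microscopic field is annotated with three binary masks of equal size: the
tumor stroma, the region occupied by mononuclear inflammatory cells (TILs),
and an exclusion region (granulocyte-rich, ulcerated, crushed or necrotic
areas, which are not evaluable). The field-level measurement is

    %stromal TILs = 100 * area(TIL n stroma \\ exclusion) / area(stroma \\ exclusion)

i.e. the proportion of evaluable stromal area occupied by TILs. TIL pixels
annotated outside the stroma are ignored (the quantity is defined as a
fraction of stroma, and manual annotations overlap imperfectly). A case is
measured on five representative fields and scored as the arithmetic mean of
the five field percentages. Cases are dichotomized at the cohort median, with
values at the cutoff labelled "low".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FieldAnnotation",
    "CaseTILMeasurement",
    "MedianSplit",
    "field_til_percentage",
    "case_til_percentage",
    "dichotomize_by_median",
    "read_mask",
    "write_mask",
    "DEFAULT_FIELDS_PER_CASE",
]

DEFAULT_FIELDS_PER_CASE = 5


@dataclass(frozen=True)
class FieldAnnotation:
    """One microscopic field's stroma / TIL / exclusion masks (same shape).

    Masks are boolean rasters; any nonzero input pixel counts as inside the
    region. ``exclusion_mask`` may be omitted (no excluded area).
    """

    field_id: str
    stroma_mask: np.ndarray
    til_mask: np.ndarray
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        stroma = np.asarray(self.stroma_mask) != 0
        til = np.asarray(self.til_mask) != 0
        excl = (
            np.zeros_like(stroma)
            if self.exclusion_mask is None
            else np.asarray(self.exclusion_mask) != 0
        )
        if not (stroma.shape == til.shape == excl.shape):
            raise ValueError(
                f"field {self.field_id!r}: mask dimensions differ "
                f"({stroma.shape}, {til.shape}, {excl.shape})"
            )
        object.__setattr__(self, "stroma_mask", stroma)
        object.__setattr__(self, "til_mask", til)
        object.__setattr__(self, "exclusion_mask", excl)


@dataclass(frozen=True)
class CaseTILMeasurement:
    case_id: str
    field_percentages: tuple[float, ...]
    case_percentage: float
    til_category: str | None = None  # 'low' / 'high', assigned at cohort level


@dataclass(frozen=True)
class MedianSplit:
    """Cohort median cutoff and the per-case low/high labels it induces."""

    cutoff: float
    labels: tuple[str, ...]


def field_til_percentage(field: FieldAnnotation) -> float:
    """Percentage of evaluable stromal area occupied by TILs, in [0, 100]."""
    effective_stroma = field.stroma_mask & ~field.exclusion_mask
    denom = int(effective_stroma.sum())
    if denom == 0:
        raise ValueError(
            f"field {field.field_id!r}: no evaluable stromal area "
            "(stroma empty or fully excluded)"
        )
    numer = int((field.til_mask & effective_stroma).sum())
    return 100.0 * numer / denom


def case_til_percentage(
    case_id: str,
    fields: Sequence[FieldAnnotation],
    *,
    min_fields: int = DEFAULT_FIELDS_PER_CASE,
) -> CaseTILMeasurement:
    """Average the field percentages of one case's representative fields.

    Exactly ``min_fields`` fields (default 5) are required; pass a smaller
    ``min_fields`` explicitly to accept cases with fewer evaluable fields.
    """
    if len(fields) < min_fields:
        raise ValueError(
            f"case {case_id!r}: {len(fields)} field(s) provided, "
            f"{min_fields} required (set min_fields to override)"
        )
    pcts = tuple(field_til_percentage(f) for f in fields)
    return CaseTILMeasurement(
        case_id=case_id,
        field_percentages=pcts,
        case_percentage=float(np.mean(pcts)),
    )


def dichotomize_by_median(values: Sequence[float]) -> MedianSplit:
    """Split case percentages at the cohort median; ties at the median go low.

    Returns the cutoff (the sample median) and one 'low'/'high' label per
    input value: value <= cutoff -> 'low', value > cutoff -> 'high'.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 cases to dichotomize")
    cutoff = float(np.median(v))
    if np.ptp(v) == 0:
        warnings.warn(
            "all case percentages identical; every case labelled 'low'",
            stacklevel=2,
        )
    labels = tuple("low" if x <= cutoff else "high" for x in v)
    return MedianSplit(cutoff=cutoff, labels=labels)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel PNG/TIFF mask; nonzero pixels are inside."""
    img = iio.imread(path)
    if img.ndim == 3:  # collapse any color/alpha channels
        img = img[..., :3].max(axis=-1)
    return img != 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) != 0).astype(np.uint8) * 255)
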