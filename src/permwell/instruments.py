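"""Scoring of the five mental-wellbeing measurement instruments.

PHQ-9 (depression), GAD-7 (anxiety), BRS (resilience), EQ-5D-5L (health
related quality of life) and EQ-VAS (self-rated health).  PHQ-9, GAD-7 and
EQ-5D-5L totals are item sums; BRS is the item mean after optional
reverse-coding; EQ-VAS is a single 0-100 rating passed through unchanged.
Severity bands follow the conventional published cut-offs.

Two conventions are configurable because the source instruments admit
variants:

* BRS items 2, 4 and 6 are negatively worded and reverse-coded
  (v -> 6 - v) by default; pass ``reverse_items=()`` to score raw items.
* GAD-7 banding defaults to the tabulated ranges 0-5 / 6-10 / 11-15 /
  16-21; ``bands="cutoff"`` switches to the alternative 5/10/15 cut-off
  reading in which a total of 5 is already "mild".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScoredInstrument",
    "score_phq9",
    "score_gad7",
    "score_brs",
    "score_eq5d5l",
    "score_eqvas",
    "validate_scale",
    "PHQ9_BANDS",
    "GAD7_BANDS_TABLE",
    "GAD7_BANDS_CUTOFF",
    "BRS_BANDS",
]


@dataclass(frozen=True)
class ScoredInstrument:
    """An instrument total and its severity band (``None`` if unbanded)."""

    total: float
    band: str | None


# Bands as (lo, hi, label) with closed intervals on the total score.
PHQ9_BANDS = (
    (0, 4, "none"),
    (5, 9, "mild"),
    (10, 14, "moderate"),
    (15, 19, "moderately severe"),
    (20, 27, "severe"),
)

GAD7_BANDS_TABLE = (
    (0, 5, "none"),
    (6, 10, "mild"),
    (11, 15, "moderate"),
    (16, 21, "severe"),
)

GAD7_BANDS_CUTOFF = (
    (0, 4, "none"),
    (5, 9, "mild"),
    (10, 14, "moderate"),
    (15, 21, "severe"),
)

BRS_BANDS = (
    (1.00, 2.99, "low"),
    (3.00, 4.30, "normal"),
    (4.31, 5.00, "high"),
)


def validate_scale(value: float, lo: float, hi: float) -> float:
    """Return ``value`` unchanged if it lies within [lo, hi], else raise."""
    if not (lo <= value <= hi):
        raise ValueError(f"value {value} outside scale [{lo}, {hi}]")
    return value


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValueError(f"{name} requires exactly {n} items, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{name} items must be numeric")
    if np.any((arr < lo) | (arr > hi)) or np.any(arr != np.round(arr)):
        raise ValueError(f"{name} items must be integers in [{lo}, {hi}]")
    return arr.astype(np.int64)


def _band(total: float, bands) -> str:
    for lo, hi, label in bands:
        if lo <= total <= hi:
            return label
    raise ValueError(f"total {total} not covered by band table")  # pragma: no cover


def score_phq9(items: Sequence[int]) -> ScoredInstrument:
    """Sum nine 0-3 depression items; band none/mild/moderate/mod-severe/severe."""
    arr = _check_items(items, 9, 0, 3, "PHQ-9")
    total = int(arr.sum())
    return ScoredInstrument(float(total), _band(total, PHQ9_BANDS))


def score_gad7(items: Sequence[int], bands: str = "table") -> ScoredInstrument:
    """Sum seven 0-3 anxiety items.

    ``bands="table"`` uses the tabulated ranges (0-5 none, 6-10 mild,
    11-15 moderate, 16-21 severe); ``bands="cutoff"`` uses the 5/10/15
    cut-off variant.
    """
    arr = _check_items(items, 7, 0, 3, "GAD-7")
    total = int(arr.sum())
    table = {"table": GAD7_BANDS_TABLE, "cutoff": GAD7_BANDS_CUTOFF}.get(bands)
    if table is None:
        raise ValueError(f"bands must be 'table' or 'cutoff', got {bands!r}")
    return ScoredInstrument(float(total), _band(total, table))


def score_brs(items: Sequence[int], reverse_items: Iterable[int] = (2, 4, 6)) -> ScoredInstrument:
    """Mean of six 1-5 resilience items after reverse-coding.

    ``reverse_items`` gives 1-based positions mapped v -> 6 - v before
    averaging (default: the negatively worded items 2, 4, 6).  Bands:
    mean <= 2.99 low, 3.00-4.30 normal, >= 4.31 high; the item-mean grid
    (multiples of 1/6) never falls between adjacent band edges.
    """
    arr = _check_items(items, 6, 1, 5, "BRS").astype(float)
    for pos in reverse_items:
        if not 1 <= int(pos) <= 6:
            raise ValueError(f"reverse item position {pos} out of range 1..6")
        arr[int(pos) - 1] = 6 - arr[int(pos) - 1]
    total = float(arr.mean())
    if total < 3.0 - 1e-9:
        band = "low"
    elif total <= 4.30 + 1e-9:
        band = "normal"
    else:
        band = "high"
    return ScoredInstrument(total, band)


def score_eq5d5l(items: Sequence[int]) -> ScoredInstrument:
    """Sum of the five 1-5 dimension levels: 5 = best health, 25 = worst."""
    arr = _check_items(items, 5, 1, 5, "EQ-5D-5L")
    return ScoredInstrument(float(arr.sum()), None)


def score_eqvas(value: float) -> ScoredInstrument:
    """Pass through a 0-100 visual-analogue health rating (100 = best)."""
    return ScoredInstrument(float(validate_scale(value, 0, 100)), None)
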