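"""Immunoreactive score (IRS) computation and between-subtype comparison.

The IRS summarizes a stained section as the product of a positive-cell
percentage bin score (1-4) and a staining intensity grade (0-3), giving a
score in 0..12.  Group comparison between RMPA-high and RMPA-low tumors
uses an unpaired two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

MARKERS = ("p-ERK", "p-AKT")

#: percentage bins: <10% -> 1, 10-50% -> 2, 51-80% -> 3, >80% -> 4.
#: The printed bins leave (0.50, 0.51) undefined; fractions there map to the
#: upper bin (score 3) by convention.
_BIN_EDGES = (0.10, 0.50, 0.80)


def percentage_score(positive_fraction: float) -> int:
    """Bin the fraction of positively stained cells into score 1..4."""
    f = float(positive_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"positive fraction must be in [0,1], got {f}")
    if f < _BIN_EDGES[0]:
        return 1
    if f <= _BIN_EDGES[1]:
        return 2
    if f <= _BIN_EDGES[2]:
        return 3
    return 4


def irs(percentage_score: int, intensity_grade: int) -> int:
    """IRS = percentage score (1-4) x intensity grade (0-3), range 0-12."""
    p, i = int(percentage_score), int(intensity_grade)
    if p not in (1, 2, 3, 4):
        raise ValueError(f"percentage score must be in 1..4, got {p}")
    if i not in (0, 1, 2, 3):
        raise ValueError(f"intensity grade must be in 0..3, got {i}")
    return p * i


def irs_from_staining(positive_fraction: float, intensity_grade: int) -> int:
    """Convenience: score a section directly from its staining readouts."""
    return irs(percentage_score(positive_fraction), intensity_grade)


@dataclass
class IRSComparison:
    mean_high: float
    mean_low: float
    t_statistic: float
    p_value: float
    n_high: int
    n_low: int
    degenerate: bool = False


def compare_irs(
    group_high: Sequence[float],
    group_low: Sequence[float],
    welch: bool = False,
) -> IRSComparison:
    """Unpaired two-sample t test of IRS values between subtypes.

    Pooled-variance (Student) by default; ``welch=True`` drops the
    equal-variance assumption.  Zero pooled variance with equal means gives
    t=0, p=1; with unequal means the result is flagged degenerate.
    """
    a = np.asarray(group_high, dtype=float)
    b = np.asarray(group_low, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return IRSComparison(a.mean(), b.mean(), 0.0, 1.0, len(a), len(b))
        return IRSComparison(
            a.mean(), b.mean(), np.inf, 0.0, len(a), len(b), degenerate=True
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return IRSComparison(a.mean(), b.mean(), float(t), float(p), len(a), len(b))
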