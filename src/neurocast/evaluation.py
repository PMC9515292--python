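"""Descriptive statistics for model assessment: cutoff splits, same-side
agreement, group range summaries and mean confidence bands.

A score counts as *normal* when it lies on the healthy side of its test's
cutoff, boundary included (MMSE >= 28; ADAS Q4 <= 5; ADAS Cog-11 <= 10;
ADAS Cog-13 <= 13; FAQ <= 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curation import TestSpec


def cutoff_split_percentages(
    scores, groups, spec: TestSpec
) -> dict[str, tuple[float, float]]:
    """Per-group (percent_normal, percent_abnormal) split at the cutoff.

    Empty groups are omitted with a warning. Exact percentages are
    returned; round for display.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if scores.shape != groups.shape:
        raise ValueError("scores and groups must align")
    out: dict[str, tuple[float, float]] = {}
    for g in dict.fromkeys(groups):  # preserves first-seen order
        vals = scores[groups == g]
        if vals.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        normal = 100.0 * spec.is_normal(vals).mean()
        out[str(g)] = (normal, 100.0 - normal)
    return out


def same_side_percentage(actual, predicted, spec: TestSpec) -> float:
    """Percent of pairs where actual and predicted scores fall on the same
    side of the cutoff (boundary counts as normal)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if a.size == 0:
        raise ValueError("empty input")
    agree = spec.is_normal(a) == spec.is_normal(p)
    return 100.0 * float(agree.mean())


@dataclass
class GroupSummary:
    group: str
    n: int
    min: float
    max: float
    mean: float
    q25: float
    median: float
    q75: float


def group_range_stats(scores, groups) -> list[GroupSummary]:
    """Boxplot-style summaries per group (linear-interpolation quartiles)."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if scores.size == 0:
        raise ValueError("empty input")
    out = []
    for g in dict.fromkeys(groups):
        vals = scores[groups == g]
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
        out.append(
            GroupSummary(
                str(g),
                int(vals.size),
                float(vals.min()),
                float(vals.max()),
                float(vals.mean()),
                float(q25),
                float(med),
                float(q75),
            )
        )
    return out


def mean_confidence_band(
    values_by_visit: dict[int, "np.ndarray"], level: float = 0.95
) -> dict[int, tuple[float, float, float]]:
    """Student-t mean confidence interval per visit month.

    Returns month -> (mean, lower, upper); requires at least two values
    per month.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    out: dict[int, tuple[float, float, float]] = {}
    for month, vals in values_by_visit.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"month {month}: need >= 2 values for an interval")
        m = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(v.size))
        t = float(stats.t.ppf(0.5 + level / 2.0, df=v.size - 1))
        out[int(month)] = (m, m - t * se, m + t * se)
    return out
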