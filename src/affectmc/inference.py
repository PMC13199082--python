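"""Association and group-difference statistics for the valence analysis.

Covers the chi-square screen of response quality against the next
emotional state, per-dimension Welch t-tests with Cohen's d for the two
stability groups, the Mann-Whitney comparison of component scores, and
the relative-improvement identity used for classifier accuracies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EmotionState, QualityLevel, StabilityGroup, TransitionData
from .grouping import DIMENSIONS, ScaleResponse


@dataclass
class ContingencyTable:
    """Labelled non-negative count table (at least 2x2)."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("grand total must be >= 1")

    @classmethod
    def from_transitions(cls, data: TransitionData) -> "ContingencyTable":
        """Quality x next-state table from extracted transitions."""
        counts = np.zeros((len(QualityLevel), len(EmotionState)))
        for rec in data.records:
            counts[int(rec.quality), int(rec.next)] += 1
        return cls(
            counts=counts,
            row_labels=[q.label for q in QualityLevel],
            col_labels=[s.label for s in EmotionState],
        )


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(statistic, df, p)`` with df = (r-1)(c-1).  A zero row or
    column marginal makes the expected counts degenerate and raises.
    """
    counts = table.counts
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    if np.any(row_m == 0):
        bad = table.row_labels[int(np.argmin(row_m))]
        raise ValueError(f"zero row marginal for {bad!r}")
    if np.any(col_m == 0):
        bad = table.col_labels[int(np.argmin(col_m))]
        raise ValueError(f"zero column marginal for {bad!r}")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardised mean difference with the equal-weight pooled SD.

    ``|mean2 - mean1| / sqrt((sd1^2 + sd2^2) / 2)`` — the pooling that
    reproduces the study's printed cluster effect sizes from summary
    statistics alone.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean2 - mean1) / math.sqrt(0.5 * (sd1**2 + sd2**2))


def group_dimension_tests(
    responses: Sequence[ScaleResponse],
    labels: Mapping[str, StabilityGroup],
    welch: bool = True,
) -> pd.DataFrame:
    """Per-dimension (and total) two-group comparison table.

    One row per scale dimension plus the total score, in the canonical
    reporting order: group means +- SDs, the two-sample t (Welch by
    default), its p-value and Cohen's d.  A group of size one leaves the
    t undefined and flags the row.
    """
    low = [r for r in responses if labels[r.participant_id] is StabilityGroup.LOW]
    high = [r for r in responses if labels[r.participant_id] is StabilityGroup.HIGH]
    if not low or not high:
        raise ValueError("both stability groups must be nonempty")

    def values(group, key):
        if key == "total":
            return np.array([r.total for r in group])
        return np.array([r.dims[key] for r in group])

    rows = []
    for key in ("total",) + DIMENSIONS:
        x, y = values(low, key), values(high, key)
        m1, m2 = x.mean(), y.mean()
        s1 = x.std(ddof=1) if x.size > 1 else np.nan
        s2 = y.std(ddof=1) if y.size > 1 else np.nan
        flagged = x.size < 2 or y.size < 2
        if flagged:
            t = p = d = np.nan
        elif s1 == 0 and s2 == 0 and m1 == m2:
            # degenerate but well-defined null: no variation, no difference
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=not welch)
            if s1 > 0 and s2 > 0:
                d = cohens_d(m1, s1, m2, s2)
            elif m1 == m2:
                d = 0.0
            else:
                d = np.nan
                flagged = True
        rows.append({
            "dimension": key,
            "low_mean": m1, "low_sd": s1, "high_mean": m2, "high_sd": s2,
            "t": float(t) if not flagged else np.nan,
            "p": float(p) if not flagged else np.nan,
            "cohens_d": d, "flagged": flagged,
        })
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney rank-sum test.

    Returns the conventional ``U`` (the smaller of U_x and U_y) and the
    two-sided p-value from the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u_x, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    u = min(float(u_x), x.size * y.size - float(u_x))
    return u, float(p)


def relative_improvement(baseline: float, final: float) -> float:
    """Percent change of ``final`` relative to ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return (final - baseline) / baseline * 100.0
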