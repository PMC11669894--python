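"""Group comparisons: asymptotic Wilcoxon-Mann-Whitney tests and summaries.

The two-sample comparison used throughout is the rank-sum test in its
normal-approximation ("asymptotic") form with tie-corrected variance and no
continuity correction; significance bands follow the conventional
* p <= 0.05, ** p <= 0.01, *** p <= 0.001 annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


def significance_band(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Result of one two-sample rank comparison."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    u_statistic: float  # U for group a
    z_value: float
    p_value: float
    median_a: float
    median_b: float
    tied: bool = False

    @property
    def band(self) -> str:
        return significance_band(self.p_value)


def mann_whitney_asymptotic(
    a: Sequence[float],
    b: Sequence[float],
    name_a: str = "a",
    name_b: str = "b",
    continuity: bool = False,
) -> GroupComparison:
    """Two-sided asymptotic Mann-Whitney U test.

    U is computed from midranks; the normal approximation uses the
    tie-corrected variance

        var(U) = n_a n_b / 12 * [(n + 1) - sum(t^3 - t) / (n (n - 1))]

    over tie groups of size t. Continuity correction is off by default. If
    every value across both groups is tied the statistic is degenerate and
    p = 1 is returned with a warning.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n_a, n_b = len(x), len(y)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    mean_u = n_a * n_b / 2.0
    if n > 1:
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var_u = 0.0
    tied = False
    if var_u <= 0:
        tied = True
        warnings.warn("all values tied across both groups; p set to 1", stacklevel=2)
        z = 0.0
        p = 1.0
    else:
        diff = u_a - mean_u
        if continuity:
            diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var_u)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return GroupComparison(
        name_a=name_a,
        name_b=name_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=float(u_a),
        z_value=float(z),
        p_value=p,
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        tied=tied,
    )


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> float:
    """Exhaustive-enumeration two-sided p (small samples; testing oracle).

    Enumerates all labelings of the pooled sample and counts |U - mean(U)|
    at least as extreme as observed. Intended for n_a, n_b <= ~8.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n_a = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mean_u = n_a * len(y) / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

    observed = abs(u_of(tuple(range(n_a))) - mean_u)
    total = 0
    extreme = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(idx) - mean_u) >= observed - 1e-12:
            extreme += 1
    return extreme / total


@dataclass
class ClassSummary:
    label: str
    n: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]


def group_property_summary(
    values: Mapping[str, Sequence[float]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[dict[str, ClassSummary], list[GroupComparison]]:
    """Per-class median/IQR plus pairwise rank tests.

    Quantiles use linear interpolation (numpy default, "type 7"). Empty
    classes are reported with n = 0 and excluded from the tests. ``pairs``
    restricts which class pairs are compared (default: all).
    """
    if not any(len(v) for v in values.values()):
        raise ValueError("at least one class must be non-empty")
    summaries: dict[str, ClassSummary] = {}
    for label, sample in values.items():
        arr = np.asarray(sample, dtype=float)
        if arr.size == 0:
            summaries[label] = ClassSummary(label, 0, None, None, None)
        else:
            q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
            summaries[label] = ClassSummary(label, arr.size, float(med), float(q1), float(q3))
    labels = [l for l in values if summaries[l].n > 0]
    wanted = pairs if pairs is not None else list(combinations(labels, 2))
    comparisons = []
    for la, lb in wanted:
        if summaries[la].n == 0 or summaries[lb].n == 0:
            logger.info("skipping comparison %s vs %s: empty class", la, lb)
            continue
        comparisons.append(
            mann_whitney_asymptotic(values[la], values[lb], name_a=la, name_b=lb)
        )
    return summaries, comparisons


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.name_a,
                "group_b": c.name_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.u_statistic,
                "z": round(c.z_value, 4),
                "p": c.p_value,
                "band": c.band,
                "median_a": c.median_a,
                "median_b": c.median_b,
            }
            for c in comparisons
        ]
    )


def long_format(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Plot-ready long-format table of (class, value) rows."""
    rows = [
        {"class": label, "value": float(v)}
        for label, sample in values.items()
        for v in sample
    ]
    return pd.DataFrame(rows)
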