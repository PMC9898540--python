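"""Group comparisons and clonal diversity.

Two-group comparisons use the one-tailed two-sample unequal-variance
(Welch) t-test with the mouse as the unit of replication; significance is
tagged ``*`` for p <= 0.05 and ``**`` for p < 0.01.  The direction of the
one-tailed alternative is always an explicit argument — inferring it from
the data would invalidate the one-tailed p value.  No multiple-testing
correction is applied; reports carry the number of tests run instead.

Clonal diversity is the Shannon index H = -sum p_i ln p_i over each clone's
share of one (mouse, cell type, time point) sample, in nats by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ClonalAbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "welch_t_one_tailed",
    "shannon_index",
    "diversity_table",
    "compare_groups",
    "GroupComparison",
    "per_mouse_total_abundance",
]


def welch_t_one_tailed(a, b, alternative: str) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, one-tailed.

    ``alternative="greater"`` tests mean(a) > mean(b); ``"less"`` tests
    mean(a) < mean(b).  Returns (t, Welch-Satterthwaite df, one-tailed p).
    Both groups need n >= 2; when both variances are zero and the means are
    equal, p = 0.5 by convention (with a warning).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 values (got {na} and {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; p = 0.5 by convention")
            return 0.0, float(na + nb - 2), 0.5
        raise ValueError("zero variance in both groups with unequal means: t is undefined")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = sps.t.sf(t, df) if alternative == "greater" else sps.t.cdf(t, df)
    return float(t), float(df), float(p)


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon diversity of one sample's clone abundances.

    H = -sum p_i log p_i over p_i = a_i / sum(a), natural log by default.
    Invariant to rescaling; maximal (log k) for k equal clones.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("no detected clones")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum()) + 0.0  # normalize -0.0 for single clones
    if base is not None:
        h /= math.log(base)
    return h


def diversity_table(matrix: ClonalAbundanceMatrix, base: float | None = None) -> pd.DataFrame:
    """Shannon index per (mouse, cell type, time point).

    Samples with no detected clone are skipped with a warning rather than
    raising: late time points can legitimately drop out.
    """
    rows = []
    for mouse in matrix.mice:
        block = matrix.for_mouse(mouse)
        for cell_type, timepoint in block.columns:
            values = block[(cell_type, timepoint)].to_numpy()
            if values.sum() == 0:
                logger.warning("sample %s:%s:%g empty; Shannon index skipped", mouse, cell_type, timepoint)
                continue
            rows.append(
                {
                    "mouse": mouse,
                    "group": matrix.groups[mouse],
                    "cell_type": cell_type,
                    "timepoint": timepoint,
                    "shannon_index": shannon_index(values, base=base),
                    "n_detected": int((values > 0).sum()),
                }
            )
    return pd.DataFrame(rows, columns=["mouse", "group", "cell_type", "timepoint", "shannon_index", "n_detected"])


@dataclass
class GroupComparison:
    """One two-group test: per-group summaries, Welch statistics and the tag."""

    metric: str
    group_a: str
    group_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    alternative: str
    t: float
    df: float
    p: float

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b))

    @property
    def sem_a(self) -> float:
        return float(np.std(self.values_a, ddof=1) / math.sqrt(len(self.values_a)))

    @property
    def sem_b(self) -> float:
        return float(np.std(self.values_b, ddof=1) / math.sqrt(len(self.values_b)))

    @property
    def significance(self) -> str:
        if self.p < 0.01:
            return "**"
        if self.p <= 0.05:
            return "*"
        return ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": self.metric,
                    "group_a": self.group_a,
                    "group_b": self.group_b,
                    "n_a": len(self.values_a),
                    "n_b": len(self.values_b),
                    "mean_a": self.mean_a,
                    "sem_a": self.sem_a,
                    "mean_b": self.mean_b,
                    "sem_b": self.sem_b,
                    "alternative": self.alternative,
                    "t": self.t,
                    "df": self.df,
                    "p_one_tailed": self.p,
                    "significance": self.significance,
                }
            ]
        )

    def summary(self) -> str:
        return (
            f"{self.metric}: {self.group_a} {self.mean_a:.4g} ± {self.sem_a:.4g} (n={len(self.values_a)}) vs "
            f"{self.group_b} {self.mean_b:.4g} ± {self.sem_b:.4g} (n={len(self.values_b)}); "
            f"one-tailed Welch t={self.t:.3f}, df={self.df:.2f}, p={self.p:.4g} {self.significance}"
        )


def compare_groups(
    per_mouse: pd.DataFrame,
    metric: str,
    alternative: str,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Welch-test a per-mouse metric between two groups.

    ``per_mouse`` needs columns ``mouse``, ``group`` and ``value`` — one row
    per mouse, so mice (not clones) are the replicates.
    ``alternative="greater"`` tests group_a > group_b.
    """
    values = {}
    for g in (group_a, group_b):
        v = per_mouse.loc[per_mouse["group"] == g, "value"].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {g!r} has {len(v)} mice; need >= 2")
        values[g] = v
    try:
        t, df, p = welch_t_one_tailed(values[group_a], values[group_b], alternative)
    except ValueError:
        raise
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        values_a=values[group_a],
        values_b=values[group_b],
        alternative=alternative,
        t=t,
        df=df,
        p=p,
    )


def per_mouse_total_abundance(
    matrix: ClonalAbundanceMatrix, cell_type: str, timepoint: float
) -> pd.DataFrame:
    """Summed clonal %WBC abundance of one sample per mouse, ready for
    :func:`compare_groups` (columns mouse, group, value)."""
    sums = matrix.abundance[(cell_type, timepoint)].groupby(level="mouse").sum()
    return pd.DataFrame(
        {"mouse": sums.index, "group": [matrix.groups[m] for m in sums.index], "value": sums.to_numpy()}
    )
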