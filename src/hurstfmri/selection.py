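"""Per-fold discriminative feature selection: t-test filter + Fisher score.

The retention filter is a two-sample two-tailed Student t-test at an
uncorrected significance level (default 0.05); the Fisher score

    FS = (n1 (m1 - m)^2 + n2 (m2 - m)^2) / (n1 s1^2 + n2 s2^2)

ranks and documents the retained features (group variances s_k^2 use the
population convention, matching the n_k-weighted denominator).  Selection
must only ever see training-fold rows; the cross-validation driver passes a
fold view and this module never touches anything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateFeatureError,
    InvalidInputError,
)

__all__ = [
    "GroupStats",
    "SelectionResult",
    "group_stats",
    "fisher_score",
    "two_sample_t",
    "select_features",
]


@dataclass(frozen=True)
class GroupStats:
    """Per-group first and second moments of one feature."""

    n1: int
    n2: int
    m1: float
    m2: float
    m: float  # pooled mean over both groups
    var1: float  # population variances (divide by n_k)
    var2: float


@dataclass
class SelectionResult:
    """Outcome of one training-fold selection pass.

    ``retained`` holds the indices with p < alpha ordered by descending
    Fisher score (ties broken by ascending index).  When nothing passes,
    ``retained`` is empty and ``empty_selection`` is set; the CV driver
    falls back to the single best-scoring feature.
    """

    retained: list[int]
    p_values: np.ndarray
    fisher_scores: np.ndarray
    alpha: float
    empty_selection: bool = False


def _split(feature: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(feature, dtype=float)
    g = np.asarray(groups)
    if g.dtype != bool:
        g = g == "MCI"
    if x.shape[0] != g.shape[0]:
        raise InvalidInputError("feature and group labels differ in length")
    x1, x2 = x[g], x[~g]
    if len(x1) < 2 or len(x2) < 2:
        raise InvalidInputError("each group needs at least 2 members")
    return x1, x2


def group_stats(feature: np.ndarray, groups) -> GroupStats:
    """Group means/variances and pooled mean of one feature.

    ``groups`` is boolean (True = first group) or string labels where
    "MCI" marks the first group.
    """
    x1, x2 = _split(feature, groups)
    return GroupStats(
        n1=len(x1),
        n2=len(x2),
        m1=float(x1.mean()),
        m2=float(x2.mean()),
        m=float(np.concatenate([x1, x2]).mean()),
        var1=float(x1.var()),
        var2=float(x2.var()),
    )


def fisher_score(stats_: GroupStats) -> float:
    """Between-group over within-group variance ratio of one feature."""
    denom = stats_.n1 * stats_.var1 + stats_.n2 * stats_.var2
    if denom <= 0:
        raise DegenerateFeatureError(
            "both groups are constant; Fisher score undefined"
        )
    num = stats_.n1 * (stats_.m1 - stats_.m) ** 2 + stats_.n2 * (stats_.m2 - stats_.m) ** 2
    return float(num / denom)


def two_sample_t(feature: np.ndarray, groups) -> tuple[float, float]:
    """Pooled-variance Student t and two-tailed p (df = n1 + n2 - 2).

    Degenerate dispersion: zero pooled variance with equal means gives
    (0, 1); with unequal means the statistic is infinite and p = 0.
    """
    x1, x2 = _split(feature, groups)
    n1, n2 = len(x1), len(x2)
    df = n1 + n2 - 2
    ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    diff = x1.mean() - x2.mean()
    if ss == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def select_features(
    values: np.ndarray, groups, alpha: float = 0.05
) -> SelectionResult:
    """t-test filter (p < alpha, uncorrected) with Fisher-score ranking.

    ``values`` is a (training subjects x features) matrix.  Features whose
    Fisher denominator is zero get score 0 when group means agree and +inf
    otherwise (perfectly separating constant groups).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("expected a 2D (subjects x features) matrix")
    n_feat = x.shape[1]
    p = np.empty(n_feat)
    fs = np.empty(n_feat)
    for j in range(n_feat):
        st = group_stats(x[:, j], groups)
        _, p[j] = two_sample_t(x[:, j], groups)
        try:
            fs[j] = fisher_score(st)
        except DegenerateFeatureError:
            fs[j] = 0.0 if st.m1 == st.m2 else np.inf
    passing = np.nonzero(p < alpha)[0]
    # order by descending score, ties by ascending index
    order = passing[np.lexsort((passing, -fs[passing]))]
    return SelectionResult(
        retained=order.tolist(),
        p_values=p,
        fisher_scores=fs,
        alpha=alpha,
        empty_selection=len(order) == 0,
    )
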