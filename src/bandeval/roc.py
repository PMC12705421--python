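"""AUROC estimation and paired comparison (DeLong) for score evaluation.

The AUROC is estimated by the Mann–Whitney statistic with mid-rank tie
correction: the probability that a random positive outscores a random
negative, counting ties as one half.  Variance estimation and the paired
two-score comparison use DeLong's structural-components method: each
patient contributes a placement value (the fraction of the opposite class
it outranks), and the covariance of the two scores' placements gives the
variance of the AUROC difference.  Because only ranks enter, both the
AUROC and the test are invariant under strictly monotone transforms of
either score.

Subgroup comparisons (e.g. immunosuppressed versus immunocompetent) use a
stratified bootstrap: patients are resampled within group and class, and
the two-sided p-value is read off the bootstrap distribution of the AUROC
difference.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

DEFAULT_CI_LEVEL = 0.80


@dataclasses.dataclass(frozen=True)
class RocResult:
    """AUROC point estimate with a normal-approximation CI."""

    auroc: float
    ci: Tuple[float, float]
    level: float
    n_pos: int
    n_neg: int


def _validate_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        uniq = set(np.unique(y).tolist())
        if not uniq <= {0, 1, False, True}:
            raise ValueError(f"labels must be binary, got values {sorted(uniq)}")
        y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _placements(scores: np.ndarray, y: np.ndarray):
    """Mid-rank placement values V10 (per positive) and V01 (per negative).

    V10[i] = fraction of negatives outranked by positive i (ties half);
    V01[j] = fraction of positives outranked *below* negative j, oriented
    so that mean(V10) = mean(V01) = AUROC.
    """
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01


def auroc(scores, labels, level: float = DEFAULT_CI_LEVEL) -> RocResult:
    """AUROC with a DeLong-variance confidence interval.

    ``auroc = P(score_pos > score_neg) + ½·P(tie)`` computed by mid-ranks;
    the CI is the normal interval on the DeLong variance, clipped to
    [0, 1].
    """
    y = _validate_binary(labels)
    x = np.asarray(scores, float)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    v10, v01 = _placements(x, y)
    a = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return RocResult(
        auroc=a,
        ci=(max(0.0, a - half), min(1.0, a + half)),
        level=level,
        n_pos=m,
        n_neg=n,
    )


@dataclasses.dataclass(frozen=True)
class DeLongResult:
    auroc_a: float
    auroc_b: float
    difference: float
    se: float
    p_value: float


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test for two paired AUROCs on the same patients.

    Returns the two AUROCs, their difference (a − b), its standard error
    from the structural-components covariance, and the two-sided normal
    p-value.  Identical score vectors give difference 0 and p = 1.
    """
    y = _validate_binary(labels)
    xa = np.asarray(scores_a, float)
    xb = np.asarray(scores_b, float)
    if xa.shape != y.shape or xb.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be equal length "
                         "(paired input)")
    va10, va01 = _placements(xa, y)
    vb10, vb01 = _placements(xb, y)
    a_a, a_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)

    def cov(u, v):
        if len(u) < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    var = (
        (cov(va10, va10) + cov(vb10, vb10) - 2 * cov(va10, vb10)) / m
        + (cov(va01, va01) + cov(vb01, vb01) - 2 * cov(va01, vb01)) / n
    )
    diff = a_a - a_b
    if var <= 0:
        # degenerate (e.g. identical scores): no evidence of a difference
        se = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        se = math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(diff) / se))
        p = min(p, 1.0)
    return DeLongResult(a_a, a_b, diff, se, p)


def subgroup_auroc(
    scores,
    labels,
    groups,
    level: float = DEFAULT_CI_LEVEL,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, RocResult], Dict[Tuple[str, str], float]]:
    """Per-group AUROC plus stratified-bootstrap between-group p-values.

    Groups with a single class are skipped with a warning.  For each pair
    of eligible groups the bootstrap resamples patients within (group,
    class) strata and reports a two-sided p-value for a zero AUROC
    difference.  Returns ``(per_group, pairwise_p)``.
    """
    x = np.asarray(scores, float)
    y = _validate_binary(labels)
    g = np.asarray(groups)
    rng = np.random.default_rng(seed)
    per_group: Dict[str, RocResult] = {}
    eligible = []
    for name in pd_unique(g):
        sel = g == name
        ysel = y[sel]
        if ysel.all() or not ysel.any():
            warnings.warn(
                f"group {name!r} has a single class; skipped", stacklevel=2
            )
            continue
        per_group[str(name)] = auroc(x[sel], ysel, level)
        eligible.append(name)

    pairwise: Dict[Tuple[str, str], float] = {}
    for i, ga in enumerate(eligible):
        for gb in eligible[i + 1:]:
            diffs = np.empty(n_boot)
            idx_a_pos = np.flatnonzero((g == ga) & y)
            idx_a_neg = np.flatnonzero((g == ga) & ~y)
            idx_b_pos = np.flatnonzero((g == gb) & y)
            idx_b_neg = np.flatnonzero((g == gb) & ~y)
            for k in range(n_boot):
                sa = np.concatenate(
                    [rng.choice(idx_a_pos, len(idx_a_pos)),
                     rng.choice(idx_a_neg, len(idx_a_neg))]
                )
                sb = np.concatenate(
                    [rng.choice(idx_b_pos, len(idx_b_pos)),
                     rng.choice(idx_b_neg, len(idx_b_neg))]
                )
                aa = _fast_auc(x[sa], np.concatenate(
                    [np.ones(len(idx_a_pos), bool),
                     np.zeros(len(idx_a_neg), bool)]))
                ab = _fast_auc(x[sb], np.concatenate(
                    [np.ones(len(idx_b_pos), bool),
                     np.zeros(len(idx_b_neg), bool)]))
                diffs[k] = aa - ab
            # two-sided bootstrap p for H0: equal AUROCs
            prop = min((diffs <= 0).mean(), (diffs >= 0).mean())
            pairwise[(str(ga), str(gb))] = float(
                min(1.0, 2 * (prop + 1 / n_boot))
            )
    return per_group, pairwise


def _fast_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    m = int(y.sum())
    n = len(y) - m
    return (ranks[y].sum() - m * (m + 1) / 2) / (m * n)


def pd_unique(arr):
    """Order-preserving unique (first appearance)."""
    seen = []
    for v in arr:
        if v not in seen:
            seen.append(v)
    return seen
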