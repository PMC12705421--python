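"""Likelihood-ratio Bayesian updating and treatment-threshold analysis.

Post-test probability follows the odds form of Bayes' theorem: with
pre-test probability *p* and band likelihood ratio *LR*,

    post = LR·p / (LR·p + 1 − p)

Evaluated at the cohort prevalence with a band's stratum-specific LR this
reproduces the band's predictive value exactly (odds algebra), which ties
the nomogram to the contingency table.

Treatment thresholds come from surveyed clinician decision points: 69%
probability of bacterial infection to start antibiotics overall, 55% under
high illness severity, 84% under low severity.  Threshold crossings are
reported on a pre-test probability grid (default 0 to 1 in 0.1 steps),
matching the binned presentation clinicians would use, not by
root-finding.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclasses.dataclass(frozen=True)
class ThresholdPolicy:
    """Treat/no-treat probability thresholds.

    ``treat_threshold`` is the overall antibiotic-initiation threshold;
    the severity-conditional variants reflect that clinicians accept a
    lower threshold when illness is severe.
    """

    treat_threshold: float = 0.69
    high_severity_threshold: float = 0.55
    low_severity_threshold: float = 0.84

    def __post_init__(self):
        for name in dataclasses.fields(self):
            v = getattr(self, name.name)
            if not 0 < v < 1:
                raise ValueError(f"{name.name} must be in (0, 1), got {v}")


def post_test_probability(pre, lr):
    """Odds-form Bayesian update; exact under ``fractions.Fraction`` inputs.

    ``post = lr·pre / (lr·pre + 1 − pre)``; maps 0→0 and 1→1 for any
    positive likelihood ratio, and is the identity when ``lr == 1``.
    """
    if not 0 <= pre <= 1:
        raise ValueError(f"pre-test probability must be in [0, 1], got {pre}")
    if lr < 0:
        raise ValueError(f"likelihood ratio must be ≥ 0, got {lr}")
    num = lr * pre
    return num / (num + (1 - pre))


def threshold_crossing(
    lr: float,
    policy: ThresholdPolicy | float = ThresholdPolicy(),
    grid: Sequence[float] = DEFAULT_GRID,
    direction: str = "auto",
) -> Optional[float]:
    """Grid pre-test probability at which the post-test crosses the threshold.

    For rule-in likelihood ratios (LR ≥ 1) this is the smallest grid
    pre-test probability whose post-test probability reaches the
    threshold; for rule-out LRs (< 1) the largest grid value kept strictly
    below it.  ``direction`` may force ``"rule_in"``/``"rule_out"``.
    Returns ``None`` when the threshold is never crossed on the grid.
    """
    threshold = (
        policy.treat_threshold if isinstance(policy, ThresholdPolicy) else policy
    )
    grid = list(grid)
    if not grid:
        raise ValueError("empty pre-test probability grid")
    if sorted(grid) != grid or grid[0] < 0 or grid[-1] > 1:
        raise ValueError("grid must be sorted within [0, 1]")
    if direction == "auto":
        direction = "rule_in" if lr >= 1 else "rule_out"
    posts = [post_test_probability(p, lr) for p in grid]
    if direction == "rule_in":
        for pre, post in zip(grid, posts):
            if post >= threshold:
                return pre
        return None
    if direction == "rule_out":
        below = [pre for pre, post in zip(grid, posts) if post < threshold]
        return max(below) if below else None
    raise ValueError(f"unknown direction {direction!r}")


def post_test_matrix(
    band_lrs: Sequence[float],
    grid: Sequence[float] = DEFAULT_GRID,
    band_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Grid × band table of post-test probabilities.

    Rows are pre-test probabilities, one column per band likelihood ratio
    (any number of bands; five for the standard nomogram).  The matrix is
    non-decreasing along rows (in LR order) and down columns.
    """
    lrs = np.asarray(list(band_lrs), float)
    if not np.isfinite(lrs).all():
        raise ValueError("band likelihood ratios must be finite")
    if band_names is None:
        band_names = [f"lr={lr:g}" for lr in lrs]
    rows = {
        name: [post_test_probability(p, lr) for p in grid]
        for name, lr in zip(band_names, lrs)
    }
    out = pd.DataFrame(rows, index=pd.Index(list(grid), name="pre_test"))
    return out
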