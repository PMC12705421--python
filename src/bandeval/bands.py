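"""Interpretation bands for 0–50 triage scores.

A score in [0, 50] maps to one of five ordered interpretation bands
(Very Low < Low < Moderate < High < Very High).  The two highest bands are
read clinically as "rule-in", the two lowest as "rule-out"; Moderate is not
actionable.

Two boundary conventions exist for the upper three bands and are both
exposed here:

* ``"table"`` (default): Moderate 21–29, High 30–39, Very High 40–50 —
  the convention under which all quantitative results in this package are
  reported.
* ``"prose"``: Moderate 21–30, High 31–40, Very High 41–50.

The conventions agree on Very Low (0–10) and Low (11–20).
"""

from __future__ import annotations

import enum
from typing import Mapping, Tuple


class Band(enum.IntEnum):
    """Ordered interpretation band; integer value gives the ordering."""

    VERY_LOW = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3
    VERY_HIGH = 4

    def __str__(self) -> str:  # "Very High" etc., as printed in reports
        return _LABELS[self]


_LABELS = {
    Band.VERY_LOW: "Very Low",
    Band.LOW: "Low",
    Band.MODERATE: "Moderate",
    Band.HIGH: "High",
    Band.VERY_HIGH: "Very High",
}

#: Bands ordered from lowest to highest score.
BANDS_ASCENDING: Tuple[Band, ...] = (
    Band.VERY_LOW,
    Band.LOW,
    Band.MODERATE,
    Band.HIGH,
    Band.VERY_HIGH,
)

#: Bands ordered as table rows are printed (highest first).
BANDS_DESCENDING: Tuple[Band, ...] = tuple(reversed(BANDS_ASCENDING))

#: Inclusive (low, high) score intervals per convention.
BAND_INTERVALS: Mapping[str, Mapping[Band, Tuple[int, int]]] = {
    "table": {
        Band.VERY_LOW: (0, 10),
        Band.LOW: (11, 20),
        Band.MODERATE: (21, 29),
        Band.HIGH: (30, 39),
        Band.VERY_HIGH: (40, 50),
    },
    "prose": {
        Band.VERY_LOW: (0, 10),
        Band.LOW: (11, 20),
        Band.MODERATE: (21, 30),
        Band.HIGH: (31, 40),
        Band.VERY_HIGH: (41, 50),
    },
}

#: Clinically actionable bands (rule-in or rule-out; everything but Moderate).
ACTIONABLE_BANDS = frozenset(
    {Band.VERY_LOW, Band.LOW, Band.HIGH, Band.VERY_HIGH}
)

SCORE_MIN, SCORE_MAX = 0, 50


def band_interval(band: Band, convention: str = "table") -> Tuple[int, int]:
    """Inclusive integer score interval of *band* under *convention*."""
    try:
        return BAND_INTERVALS[convention][band]
    except KeyError:
        raise ValueError(
            f"unknown band convention {convention!r}; "
            f"expected one of {sorted(BAND_INTERVALS)}"
        ) from None


def assign_band(score: int, convention: str = "table") -> Band:
    """Map an integer score in [0, 50] to its interpretation band.

    Raises ``ValueError`` for non-integer or out-of-range scores.
    """
    if isinstance(score, bool) or int(score) != score:
        raise ValueError(f"score must be an integer, got {score!r}")
    score = int(score)
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(
            f"score {score} outside the [{SCORE_MIN}, {SCORE_MAX}] range"
        )
    for band, (lo, hi) in BAND_INTERVALS[
        convention if convention in BAND_INTERVALS else _bad(convention)
    ].items():
        if lo <= score <= hi:
            return band
    raise AssertionError("unreachable: intervals partition [0, 50]")


def _bad(convention: str):
    raise ValueError(
        f"unknown band convention {convention!r}; "
        f"expected one of {sorted(BAND_INTERVALS)}"
    )


def assign_bands(scores, convention: str = "table"):
    """Vectorised :func:`assign_band` for a sequence/array of scores.

    Returns a numpy array of :class:`Band` ordinals (``Band.value``).
    """
    import numpy as np

    arr = np.asarray(scores)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flt = arr.astype(float)
        if not np.all(flt == np.floor(flt)):
            raise ValueError("scores must be integers")
        arr = flt.astype(int)
    if arr.size and (arr.min() < SCORE_MIN or arr.max() > SCORE_MAX):
        raise ValueError("score outside the [0, 50] range")
    intervals = BAND_INTERVALS.get(convention) or _bad(convention)
    # upper edges ascending; searchsorted gives the band ordinal
    uppers = np.array([intervals[b][1] for b in BANDS_ASCENDING])
    return np.searchsorted(uppers, arr, side="left")
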