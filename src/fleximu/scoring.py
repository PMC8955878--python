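"""Gamified star scoring of the per-instant anomaly classification stream.

Each classified instant contributes its binary ``anomalyclass`` (1 =
correct exercising) to a running sum, and the star display is a linear
map of that sum::

    SCORE(n)         = sum_{t=Ns}^{n} anomalyclass(t)
    N_STARS_SHOWN(n) = floor(numstars / (fs * p * Tmax) * SCORE(n))

``p`` is a margin of error: with the default ``p = 0.8`` a patient whose
actions are classified correct for 80% of the interaction time already
earns the maximum five stars.  Because more than ``p`` of the time can be
correct, the raw formula can exceed ``numstars``; the display clamps at
``numstars`` (a "perfect score" is five stars, never six).  The sum
starts at the first full window (t = Ns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

__all__ = ["ScoreState", "update_score", "stars_shown", "score_stream"]


@dataclass(frozen=True)
class ScoreState:
    """Running score for one training session."""

    fs: float                 # sampling rate, Hz
    tmax: float               # session length, s
    ns: int = 21              # window length, samples
    p: float = 0.8            # margin of error (fraction of time for max stars)
    numstars: int = 5
    score: int = 0            # cumulative sum of binary classifications
    n: int = 0                # classified instants so far (t - Ns)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.tmax <= 0 or not 0 < self.p <= 1:
            raise ValueError("fs, Tmax must be positive and p in (0, 1]")
        if self.score < 0 or self.score > self.n:
            raise ValueError("score must stay within [0, instants classified]")


def update_score(state: ScoreState, anomaly_class: int) -> ScoreState:
    """Accumulate one binary classification (binarize scores first)."""
    if anomaly_class not in (0, 1):
        raise ValueError(
            f"anomaly_class must be binary 0/1, got {anomaly_class!r}; "
            "binarize classifier scores before scoring"
        )
    return replace(state, score=state.score + int(anomaly_class), n=state.n + 1)


def stars_shown(state: ScoreState) -> int:
    """Stars currently displayed: floor of the linear map, clamped to [0, numstars]."""
    raw = math.floor(
        state.numstars / (state.fs * state.p * state.tmax) * state.score
    )
    return max(0, min(state.numstars, raw))


def score_stream(
    classes: Iterable[int],
    fs: float,
    tmax: float,
    ns: int = 21,
    p: float = 0.8,
    numstars: int = 5,
) -> Iterator[tuple[ScoreState, int]]:
    """Fold a classification stream into (state, stars) updates."""
    state = ScoreState(fs=fs, tmax=tmax, ns=ns, p=p, numstars=numstars)
    for c in classes:
        state = update_score(state, c)
        yield state, stars_shown(state)
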