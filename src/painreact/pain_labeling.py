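"""Per-frame pain labels from sparse 0-10 self-reports.

A verbal rating arrives with latency, so every report time is first shifted
backward (default 2 s, floored at zero).  Between shifted reports the rating
is held constant (zero-order hold; zero before the first report).  Each 4 s
frame takes the maximum rating occurring within it, and a double threshold
turns that into three classes: below the lower threshold is *no pain*, at or
above the upper threshold is *severe pain*, anything between is *moderate
pain*.  The thresholds are deliberately parameters — pain resistance is
subject-dependent and the appropriate cut points are a property of the
cohort, not of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .core_data import PainReportSeries
from .feature_extraction import FramingSpec


class PainClass(IntEnum):
    NO_PAIN = 0
    MODERATE_PAIN = 1
    SEVERE_PAIN = 2


@dataclass(frozen=True)
class LabelingConfig:
    """Backward shift and the two thresholds on the 0-10 scale.

    Boundary convention: ``rating < t_low`` is no pain,
    ``rating >= t_high`` is severe pain.
    """

    shift_s: float = 2.0
    t_low: float = 4.0
    t_high: float = 7.0

    def __post_init__(self):
        if self.shift_s < 0:
            raise ValueError("shift_s must be >= 0")
        if not 0 <= self.t_low < self.t_high <= 10:
            raise ValueError("need 0 <= t_low < t_high <= 10")

    def classify(self, rating) -> np.ndarray:
        rating = np.asarray(rating, dtype=float)
        out = np.full(rating.shape, PainClass.MODERATE_PAIN, dtype=int)
        out[rating < self.t_low] = PainClass.NO_PAIN
        out[rating >= self.t_high] = PainClass.SEVERE_PAIN
        return out


@dataclass(frozen=True)
class RatingStep:
    """Piecewise-constant rating over time after the backward shift."""

    times: np.ndarray    # shifted, non-decreasing event times
    values: np.ndarray   # rating from each event time onward

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.zeros(t.shape) if t.ndim else 0.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return out if out.ndim else float(out)

    def max_in(self, start: float, stop: float) -> float:
        """Maximum of the step function over the half-open [start, stop)."""
        best = float(self(start))
        inside = (self.times >= start) & (self.times < stop)
        if inside.any():
            best = max(best, float(self.values[inside].max()))
        return best


def rating_step_function(reports: PainReportSeries,
                         shift_s: float = 2.0) -> RatingStep:
    """Shift each report back by ``shift_s`` (floored at 0) and hold it."""
    if shift_s < 0:
        raise ValueError("shift_s must be >= 0")
    shifted = np.maximum(reports.times - shift_s, 0.0)
    return RatingStep(times=shifted, values=reports.ratings.astype(float))


@dataclass(frozen=True)
class FrameLabels:
    """Per-frame class and the max rating that produced it."""

    classes: np.ndarray
    max_ratings: np.ndarray
    frame_starts: np.ndarray

    def __len__(self) -> int:
        return self.classes.size

    def class_counts(self) -> dict:
        return {c.name.lower(): int((self.classes == c).sum())
                for c in PainClass}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_start_s": self.frame_starts,
            "max_rating": self.max_ratings,
            "class": [PainClass(c).name.lower() for c in self.classes],
        })


def label_frames(reports: PainReportSeries, duration_s: float,
                 framing: FramingSpec = FramingSpec(),
                 config: LabelingConfig = LabelingConfig()) -> FrameLabels:
    """Label every frame of a session of ``duration_s`` seconds."""
    step = rating_step_function(reports, config.shift_s)
    starts = framing.frame_starts(duration_s)
    max_ratings = np.asarray(
        [step.max_in(s, s + framing.window_s) for s in starts])
    return FrameLabels(classes=config.classify(max_ratings),
                       max_ratings=max_ratings, frame_starts=starts)
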