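"""Data model and common preprocessing for synchronized multimodal recordings.

A recording session carries five physiological channels — electrodermal
activity (EDA), corrugator electromyography (EMG), respiration (RSP), blood
volume pulse (BVP) and hand dynamometer force (GRIP) — on a shared session
clock, together with the patient's sparse 0-10 verbal pain ratings.  This
module defines the containers, the directory-based CSV I/O, and the two
preprocessing steps shared by every downstream stage: polyphase FIR
anti-aliasing resampling and Gaussian-weighted moving-average smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

CHANNEL_NAMES = ("EDA", "EMG", "RSP", "BVP", "GRIP")

#: Sampling rates (Hz) each channel is brought to before feature extraction.
TARGET_RATES = {"EMG": 256.0, "BVP": 64.0, "EDA": 8.0, "RSP": 8.0, "GRIP": 75.0}


class MissingChannelError(KeyError):
    """A required channel file or entry is absent from a recording."""


class RecordingParseError(ValueError):
    """A recording file is malformed; carries the offending line number."""

    def __init__(self, message: str, path: Path | str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


@dataclass(frozen=True)
class ChannelSignal:
    """One uniformly sampled channel on the session clock."""

    name: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D series")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"channel {self.name!r} contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PainReportSeries:
    """Sparse verbal pain ratings: strictly increasing times, integers 0-10."""

    times: np.ndarray
    ratings: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ratings = np.asarray(self.ratings, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ratings", ratings)
        if times.shape != ratings.shape or times.ndim != 1:
            raise ValueError("times and ratings must be 1-D and equally long")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("report times must be strictly increasing")
        if ratings.size and (ratings.min() < 0 or ratings.max() > 10):
            bad = ratings[(ratings < 0) | (ratings > 10)][0]
            raise ValueError(f"pain rating {bad} outside the 0-10 scale")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MultimodalRecording:
    """One subject session: all five channels plus the self-report track."""

    subject_id: str
    channels: Mapping[str, ChannelSignal]
    reports: PainReportSeries
    baseline_end: float = 30.0
    native_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = [n for n in CHANNEL_NAMES if n not in self.channels]
        if missing:
            raise MissingChannelError(
                f"recording {self.subject_id!r} missing channel(s): {missing}")
        if not (0 <= self.baseline_end <= self.duration + 1e-9):
            raise ValueError(
                f"baseline_end {self.baseline_end} outside session span "
                f"[0, {self.duration:.3f}]")

    @property
    def duration(self) -> float:
        """Common session span covered by every channel, in seconds."""
        return min(c.t0 + c.duration for c in self.channels.values()) - max(
            c.t0 for c in self.channels.values())

    def with_channel(self, channel: ChannelSignal) -> "MultimodalRecording":
        channels = dict(self.channels)
        channels[channel.name] = channel
        return replace(self, channels=channels)


def resample_channel(sig: ChannelSignal, target_fs: float) -> ChannelSignal:
    """Rational polyphase resampling with a Kaiser-windowed FIR anti-alias filter.

    The low-pass cutoff sits at the smaller of the two Nyquist frequencies, so
    downsampling attenuates content above the target Nyquist by the filter's
    stopband.  ``padtype='line'`` extrapolates edges linearly, which keeps DC
    signals exactly constant through the transition regions.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    ratio = Fraction(target_fs / sig.fs).limit_denominator(1000)
    if ratio == 1:
        return sig
    up, down = ratio.numerator, ratio.denominator
    x = sig.samples
    n = x.size
    # reflect-pad past the filter transient so edge error stays at the
    # filter's ripple level; pad is a multiple of `down` so the crop index
    # is exact on the output grid
    pad = min(n - 1, 20 * max(up, down) * down)
    pad -= pad % down
    xp = np.pad(x, pad, mode="reflect") if pad else x
    full = sps.resample_poly(xp, up, down, window=("kaiser", 14.0),
                             padtype="line")
    start = pad * up // down
    out_len = int(np.ceil(n * up / down))
    out = full[start:start + out_len]
    return ChannelSignal(sig.name, target_fs, out, sig.t0)


def gaussian_smooth(sig: ChannelSignal, window_samples: int | None = None,
                    sigma_fraction: float = 0.2) -> ChannelSignal:
    """Gaussian-weighted moving average (weights sum to 1, reflected edges).

    Default window is one second of samples at the channel's rate; the
    Gaussian standard deviation is ``sigma_fraction * window`` samples.
    """
    if window_samples is None:
        window_samples = max(1, round(sig.fs))
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    n = sig.samples.size
    if window_samples > n:
        raise ValueError(
            f"smoothing window ({window_samples}) longer than signal ({n})")
    w = sps.windows.gaussian(window_samples, std=sigma_fraction * window_samples)
    w /= w.sum()
    half = window_samples // 2
    padded = np.pad(sig.samples, (half, window_samples - 1 - half), mode="reflect")
    out = np.convolve(padded, w, mode="valid")
    return ChannelSignal(sig.name, sig.fs, out, sig.t0)


# ---------------------------------------------------------------------------
# Directory I/O.  Layout: eda.csv emg.csv rsp.csv bvp.csv grip.csv (time_s,value),
# reports.csv (time_s,rating), session.json (subject_id, baseline_end_s, rates).
# ---------------------------------------------------------------------------

_UNIFORMITY_RTOL = 1e-3


def _read_series_csv(path: Path, value_col: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise RecordingParseError(str(exc), path) from exc
    for col in ("time_s", value_col):
        if col not in df.columns:
            raise RecordingParseError(f"missing column {col!r}", path, line=1)
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            # +2: header row plus 1-based numbering
            raise RecordingParseError(
                f"non-numeric {col!r} value", path, line=int(np.argmax(bad.values)) + 2)
    return df


def _channel_from_csv(path: Path, name: str) -> ChannelSignal:
    df = _read_series_csv(path, "value")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise RecordingParseError("channel needs at least 2 samples", path, line=2)
    dt = np.diff(t)
    med = np.median(dt)
    if med <= 0:
        raise RecordingParseError("timestamps not increasing", path,
                                  line=int(np.argmax(dt <= 0)) + 2)
    off = np.abs(dt - med) > _UNIFORMITY_RTOL * med
    if off.any():
        raise RecordingParseError(
            "non-uniform sampling interval", path, line=int(np.argmax(off)) + 3)
    return ChannelSignal(name, 1.0 / med, df["value"].to_numpy(float), t0=t[0])


def load_recording(directory: str | Path) -> MultimodalRecording:
    """Read one recording directory and return a validated recording."""
    directory = Path(directory)
    meta_path = directory / "session.json"
    if not meta_path.exists():
        raise RecordingParseError("session.json not found", meta_path)
    meta = json.loads(meta_path.read_text())

    channels = {}
    for name in CHANNEL_NAMES:
        path = directory / f"{name.lower()}.csv"
        if not path.exists():
            raise MissingChannelError(f"channel file missing for {name}: {path}")
        channels[name] = _channel_from_csv(path, name)

    rep_df = _read_series_csv(directory / "reports.csv", "rating")
    ratings = rep_df["rating"].to_numpy(float)
    if ratings.size and (ratings.min() < 0 or ratings.max() > 10):
        bad = int(np.argmax((ratings < 0) | (ratings > 10)))
        raise RecordingParseError(
            f"rating {ratings[bad]:g} outside 0-10", directory / "reports.csv",
            line=bad + 2)
    t = rep_df["time_s"].to_numpy(float)
    if t.size and np.any(np.diff(t) <= 0):
        raise RecordingParseError(
            "report times not strictly increasing", directory / "reports.csv",
            line=int(np.argmax(np.diff(t) <= 0)) + 3)
    reports = PainReportSeries(t, ratings.round().astype(int))

    return MultimodalRecording(
        subject_id=str(meta.get("subject_id", directory.name)),
        channels=channels,
        reports=reports,
        baseline_end=float(meta.get("baseline_end_s", 30.0)),
        native_rates={k: float(v) for k, v in meta.get("native_rates", {}).items()},
    )


def write_recording(rec: MultimodalRecording, directory: str | Path) -> Path:
    """Write a recording in the directory layout :func:`load_recording` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, ch in rec.channels.items():
        pd.DataFrame({"time_s": ch.times, "value": ch.samples}).to_csv(
            directory / f"{name.lower()}.csv", index=False)
    pd.DataFrame({"time_s": rec.reports.times,
                  "rating": rec.reports.ratings}).to_csv(
        directory / "reports.csv", index=False)
    meta = {"subject_id": rec.subject_id,
            "baseline_end_s": rec.baseline_end,
            "native_rates": {k: v for k, v in rec.native_rates.items()}}
    (directory / "session.json").write_text(json.dumps(meta, indent=1))
    return directory
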