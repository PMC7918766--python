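"""Per-frame feature matrix: scattering energies, spectral entropy,
time-domain and derivative statistics, an STFT-energy variant, and
subject-based z-score normalization.

All modalities share one frame grid — 4 s windows advancing by 2 s — so a
session of duration D yields ``floor((D - 4)/2) + 1`` frames regardless of a
channel's sampling rate.  The default (scattering) configuration produces
exactly 33 named columns:

* 20 scattering energies — S/U layer energies for EMG (6) and BVP (6) from
  the three-layer transform and for the EDA phasic component (4) and RSP (4)
  from the two-layer transform;
* 2 spectral entropies (EMG, RSP);
* 8 windowed statistics — max, median, sd, peak-to-peak amplitude for the
  EDA phasic component and RSP;
* 3 first-derivative statistics — max, mean, sd for the EDA phasic component.

The STFT variant replaces the 20 scattering energies with one spectrogram
frame energy per modality, giving 17 columns.  The statistic-to-signal
allocation is configurable; the default is the one consistent with the
33-column total.  GRIP consequently contributes no default features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import ChannelSignal, MultimodalRecording
from .scattering import (FilterBankConfig, ScatteringOutput, align_frames,
                         scattering_transform)

#: Per-layer voices per octave by channel; three layers for the
#: high-frequency channels, two for the low-frequency ones.
SCATTERING_Q = {"EMG": (8, 4, 1), "BVP": (8, 4, 1), "EDA": (8, 1), "RSP": (8, 1)}

SPECTRAL_CHANNELS = ("EMG", "BVP", "EDA", "RSP")
ENTROPY_CHANNELS = ("EMG", "RSP")
STAT_CHANNELS = ("EDA", "RSP")
DERIVATIVE_CHANNELS = ("EDA",)


@dataclass(frozen=True)
class FramingSpec:
    """The shared 4 s / 50 %-overlap frame grid."""

    window_s: float = 4.0
    hop_s: float = 2.0

    def __post_init__(self):
        if self.window_s <= 0 or not 0 < self.hop_s <= self.window_s:
            raise ValueError("need window_s > 0 and 0 < hop_s <= window_s")

    def n_frames(self, duration_s: float) -> int:
        return int(np.floor((duration_s - self.window_s) / self.hop_s)) + 1

    def frame_starts(self, duration_s: float) -> np.ndarray:
        return np.arange(self.n_frames(duration_s)) * self.hop_s

    def frame_slices(self, n_samples: int, fs: float) -> list[slice]:
        starts = self.frame_starts(n_samples / fs)
        w = round(self.window_s * fs)
        return [slice(int(round(s * fs)), int(round(s * fs)) + w)
                for s in starts]


@dataclass(frozen=True)
class FeatureMatrix:
    """Frames x features with named columns for one subject."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    subject_id: str
    frame_starts: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2 or values.shape[1] != len(self.feature_names):
            raise ValueError("values shape does not match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "frame_start_s", self.frame_starts)
        df.insert(0, "subject_id", self.subject_id)
        return df


def frame_energy(aligned: ScatteringOutput) -> tuple[np.ndarray, list[str]]:
    """One energy column per S/U matrix: sum over paths of squared
    coefficients at each frame, ordered S1, U1, S2, U2, ...

    A three-layer transform yields 6 columns, a two-layer one 4.
    """
    cols, names = [], []
    for layer, (s_mat, u_mat) in enumerate(zip(aligned.S, aligned.U), start=1):
        if s_mat.shape[1] != u_mat.shape[1]:
            raise ValueError("align_frames must be applied before frame_energy")
        cols.append((s_mat ** 2).sum(axis=0))
        names.append(f"S{layer}_energy")
        cols.append((u_mat ** 2).sum(axis=0))
        names.append(f"U{layer}_energy")
    return np.column_stack(cols), names


def entropy_bits(power: np.ndarray) -> float:
    """Shannon entropy (bits) of a power distribution; all-zero -> 0."""
    power = np.asarray(power, dtype=float)
    total = power.sum()
    if total <= 0:
        return 0.0
    p = power / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def spectral_entropy(samples: np.ndarray, fs: float,
                     framing: FramingSpec) -> np.ndarray:
    """Per-frame spectral entropy: Hann-windowed periodogram of each 4 s
    frame, normalized to a probability distribution, entropy in bits."""
    samples = np.asarray(samples, dtype=float)
    out = []
    for sl in framing.frame_slices(samples.size, fs):
        frame = samples[sl]
        if frame.size < 2:
            raise ValueError("frame too short for a spectrum")
        w = np.hanning(frame.size)
        spec = np.abs(np.fft.rfft(frame * w)) ** 2
        out.append(entropy_bits(spec))
    return np.asarray(out)


def time_domain_stats(samples: np.ndarray, fs: float,
                      framing: FramingSpec) -> tuple[np.ndarray, list[str]]:
    """Per-frame (max, median, sample sd, peak-to-peak amplitude)."""
    samples = np.asarray(samples, dtype=float)
    rows = []
    for sl in framing.frame_slices(samples.size, fs):
        f = samples[sl]
        rows.append([f.max(), float(np.median(f)),
                     f.std(ddof=1) if f.size > 1 else 0.0,
                     float(np.ptp(f))])
    return np.asarray(rows), ["max", "median", "sd", "amplitude"]


def derivative_stats(samples: np.ndarray, fs: float,
                     framing: FramingSpec) -> tuple[np.ndarray, list[str]]:
    """Per-frame (max, mean, sample sd) of the first derivative (diff * fs)."""
    samples = np.asarray(samples, dtype=float)
    rows = []
    for sl in framing.frame_slices(samples.size, fs):
        d = np.diff(samples[sl]) * fs
        if d.size < 1:
            raise ValueError("frame too short for a derivative")
        rows.append([d.max(), d.mean(), d.std(ddof=1) if d.size > 1 else 0.0])
    return np.asarray(rows), ["d1_max", "d1_mean", "d1_sd"]


def stft_frame_energy(samples: np.ndarray, fs: float,
                      framing: FramingSpec) -> np.ndarray:
    """Spectrogram energy of each 4 s frame: sum of |STFT|^2 over frequency
    bins, scaled so it equals the Hann-weighted time-domain frame energy
    (Parseval)."""
    samples = np.asarray(samples, dtype=float)
    out = []
    for sl in framing.frame_slices(samples.size, fs):
        frame = samples[sl]
        w = np.hanning(frame.size)
        spec = np.abs(np.fft.rfft(frame * w)) ** 2
        full = 2 * spec.sum() - spec[0]
        if frame.size % 2 == 0:
            full -= spec[-1]
        out.append(full / frame.size)
    return np.asarray(out)


def _scattering_energies(ch: ChannelSignal, framing: FramingSpec,
                         n_frames: int) -> tuple[np.ndarray, list[str]]:
    cfg = FilterBankConfig(fs=ch.fs, voices_per_octave=SCATTERING_Q[ch.name],
                           invariance_scale_s=framing.window_s,
                           hop_fraction=framing.hop_s / framing.window_s)
    out = scattering_transform(ch.samples, cfg, n_frames=n_frames)
    energies, names = frame_energy(align_frames(out, n_frames))
    return energies, [f"{ch.name}_scat_{n}" for n in names]


def extract_features(rec: MultimodalRecording, mode: str = "scattering",
                     framing: FramingSpec = FramingSpec()) -> FeatureMatrix:
    """Build the per-frame feature matrix for one preprocessed recording.

    The recording must already be at the analysis rates with the EDA channel
    replaced by its phasic component (see
    :func:`painreact.pipeline.preprocess_recording`).
    """
    if mode not in ("scattering", "stft"):
        raise ValueError(f"unknown feature mode {mode!r}")
    duration = rec.duration
    if duration < framing.window_s:
        raise ValueError(f"recording ({duration:.1f} s) shorter than one "
                         f"{framing.window_s} s frame")
    n_frames = framing.n_frames(duration)

    cols: list[np.ndarray] = []
    names: list[str] = []

    if mode == "scattering":
        for name in SPECTRAL_CHANNELS:
            e, n = _scattering_energies(rec.channels[name], framing, n_frames)
            cols.append(e[:n_frames])
            names.extend(n)
    else:
        for name in SPECTRAL_CHANNELS:
            ch = rec.channels[name]
            e = stft_frame_energy(ch.samples, ch.fs, framing)
            cols.append(e[:n_frames, None])
            names.append(f"{name}_stft_energy")

    for name in ENTROPY_CHANNELS:
        ch = rec.channels[name]
        cols.append(spectral_entropy(ch.samples, ch.fs, framing)[:n_frames, None])
        names.append(f"{name}_spectral_entropy")

    for name in STAT_CHANNELS:
        ch = rec.channels[name]
        stats, stat_names = time_domain_stats(ch.samples, ch.fs, framing)
        cols.append(stats[:n_frames])
        names.extend(f"{name}_{s}" for s in stat_names)

    for name in DERIVATIVE_CHANNELS:
        ch = rec.channels[name]
        stats, stat_names = derivative_stats(ch.samples, ch.fs, framing)
        cols.append(stats[:n_frames])
        names.extend(f"{name}_{s}" for s in stat_names)

    values = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
    return FeatureMatrix(values=values, feature_names=tuple(names),
                         subject_id=rec.subject_id,
                         frame_starts=framing.frame_starts(duration))


def zscore_by_subject(matrices):
    """Z-score each subject's columns with that subject's own mean and sd.

    Accepts one :class:`FeatureMatrix` or an iterable of them (one per
    subject); zero-variance columns become all zeros.  A subject with a
    single frame has no defined sd and raises.
    """
    single = isinstance(matrices, FeatureMatrix)
    mats: Sequence[FeatureMatrix] = [matrices] if single else list(matrices)
    out = []
    for fm in mats:
        if fm.n_frames < 2:
            raise ValueError(
                f"subject {fm.subject_id!r} has {fm.n_frames} frame(s); "
                "z-scoring needs at least 2")
        mu = fm.values.mean(axis=0)
        sd = fm.values.std(axis=0, ddof=1)
        z = np.where(sd > 0, (fm.values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out.append(replace(fm, values=z))
    return out[0] if single else out


def pool_features(matrices: Iterable[FeatureMatrix]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject matrices into (X, subject_ids) for classification."""
    mats = list(matrices)
    names = mats[0].feature_names
    if any(m.feature_names != names for m in mats):
        raise ValueError("feature name mismatch across subjects")
    X = np.vstack([m.values for m in mats])
    subjects = np.concatenate([[m.subject_id] * m.n_frames for m in mats])
    return X, subjects
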