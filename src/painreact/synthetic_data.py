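"""Synthetic multimodal cohorts with known ground truth.

The clinical recordings behind this pipeline (fascial neck/arm therapy
sessions) are not publicly available, so every downstream stage is exercised
on simulated cohorts instead.  Each simulated session follows the study
protocol: a no-pain baseline (default 30 s), then a 2-3 minute therapy
segment in which pain episodes arrive irregularly.  An episode carries a
latent 0-10 intensity that jointly modulates all five channels — a Bateman
skin-conductance response in EDA, a corrugator EMG burst, faster/deeper
breathing in RSP, a pulse-rate shift in BVP, and (for intense episodes) a
grip squeeze — scaled per subject by reactivity gains, because patients vary
widely in pain reactions.  The patient calls out integer ratings with a
short latency, and keeps reporting as the pain subsides, so the report track
rises and falls with the latent intensity.

The simulator is a statistical stand-in, not a physiological model: it
produces the structure the pipeline exploits (correlated multichannel
responses, delayed discrete reports), with everything reproducible from
``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core_data import (ChannelSignal, MultimodalRecording, PainReportSeries,
                        write_recording)

#: Device-side sampling rates the simulator emits; the pipeline resamples
#: these to the analysis rates in :data:`painreact.core_data.TARGET_RATES`.
DEFAULT_NATIVE_RATES = {"EDA": 32.0, "EMG": 512.0, "RSP": 32.0,
                        "BVP": 128.0, "GRIP": 150.0}

DEFAULT_REACTIVITY_RANGES = {name: (0.6, 1.6) for name in DEFAULT_NATIVE_RATES}

DEFAULT_NOISE_LEVELS = {"EDA": 0.01, "EMG": 0.01, "RSP": 0.03,
                        "BVP": 0.05, "GRIP": 0.02}


def bateman_kernel(tau0: float, tau1: float, fs: float,
                   duration_s: float) -> np.ndarray:
    """Skin-conductance-response impulse shape, normalized to unit peak.

    ``h(t) = exp(-t/tau1) - exp(-t/tau0)`` for ``t >= 0`` with the fast rise
    constant ``tau0`` strictly below the slow decay constant ``tau1``; the
    analytic peak sits at ``t* = tau0*tau1/(tau1-tau0) * ln(tau1/tau0)``.
    """
    if not 0 < tau0 < tau1:
        raise ValueError(f"need 0 < tau0 < tau1, got tau0={tau0}, tau1={tau1}")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = np.exp(-t / tau1) - np.exp(-t / tau0)
    peak = np.exp(-_bateman_peak_time(tau0, tau1) / tau1) - np.exp(
        -_bateman_peak_time(tau0, tau1) / tau0)
    return h / peak


def _bateman_peak_time(tau0: float, tau1: float) -> float:
    return tau0 * tau1 / (tau1 - tau0) * np.log(tau1 / tau0)


def inject_scrs(event_times: np.ndarray, amplitudes: np.ndarray, fs: float,
                duration_s: float, tau0: float = 0.7,
                tau1: float = 2.0) -> np.ndarray:
    """Sum of Bateman responses: linear in the amplitudes by construction."""
    n = round(duration_s * fs)
    out = np.zeros(n)
    kernel = bateman_kernel(tau0, tau1, fs, min(duration_s, 12 * tau1))
    for t_ev, amp in zip(np.atleast_1d(event_times), np.atleast_1d(amplitudes)):
        i0 = int(round(t_ev * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        out[i0:i0 + seg.size] += amp * seg
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol parameters of a simulated cohort.

    ``session_s=None`` draws each subject's session length uniformly from
    150-210 s (a 30 s baseline followed by 2-3 minutes of therapy); a value
    fixes it.  ``episode_rate`` is pain episodes per minute of therapy.
    """

    n_subjects: int = 6
    session_s: float | None = None
    baseline_s: float = 30.0
    episode_rate: float = 3.0
    reactivity_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_REACTIVITY_RANGES))
    report_delay_s: float = 2.0
    report_delay_jitter_s: float = 0.4
    noise_levels: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_LEVELS))
    native_rates: dict = field(default_factory=lambda: dict(DEFAULT_NATIVE_RATES))
    scr_tau0: float = 0.7
    scr_tau1: float = 2.0
    latent_decay_s: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.baseline_s <= 0 or self.episode_rate < 0:
            raise ValueError("durations must be positive, rates non-negative")
        if self.session_s is not None and self.baseline_s >= self.session_s:
            raise ValueError("baseline_s must be shorter than session_s")

    @classmethod
    def easy_regime(cls, n_subjects: int = 6, seed: int = 0) -> "SimulationConfig":
        """High-reactivity, low-noise regime used for recovery checks."""
        return cls(
            n_subjects=n_subjects,
            episode_rate=3.5,
            reactivity_ranges={k: (1.5, 2.5) for k in DEFAULT_NATIVE_RATES},
            noise_levels={k: v * 0.3 for k, v in DEFAULT_NOISE_LEVELS.items()},
            seed=seed,
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator injected, for recovery tests downstream."""

    episode_times: np.ndarray
    episode_intensities: np.ndarray
    latent_times: np.ndarray        # fine grid, seconds
    latent_intensity: np.ndarray    # 0-10 latent pain on that grid
    eda_phasic_clean: np.ndarray    # noiseless injected SCR train @ EDA rate
    eda_fs: float
    reactivity: dict


def _episode_schedule(rng: np.random.Generator, baseline_s: float,
                      session_s: float, rate_per_min: float,
                      min_gap_s: float = 6.0) -> np.ndarray:
    """Poisson-like arrivals in the therapy segment with a refractory gap."""
    lo, hi = baseline_s + 3.0, session_s - 8.0
    if rate_per_min <= 0 or hi <= lo:
        return np.empty(0)
    n_cand = rng.poisson(rate_per_min * (hi - lo) / 60.0 * 1.4)
    times = np.sort(rng.uniform(lo, hi, size=n_cand))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(t)
    return np.asarray(kept)


def _latent_intensity(t: np.ndarray, ep_times: np.ndarray,
                      ep_int: np.ndarray, decay_s: float) -> np.ndarray:
    """Per-episode pulse: fast (0.5 s) rise, exponential decay, capped at 10."""
    lat = np.zeros_like(t)
    for t0, inten in zip(ep_times, ep_int):
        u = t - t0
        m = u >= 0
        lat[m] += inten * np.exp(-u[m] / decay_s) * (1 - np.exp(-u[m] / 0.5))
    return np.minimum(lat, 10.0)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited noise (corrugator EMG carrier)."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / (y.std() + 1e-12)


def simulate_subject(config: SimulationConfig,
                     subject_index: int) -> tuple[MultimodalRecording, GroundTruth]:
    """One subject session, bit-reproducible from ``(config.seed, subject_index)``."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, subject_index])
    session_s = (config.session_s if config.session_s is not None
                 else rng.uniform(150.0, 210.0))
    gains = {ch: np.exp(rng.uniform(np.log(lo), np.log(hi)))
             for ch, (lo, hi) in config.reactivity_ranges.items()}

    ep_times = _episode_schedule(rng, config.baseline_s, session_s,
                                 config.episode_rate)
    ep_int = rng.uniform(1.5, 10.0, size=ep_times.size)

    fine_fs = 32.0
    t_fine = np.arange(0.0, session_s, 1.0 / fine_fs)
    latent = _latent_intensity(t_fine, ep_times, ep_int, config.latent_decay_s)

    def latent_at(fs):
        tt = np.arange(round(session_s * fs)) / fs
        return tt, np.interp(tt, t_fine, latent)

    rates = config.native_rates
    noise = config.noise_levels
    channels = {}

    # --- EDA: tonic drift + Bateman SCR train + measurement noise
    fs = rates["EDA"]
    tt, _ = latent_at(fs)
    n = tt.size
    tonic = (2.0 + 0.3 * rng.uniform(-1, 1)
             + 0.15 * np.sin(2 * np.pi * tt / 97.0 + rng.uniform(0, 2 * np.pi))
             + 0.004 * tt / 60.0)
    phasic_clean = inject_scrs(ep_times, 0.12 * gains["EDA"] * ep_int, fs,
                               session_s, config.scr_tau0, config.scr_tau1)[:n]
    channels["EDA"] = ChannelSignal(
        "EDA", fs, tonic + phasic_clean + noise["EDA"] * rng.standard_normal(n))

    # --- EMG: resting tone plus amplitude-modulated 20-150 Hz bursts
    fs = rates["EMG"]
    tt, lat = latent_at(fs)
    carrier = _band_noise(rng, tt.size, fs, 20.0, min(150.0, 0.45 * fs))
    envelope = 0.02 + 0.18 * gains["EMG"] * (lat / 10.0) ** 1.5
    channels["EMG"] = ChannelSignal(
        "EMG", fs, envelope * carrier + noise["EMG"] * rng.standard_normal(tt.size))

    # --- RSP: breathing whose rate and depth rise with pain
    fs = rates["RSP"]
    tt, lat = latent_at(fs)
    f_breath = 0.25 * (1.0 + 0.5 * gains["RSP"] * lat / 10.0)
    phase = 2 * np.pi * np.cumsum(f_breath) / fs
    depth = 0.5 * (1.0 + 0.6 * gains["RSP"] * lat / 10.0)
    channels["RSP"] = ChannelSignal(
        "RSP", fs, depth * np.sin(phase + rng.uniform(0, 2 * np.pi))
        + noise["RSP"] * rng.standard_normal(tt.size))

    # --- BVP: pulse wave with episode-linked rate increase, mild damping
    fs = rates["BVP"]
    tt, lat = latent_at(fs)
    hr = 1.15 * (1.0 + 0.20 * gains["BVP"] * lat / 10.0)
    phase = 2 * np.pi * np.cumsum(hr) / fs + rng.uniform(0, 2 * np.pi)
    amp = 1.0 - 0.25 * gains["BVP"] * lat / 10.0 / 2.5
    channels["BVP"] = ChannelSignal(
        "BVP", fs, amp * (np.sin(phase) + 0.35 * np.sin(2 * phase + 0.8))
        + noise["BVP"] * rng.standard_normal(tt.size))

    # --- GRIP: squeeze transients for intense episodes only
    fs = rates["GRIP"]
    tt, _ = latent_at(fs)
    grip = np.full(tt.size, 0.5)
    for t0, inten in zip(ep_times, ep_int):
        if inten >= 6.0:
            grip += (0.4 * gains["GRIP"] * inten / 10.0
                     * np.exp(-0.5 * ((tt - t0 - 1.0) / 1.5) ** 2))
    channels["GRIP"] = ChannelSignal(
        "GRIP", fs, grip + noise["GRIP"] * rng.standard_normal(tt.size))

    reports = _make_reports(rng, config, ep_times, ep_int, t_fine, latent,
                            session_s)

    rec = MultimodalRecording(
        subject_id=f"S{subject_index:03d}",
        channels=channels,
        reports=reports,
        baseline_end=config.baseline_s,
        native_rates=dict(rates),
    )
    truth = GroundTruth(
        episode_times=ep_times,
        episode_intensities=ep_int,
        latent_times=t_fine,
        latent_intensity=latent,
        eda_phasic_clean=phasic_clean,
        eda_fs=rates["EDA"],
        reactivity=gains,
    )
    return rec, truth


def _make_reports(rng, config, ep_times, ep_int, t_fine, latent,
                  session_s) -> PainReportSeries:
    """Delayed integer call-outs at each episode plus decay follow-ups.

    Patients keep announcing numbers as the pain fades, so between episodes
    the track steps back down — the zero-order-hold label model then follows
    the latent intensity instead of freezing at the last peak.
    """
    events: list[tuple[float, int]] = []
    for k, (t0, inten) in enumerate(zip(ep_times, ep_int)):
        delay = max(0.3, config.report_delay_s
                    + config.report_delay_jitter_s * rng.standard_normal())
        t_rep = t0 + delay
        events.append((t_rep, int(np.clip(round(inten), 0, 10))))
        next_t = ep_times[k + 1] if k + 1 < ep_times.size else session_s
        t_follow = t_rep + 5.0
        while t_follow < min(next_t + config.report_delay_s, session_s - 0.5):
            level = float(np.interp(t_follow - config.report_delay_s,
                                    t_fine, latent))
            events.append((t_follow, int(np.clip(round(level), 0, 10))))
            if level < 0.5:
                break
            t_follow += 5.0
    events.sort()
    times, ratings = [], []
    for t, r in events:
        if t >= session_s:
            continue
        if times and t - times[-1] < 0.25:
            ratings[-1] = max(ratings[-1], r)
            continue
        times.append(t)
        ratings.append(r)
    return PainReportSeries(np.asarray(times), np.asarray(ratings, dtype=int))


def simulate_cohort(config: SimulationConfig,
                    out_dir: str | Path | None = None
                    ) -> list[tuple[MultimodalRecording, GroundTruth]]:
    """Simulate ``config.n_subjects`` independent subjects.

    With ``out_dir`` set, each recording is also written in the directory
    layout :func:`painreact.core_data.load_recording` reads, plus a
    ``ground_truth.json`` with the injected episodes.
    """
    cohort = [simulate_subject(config, i) for i in range(config.n_subjects)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        truth_dump = {}
        for rec, truth in cohort:
            write_recording(rec, out_dir / rec.subject_id)
            truth_dump[rec.subject_id] = {
                "episode_times_s": truth.episode_times.tolist(),
                "episode_intensities": truth.episode_intensities.tolist(),
                "reactivity": {k: float(v) for k, v in truth.reactivity.items()},
            }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth_dump, indent=1))
    return cohort
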