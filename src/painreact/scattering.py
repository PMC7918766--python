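"""Deep 1-D wavelet scattering transform with Morlet filter banks.

The transform iterates wavelet decomposition and modulus: the first-layer
scalogram is ``U1 = |x * psi_l1|`` for every wavelet in the first bank, the
scattergram averages it with a Gaussian low-pass, ``S1 = U1 * phi``, and each
further layer applies the next bank to the previous scalogram,
``U_{n+1} = |U_n * psi_{l_{n+1}}|`` and ``S_{n+1} = U_{n+1} * phi``.  The
modulus demodulates oscillation into slow envelopes, so ``S`` is invariant
to translations up to the averaging scale (4 s by default) while the deeper
``U`` layers recover the detail the averaging removes.

Filters are Morlet wavelets built directly in the frequency domain,
geometrically spaced with Q voices per octave per layer (here Q = [8, 4, 1]
for the 256/64 Hz channels and [8, 1] for the 8 Hz channels), with the
zero-mean admissibility correction and a bank-wide normalization that keeps
the Littlewood-Paley sum ``|phi^|^2 + sum |psi^|^2`` inside (0, 1] — which
makes the whole cascade nonexpansive.  Only frequency-decreasing paths are
kept (a child wavelet must sit below its parent's center frequency), the
standard truncation since higher child frequencies carry almost no envelope
energy.

Internally, envelopes are decimated between layers to the rate their own
bandwidth requires; output scalograms are Fourier-interpolated onto a common
time axis, and scattergrams are sampled on the 4 s / 50 %-overlap frame grid
shared with the rest of the feature pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

_LN2 = np.log(2.0)
#: Cap on a wavelet's relative bandwidth sigma_f / center (keeps the Q=1
#: filters admissible: the zero-mean correction stays a small term).
_MAX_REL_BW = 0.4


@dataclass(frozen=True)
class FilterBankConfig:
    """Per-channel scattering configuration.

    ``voices_per_octave`` lists Q for each layer (its length is the
    transform depth); ``invariance_scale_s`` is the support of the
    averaging window phi; frames advance by ``hop_fraction`` of it.
    """

    fs: float
    voices_per_octave: tuple[int, ...] = (8, 4, 1)
    invariance_scale_s: float = 4.0
    hop_fraction: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "voices_per_octave",
                           tuple(int(q) for q in self.voices_per_octave))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.voices_per_octave or any(
                q < 1 for q in self.voices_per_octave):
            raise ValueError("voices_per_octave must be positive integers")
        if self.invariance_scale_s * self.fs < 2:
            raise ValueError("invariance scale too short for this rate")
        if not 0 < self.hop_fraction <= 1:
            raise ValueError("hop_fraction must be in (0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.voices_per_octave)

    @property
    def hop_s(self) -> float:
        return self.invariance_scale_s * self.hop_fraction


def _morlet_hat(f: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Frequency response of a zero-mean Morlet: Gaussian bump minus the
    admissibility correction that cancels the response at f = 0."""
    beta = np.exp(-center ** 2 / (2 * sigma ** 2))
    return (np.exp(-((f - center) ** 2) / (2 * sigma ** 2))
            - beta * np.exp(-(f ** 2) / (2 * sigma ** 2)))


@dataclass(frozen=True)
class LayerBank:
    """One layer's wavelets: descending center frequencies plus a common gain."""

    q: int
    centers: np.ndarray
    sigmas: np.ndarray
    gain: float = 1.0

    def psi_hat(self, f: np.ndarray, index: int) -> np.ndarray:
        return self.gain * _morlet_hat(f, self.centers[index],
                                       self.sigmas[index])


@dataclass(frozen=True)
class FilterBank:
    config: FilterBankConfig
    layers: tuple[LayerBank, ...]
    sigma_t: float          # phi time-std in seconds
    f_min: float            # lowest wavelet center = band edge of phi

    def phi_hat(self, f: np.ndarray) -> np.ndarray:
        return np.exp(-2 * np.pi ** 2 * self.sigma_t ** 2 * np.asarray(f) ** 2)

    def lp_sum(self, layer: int, f: np.ndarray) -> np.ndarray:
        """Littlewood-Paley sum |phi^|^2 + sum_k |psi_k^|^2 on a grid."""
        lb = self.layers[layer]
        total = self.phi_hat(f) ** 2
        for k in range(lb.centers.size):
            total = total + np.abs(lb.psi_hat(f, k)) ** 2
        return total


def build_filterbank(config: FilterBankConfig) -> FilterBank:
    """Construct the Morlet banks and normalize each layer's gain so its
    Littlewood-Paley sum stays within (0, 1]."""
    fs = config.fs
    sigma_t = config.invariance_scale_s / 4.0
    # phi's half-power frequency; wavelets start one octave above it.
    f_hp = np.sqrt(_LN2 / 2.0) / (np.sqrt(2.0) * np.pi * sigma_t)
    f_min = 2.0 * f_hp
    f_max = 0.4 * fs
    if f_max <= f_min:
        raise ValueError("sampling rate too low for this invariance scale")

    # hybrid grid: linear coverage plus log-spaced points that resolve the
    # narrow low-frequency filters when fs spans many octaves
    grid = np.unique(np.concatenate([
        np.linspace(0.0, 0.5 * fs, 16384)[1:],
        np.geomspace(f_min / 16.0, 0.5 * fs, 8192),
    ]))
    phi2 = np.exp(-2 * np.pi ** 2 * sigma_t ** 2 * grid ** 2) ** 2

    layers = []
    for q in config.voices_per_octave:
        n_wav = int(np.floor(np.log2(f_max / f_min) * q)) + 1
        centers = f_max * 2.0 ** (-np.arange(n_wav) / q)
        rel_bw = min((2.0 ** (1.0 / q) - 1.0) / np.sqrt(2 * _LN2), _MAX_REL_BW)
        sigmas = centers * rel_bw
        a = np.zeros_like(grid)
        for c, s in zip(centers, sigmas):
            a += np.abs(_morlet_hat(grid, c, s)) ** 2
        mask = a > 1e-6 * a.max()
        # 0.5 % safety margin keeps the Littlewood-Paley sum below 1 between
        # normalization grid points
        gain = float(np.sqrt(np.min((1.0 - phi2[mask]) / a[mask]))) * 0.9975
        layers.append(LayerBank(q=q, centers=centers, sigmas=sigmas, gain=gain))
    return FilterBank(config=config, layers=tuple(layers),
                      sigma_t=sigma_t, f_min=f_min)


@dataclass(frozen=True)
class ScatteringOutput:
    """Scattergrams S_n (paths x frames) and scalograms U_n (paths x time).

    ``path_meta[n][p]`` is the tuple of wavelet center frequencies along
    path ``p`` of layer ``n``; ``layer_u_energy`` holds each layer's total
    scalogram energy (time-integral of U^2) for energy-decay diagnostics.
    """

    S: tuple[np.ndarray, ...]
    U: tuple[np.ndarray, ...]
    path_meta: tuple[tuple[tuple[float, ...], ...], ...]
    frame_starts: np.ndarray
    layer_u_energy: tuple[float, ...]
    config: FilterBankConfig

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size


def _fft_lowpass(u: np.ndarray, fs_u: float, bank: FilterBank,
                 pad: int) -> np.ndarray:
    up = np.pad(u, pad, mode="reflect") if pad else u
    f = np.fft.rfftfreq(up.size, 1.0 / fs_u)
    out = np.fft.irfft(np.fft.rfft(up) * bank.phi_hat(f), n=up.size)
    return out[pad:pad + u.size] if pad else out


def _fft_resample(u: np.ndarray, length: int) -> np.ndarray:
    if u.size == length:
        return u.copy()
    return sps.resample(u, length)


def scattering_transform(x, config: FilterBankConfig,
                         n_frames: int | None = None,
                         u_oversample: int = 4) -> ScatteringOutput:
    """Compute all scattering layers of one uniformly sampled signal.

    ``x`` may be an array at ``config.fs`` or a ``ChannelSignal``.  When
    ``n_frames`` is omitted it follows the shared framing rule
    ``floor((D - window)/hop) + 1`` for signal duration D.
    """
    samples = getattr(x, "samples", None)
    if samples is not None:
        if abs(x.fs - config.fs) > 1e-9:
            raise ValueError(f"signal at {x.fs} Hz but bank built for "
                             f"{config.fs} Hz")
        x = samples
    x = np.asarray(x, dtype=float)
    fs = config.fs
    T = config.invariance_scale_s
    n = x.size
    if n < round(T * fs):
        raise ValueError(f"signal shorter ({n / fs:.2f} s) than one "
                         f"invariance window ({T} s)")
    duration = n / fs
    if n_frames is None:
        n_frames = int(np.floor((duration - T) / config.hop_s)) + 1
    n_frames = max(n_frames, 1)
    frame_starts = np.arange(n_frames) * config.hop_s
    frame_centers = frame_starts + T / 2.0
    u_len = max(u_oversample * n_frames, 2)

    bank = build_filterbank(config)
    n_layers = config.n_layers
    S_paths: list[list[np.ndarray]] = [[] for _ in range(n_layers)]
    U_paths: list[list[np.ndarray]] = [[] for _ in range(n_layers)]
    meta: list[list[tuple[float, ...]]] = [[] for _ in range(n_layers)]
    u_energy = [0.0] * n_layers

    def process(u: np.ndarray, fs_u: float, layer: int,
                history: tuple[float, ...]) -> None:
        lb = bank.layers[layer]
        parent_f = history[-1] if history else np.inf
        keep = [k for k in range(lb.centers.size)
                if lb.centers[k] < min(parent_f, 0.45 * fs_u)]
        if not keep or u.size < 4:
            return
        pad = min(round(T * fs_u), u.size - 1)
        up = np.pad(u, pad, mode="reflect") if pad else u
        F = np.fft.fft(up)
        f_grid = np.fft.fftfreq(up.size, 1.0 / fs_u)
        for k in keep:
            psi = lb.psi_hat(f_grid, k)
            uc = np.abs(np.fft.ifft(F * psi))[pad:pad + u.size]
            path = history + (float(lb.centers[k]),)
            s_full = _fft_lowpass(uc, fs_u, bank, pad=min(pad, uc.size - 1))
            idx = np.clip(np.round(frame_centers * fs_u).astype(int),
                          0, uc.size - 1)
            S_paths[layer].append(s_full[idx])
            U_paths[layer].append(_fft_resample(uc, u_len))
            meta[layer].append(path)
            u_energy[layer] += float(np.dot(uc, uc) / fs_u)
            if layer + 1 < n_layers:
                # decimate the envelope to the rate the next layer needs
                target = max(2.5 * lb.centers[k], 4.0 * bank.f_min, 2.0)
                down = 1
                while fs_u / (down * 2) >= target and uc.size // (down * 2) > 8:
                    down *= 2
                ud = (sps.resample_poly(uc, 1, down, padtype="line")
                      if down > 1 else uc)
                process(ud, fs_u / down, layer + 1, path)

    process(x, fs, 0, ())

    S = tuple(np.vstack(p) if p else np.zeros((0, n_frames))
              for p in S_paths)
    U = tuple(np.vstack(p) if p else np.zeros((0, u_len)) for p in U_paths)
    return ScatteringOutput(
        S=S, U=U,
        path_meta=tuple(tuple(m) for m in meta),
        frame_starts=frame_starts,
        layer_u_energy=tuple(u_energy),
        config=config,
    )


def align_frames(output: ScatteringOutput, n_frames: int) -> ScatteringOutput:
    """Fourier-interpolate every S and U matrix to ``n_frames`` time points.

    Matrices already at the target length are passed through unchanged;
    constant rows stay constant (only the DC bin is nonzero).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    def fix(mat: np.ndarray) -> np.ndarray:
        if mat.shape[1] == n_frames or mat.shape[0] == 0:
            return mat if mat.shape[1] == n_frames else np.zeros((0, n_frames))
        return sps.resample(mat, n_frames, axis=1)

    hop = output.config.hop_s
    return replace(output,
                   S=tuple(fix(m) for m in output.S),
                   U=tuple(fix(m) for m in output.U),
                   frame_starts=np.arange(n_frames) * hop)
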