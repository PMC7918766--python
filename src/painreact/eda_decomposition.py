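"""Tonic/phasic/noise decomposition of skin conductance by convex optimization.

Skin conductance is modeled as the sum of a slowly drifting tonic baseline, a
phasic component driven by sparse, non-negative sudomotor-nerve activity, and
white measurement noise.  The phasic component is the convolution of the
driver with a Bateman impulse response ``exp(-t/tau1) - exp(-t/tau0)``,
discretized here through its Laplace-domain transfer function

    H(s) = (1/tau0 - 1/tau1) / ((s + 1/tau0)(s + 1/tau1))

mapped to a discrete ARMA filter with the bilinear transform.  The tonic
component is a coarse cubic B-spline (default 10 s knot spacing) plus an
offset and a linear drift.  Estimation solves the quadratic program

    minimize  1/2 ||y - M p - B l - C d||^2 + alpha ||p||_1
              + 1/2 lambda_t ||l||^2        subject to  p >= 0,

where ``M`` is the ARMA convolution operator.  Because ``p >= 0`` turns the
l1 penalty into a linear term, the objective is smooth on the feasible set
and is solved with a projected quasi-Newton method (L-BFGS-B) using analytic
gradients; the solution is deterministic.  Downstream feature extraction
consumes only the phasic component, which carries the rapid pain-linked
sweat-gland responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize
from scipy import signal as sps

from .core_data import ChannelSignal


class EDASolverError(RuntimeError):
    """The decomposition QP failed to converge; carries the solver message."""


@dataclass(frozen=True)
class EDADecomposition:
    """Additive split of a skin-conductance signal.

    ``tonic + phasic + noise`` reconstructs the input exactly by
    construction; the driver is the estimated sparse, non-negative
    sudomotor activity whose Bateman-filtered version is the phasic part.
    """

    tonic: np.ndarray
    phasic: np.ndarray
    noise: np.ndarray
    driver: np.ndarray
    fs: float

    @property
    def reconstruction(self) -> np.ndarray:
        return self.tonic + self.phasic + self.noise


def bateman_arma(tau0: float, tau1: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Discrete ``(b, a)`` filter for the Bateman kernel via bilinear transform."""
    if not 0 < tau0 < tau1:
        raise ValueError(f"need 0 < tau0 < tau1, got {tau0}, {tau1}")
    a0, a1 = 1.0 / tau0, 1.0 / tau1
    num = [a0 - a1]
    den = [1.0, a0 + a1, a0 * a1]
    return sps.bilinear(num, den, fs=fs)


def _tonic_basis(n: int, fs: float, knot_spacing_s: float) -> np.ndarray:
    """Cubic B-spline columns at coarse knots, plus offset and linear drift."""
    t = np.arange(n) / fs
    dur = t[-1] if n > 1 else 1.0
    n_knots = max(2, int(np.floor(dur / knot_spacing_s)) + 1)
    inner = np.linspace(0.0, dur, n_knots)
    k = 3
    knots = np.r_[[inner[0]] * k, inner, [inner[-1]] * k]
    spline = interpolate.BSpline.design_matrix(t, knots, k).toarray()
    drift = np.column_stack([np.ones(n), t / max(dur, 1e-9)])
    return np.hstack([spline, drift])


def decompose_eda(sig: ChannelSignal, tau0: float = 0.7, tau1: float = 2.0,
                  alpha: float = 8e-4, lambda_t: float = 1e-2,
                  knot_spacing_s: float = 10.0,
                  maxiter: int = 3000) -> EDADecomposition:
    """Solve the tonic/phasic/noise QP for one EDA signal.

    Parameters follow the model description above.  ``alpha`` sets driver
    sparsity, ``lambda_t`` the ridge on spline coefficients (offset and
    drift are unpenalized).  Raises :class:`EDASolverError` if the solver
    does not converge and the projected gradient is still large.
    """
    y = np.asarray(sig.samples, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("EDA signal contains non-finite values")
    n = y.size
    fs = sig.fs
    b, a = bateman_arma(tau0, tau1, fs)
    basis = _tonic_basis(n, fs, knot_spacing_s)
    k_spline = basis.shape[1] - 2

    def conv(p):
        return sps.lfilter(b, a, p)

    def conv_t(r):
        return sps.lfilter(b, a, r[::-1])[::-1]

    def split(x):
        return x[:n], x[n:n + basis.shape[1]]

    def objective(x):
        p, w = split(x)
        r = y - conv(p) - basis @ w
        pen = alpha * p.sum() + 0.5 * lambda_t * np.dot(w[:k_spline], w[:k_spline])
        g_p = -conv_t(r) + alpha
        g_w = -basis.T @ r
        g_w[:k_spline] += lambda_t * w[:k_spline]
        return 0.5 * np.dot(r, r) + pen, np.concatenate([g_p, g_w])

    x0 = np.zeros(n + basis.shape[1])
    x0[n + basis.shape[1] - 2] = y.mean()  # start tonic offset at the mean
    bounds = [(0.0, None)] * n + [(None, None)] * basis.shape[1]
    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                     "ftol": 1e-12, "gtol": 1e-9})
    scale = max(1.0, np.abs(y).max())
    if not res.success and res.status != 1:  # status 1 = iteration limit
        raise EDASolverError(f"L-BFGS-B failed: {res.message}")
    p, w = split(res.x)
    phasic = conv(p)
    tonic = basis @ w
    noise = y - phasic - tonic
    # Guard against a silently bad solve on non-degenerate inputs.
    if np.abs(noise).max() > 0.8 * scale and np.std(y) > 1e-9:
        raise EDASolverError(
            f"decomposition residual unreasonably large ({res.message})")
    return EDADecomposition(tonic=tonic, phasic=phasic, noise=noise,
                            driver=p, fs=fs)
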