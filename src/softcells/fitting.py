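"""Model fits shared across the analysis: VFT, stretched exponential
(KWW), and the Gaussian master curve for P(ln τα).

The VFT (Vogel–Fulcher–Tammann) law for a glass-forming packing,

    y(ϕ) = y0 · exp[ D / (ϕ0/ϕ − 1) ],

diverges at the ideal-glass packing fraction ϕ0 with apparent activation
strength D; it is fitted in log space, where the model is linear in
(ln y0, D) at fixed ϕ0, so a 1-D profile search over ϕ0 followed by a
nonlinear polish is robust even for y spanning many decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

__all__ = [
    "FitResult",
    "fit_vft",
    "vft",
    "fit_stretched_exponential",
    "stretched_exponential",
    "fit_gaussian_log_tau",
    "estimate_phi_s",
]


@dataclass
class FitResult:
    params: dict[str, float]
    stderr: dict[str, float]
    resid_norm: float
    converged: bool
    n_points: int
    window: Optional[tuple[float, float]] = None
    extras: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


# ----------------------------------------------------------------------
# stretched exponential


def stretched_exponential(t, C_s, tau, beta):
    return C_s * np.exp(-((np.asarray(t, dtype=float) / tau) ** beta))


def fit_stretched_exponential(
    t: np.ndarray,
    y: np.ndarray,
    p0: Optional[Sequence[float]] = None,
    window: Optional[tuple[float, float]] = None,
    beta_bounds: tuple[float, float] = (1e-3, 2.0),
) -> FitResult:
    """Nonlinear least squares of C_s·exp[−(t/τ)^β], β constrained to (0, 2].

    ``window`` restricts the fit to t inside [lo, hi]; ``beta_bounds``
    can narrow the exponent range (noisy plateaus admit degenerate
    β → 0 solutions whose extrapolated tail integral diverges).
    Non-convergence is reported via converged=False together with
    scipy's message.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if t.size < 3:
        raise ValueError("need at least 3 points to fit 3 parameters")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")

    # fit on a normalised scale: tiny absolute magnitudes (reduced stress
    # units) otherwise run into finite-difference step problems
    y_scale = float(np.max(np.abs(y)))
    if y_scale <= 0:
        raise ValueError("cannot fit an all-zero series")
    ys = y / y_scale

    if p0 is None:
        c0 = max(float(ys[0]), 1e-3)
        # crude 1/e crossing for the timescale guess
        below = np.nonzero(ys < c0 * np.exp(-1.0))[0]
        tau0 = float(t[below[0]]) if below.size else float(t[-1])
        tau0 = max(tau0, float(t[t > 0].min()) if np.any(t > 0) else 1.0)
        p0 = (c0, tau0, 0.7)
    else:
        p0 = (p0[0] / y_scale, p0[1], p0[2])

    names = ("C_s", "tau", "beta")
    try:
        p0 = (p0[0], p0[1], float(np.clip(p0[2], *beta_bounds)))
        popt, pcov = curve_fit(
            stretched_exponential, t, ys, p0=p0,
            bounds=([0.0, 1e-12, beta_bounds[0]],
                    [np.inf, np.inf, beta_bounds[1]]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        return FitResult(
            params={"C_s": p0[0] * y_scale, "tau": p0[1], "beta": p0[2]},
            stderr={k: np.nan for k in names},
            resid_norm=np.nan,
            converged=False,
            n_points=t.size,
            window=window,
            extras={"message": str(err)},
        )
    resid = ys - stretched_exponential(t, *popt)
    stderr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    popt = (popt[0] * y_scale, popt[1], popt[2])
    stderr = (stderr[0] * y_scale, stderr[1], stderr[2])
    return FitResult(
        params=dict(zip(names, popt)),
        stderr=dict(zip(names, stderr)),
        resid_norm=float(np.linalg.norm(resid) * y_scale),
        converged=True,
        n_points=t.size,
        window=window,
    )


# ----------------------------------------------------------------------
# VFT


def vft(phi, y0, D, phi0):
    """VFT law; refuses evaluation at or beyond the divergence ϕ0."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= phi0):
        raise ValueError("VFT is only defined for phi < phi0")
    return y0 * np.exp(D / (phi0 / phi - 1.0))


def _vft_profile(phi, log_y, w, phi0):
    """Weighted linear LSQ of ln y = ln y0 + D·x at fixed ϕ0.
    Returns (ln y0, D, weighted SSR)."""
    x = 1.0 / (phi0 / phi - 1.0)
    A = np.column_stack([np.ones_like(x), x]) * np.sqrt(w)[:, None]
    b = log_y * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    ssr = float(np.sum((A @ coef - b) ** 2))
    return coef[0], coef[1], ssr


def fit_vft(
    phi: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray] = None,
    phi_max_fit: Optional[float] = None,
    phi0_bounds: Optional[tuple[float, float]] = None,
) -> FitResult:
    """Fit y(ϕ) = y0·exp[D/(ϕ0/ϕ − 1)] in log space.

    ``phi_max_fit`` restricts the window (the VFT regime ends at the
    saturation packing fraction ϕ_S; points beyond it are excluded from
    the fit by default the caller supplies ϕ_S).  Weights are relative
    inverse variances of ln y.  A ϕ0 estimate at the search boundary is
    flagged in extras["phi0_at_boundary"].
    """
    phi = np.asarray(phi, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive (fit runs in log space)")
    w = np.ones_like(phi) if weights is None else np.asarray(weights, float)
    if phi_max_fit is not None:
        m = phi <= phi_max_fit
        phi, y, w = phi[m], y[m], w[m]
    if phi.size < 4:
        raise ValueError("need at least 4 points for a 3-parameter VFT fit")
    log_y = np.log(y)

    lo, hi = phi0_bounds or (float(phi.max()) + 5e-3, 1.1)
    res = minimize_scalar(
        lambda p0: _vft_profile(phi, log_y, w, p0)[2],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    phi0 = float(res.x)
    ln_y0, D, _ = _vft_profile(phi, log_y, w, phi0)

    # polish with a full nonlinear fit in log space for joint errors
    def model(p, ln_y0, D, phi0):
        return ln_y0 + D / (phi0 / p - 1.0)

    try:
        popt, pcov = curve_fit(
            model, phi, log_y, p0=(ln_y0, D, phi0),
            sigma=1.0 / np.sqrt(w), absolute_sigma=False,
            bounds=([-np.inf, 0.0, lo], [np.inf, np.inf, hi]),
            maxfev=20_000,
        )
        converged = True
        stderr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    except RuntimeError:
        popt = np.array([ln_y0, D, phi0])
        stderr = np.full(3, np.nan)
        converged = bool(res.success)

    resid = log_y - model(phi, *popt)
    at_boundary = popt[2] <= lo + 1e-4 or popt[2] >= hi - 1e-4
    return FitResult(
        params={"y0": float(np.exp(popt[0])), "D": float(popt[1]),
                "phi0": float(popt[2])},
        stderr={"y0": float(np.exp(popt[0]) * stderr[0]),
                "D": float(stderr[1]), "phi0": float(stderr[2])},
        resid_norm=float(np.linalg.norm(resid)),
        converged=converged,
        n_points=phi.size,
        window=(float(phi.min()), float(phi.max())),
        extras={"phi0_at_boundary": bool(at_boundary)},
    )


def estimate_phi_s(
    phi: np.ndarray, y: np.ndarray, y_std: Optional[np.ndarray] = None,
    n_sigma: float = 2.0, default: float = 0.90,
) -> float:
    """Onset of saturation: the smallest ϕ beyond which all successive
    ratios of y are statistically compatible with 1.

    Falls back to ``default`` when no plateau is detected (e.g. the data
    never leave the VFT regime).
    """
    order = np.argsort(phi)
    phi = np.asarray(phi, float)[order]
    y = np.asarray(y, float)[order]
    if y_std is None:
        y_std = 0.1 * y
    else:
        y_std = np.asarray(y_std, float)[order]
    for k in range(phi.size - 1):
        diffs = np.abs(np.diff(y[k:]))
        tol = n_sigma * np.hypot(y_std[k:-1], y_std[k + 1:])
        if np.all(diffs <= tol):
            return float(phi[k])
    return default


# ----------------------------------------------------------------------
# Gaussian master curve for P(ln τα)


def _gaussian_master(x, c, ln_tau0):
    return np.exp(-c * (x - ln_tau0) ** 2)


def fit_gaussian_log_tau(
    centers: np.ndarray, scaled_density: np.ndarray
) -> FitResult:
    """Fit the peak-scaled relaxation-time histogram to
    exp[−c (ln(τα/τ0))²].

    In the glassy (pre-saturation) regime the scaled P(ln τα) follows
    this Gaussian master curve; above the saturation packing fraction it
    does not, which shows up as a large residual (returned as
    extras["gof"], the mean squared residual).
    """
    x = np.asarray(centers, dtype=float)
    y = np.asarray(scaled_density, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 histogram bins")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (flat) histogram")
    c0 = 1.0 / max(np.var(x[y > 0.5 * y.max()]), 1e-3)
    p0 = (c0, float(x[np.argmax(y)]))
    popt, pcov = curve_fit(
        _gaussian_master, x, y, p0=p0,
        bounds=([1e-6, -np.inf], [np.inf, np.inf]), maxfev=20_000,
    )
    resid = y - _gaussian_master(x, *popt)
    gof = float(np.mean(resid**2))
    stderr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return FitResult(
        params={"c": float(popt[0]), "tau0": float(np.exp(popt[1]))},
        stderr={"c": float(stderr[0]),
                "tau0": float(np.exp(popt[1]) * stderr[1])},
        resid_norm=float(np.linalg.norm(resid)),
        converged=True,
        n_points=x.size,
        extras={"gof": gof},
    )
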