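"""Effective shear viscosity via the Green–Kubo integral of the
off-diagonal stress autocorrelation.

The effective viscosity is

    η̄ = ∫₀^∞ dt Σ_(µν) ⟨P_µν(t) P_µν(0)⟩ ,

with the off-diagonal virial stress P_µν = (1/A) Σ_{i<j} r_ij,µ f_ij,ν.
There is no kinetic contribution and no A/k_BT prefactor: the dynamics
is overdamped and athermal, so η̄ is a proxy for shear viscosity in
reduced stress²·time units.  The sum over (µν) runs over xy and yx;
central forces make P_xy = P_yx, so it equals twice the xy term.

The ACF of a glassy run decays in two steps and its long-time part is
noisy, so the integral is evaluated on a spliced curve: a natural cubic
spline of the short-time data on [0, t₁] joined to a stretched-
exponential fit C_s·exp[−(t/τ_η)^β] beyond t₁, with the analytic
incomplete-gamma tail closing the integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft
from scipy.interpolate import CubicSpline
from scipy.special import gamma as gamma_fn, gammaincc

from .fitting import FitResult, fit_stretched_exponential, stretched_exponential
from .forces import forces_and_stress
from .params import SimParams
from .population import CellPopulation
from .trajectory import TrajectoryStore

__all__ = [
    "StressSample",
    "SplicedAcf",
    "virial_stress",
    "stress_autocorrelation",
    "smooth_short_time",
    "fit_long_time",
    "choose_splice_time",
    "green_kubo_viscosity",
    "stretched_exp_integral",
    "viscosity_vs_phi",
]


@dataclass
class StressSample:
    """Instantaneous virial stress components of one configuration."""

    time: float
    p_xy: float
    p_yx: float
    p_xx: float
    p_yy: float


def virial_stress(
    pop: CellPopulation, params: SimParams, time: float = 0.0
) -> StressSample:
    """P_µν = (1/A) Σ_{i<j} r_ij,µ f_ij,ν with minimum-image r_ij.

    Kinetic terms are excluded (overdamped, athermal model).  For the
    central Hertzian forces P_xy = P_yx exactly.
    """
    _, stress = forces_and_stress(pop, params)
    return StressSample(
        time=time, p_xy=stress["xy"], p_yx=stress["yx"],
        p_xx=stress["xx"], p_yy=stress["yy"],
    )


def _acf_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged autocorrelation ⟨x(t)x(0)⟩ for lags 0..max_lag."""
    n = x.size
    nfft = next_fast_len(2 * n)
    f = rfft(x, nfft)
    acov = irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / (n - np.arange(max_lag + 1))


def stress_autocorrelation(
    traj: TrajectoryStore,
    max_lag_fraction: float = 0.25,
    subtract_mean: bool = True,
):
    """Σ_(µν) ⟨P_µν(t)P_µν(0)⟩ over the off-diagonal components.

    Since P_xy = P_yx, this is 2·⟨P_xy(t)P_xy(0)⟩.  The sample mean of
    P_xy (zero in the ensemble by symmetry) is subtracted by default to
    remove the finite-run offset that would otherwise never decay.
    Lags are truncated at ``max_lag_fraction`` of the series length,
    beyond which origin averaging is too poor to be useful.
    """
    from .observables import CorrelationSeries

    s = np.asarray(traj.stress_xy, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 stress samples")
    if subtract_mean:
        s = s - s.mean()
    dt = float(np.diff(traj.stress_times).mean())
    max_lag = max(1, int(max_lag_fraction * s.size))
    acf = 2.0 * _acf_fft(s, max_lag)
    lags = np.arange(max_lag + 1)
    return CorrelationSeries(
        t=lags * dt, value=acf, n_origins=s.size - lags
    )


def smooth_short_time(
    acf, t_end: float, delta: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline of the short-time ACF resampled on a uniform
    δt grid covering [0, t_end].  The spline interpolates the input
    points exactly and has continuous first and second derivatives."""
    m = acf.t <= t_end
    if m.sum() < 4:
        raise ValueError("need at least 4 points before t_end")
    t, v = acf.t[m], acf.value[m]
    if np.any(np.diff(t) <= 0):
        raise ValueError("lag times must be strictly increasing")
    # not-a-knot ends: value/slope/curvature continuity at interior nodes
    # as required, and exact reproduction of cubic polynomials
    spline = CubicSpline(t, v, bc_type="not-a-knot")
    grid = np.arange(0.0, t_end + 0.5 * delta, delta)
    return grid, spline(grid)


def fit_long_time(
    acf, t_start: float, t_end: Optional[float] = None
) -> FitResult:
    """Stretched-exponential fit C_s·exp[−(t/τ_η)^β] on lags ≥ t_start
    (and ≤ t_end when given: the fit should cover the decay to zero, not
    an arbitrarily long stretch of statistical noise beyond it).

    β is restricted to [0.2, 2]: on noisy plateaus the unconstrained fit
    admits degenerate β → 0 solutions whose extrapolated tail integral
    blows up, which would corrupt the Green–Kubo sum silently.
    """
    m = acf.t >= t_start
    if t_end is not None:
        m &= acf.t <= t_end
    return fit_stretched_exponential(
        acf.t[m], acf.value[m], beta_bounds=(0.2, 2.0)
    )


def _sustained_drop(
    cs: np.ndarray, t: np.ndarray, floor: float, run: int
) -> Optional[float]:
    """First lag from which the series stays below ``floor`` for ``run``
    consecutive samples; None if it never does."""
    below = (cs < floor).astype(float)
    if below.size < run:
        return None
    streak = np.convolve(below, np.ones(run), mode="valid")
    idx = np.nonzero(streak >= run)[0]
    return float(t[idx[0]]) if idx.size else None


def _signal_end(acf, t_start: float, floor: float = 0.05) -> Optional[float]:
    """Where the smoothed normalised ACF has decayed into sustained
    noise below ``floor``·C(0), doubled for safety; None if never."""
    c = acf.normalized
    w = min(15, max(3, (c.size // 20) * 2 + 1))
    cs = np.convolve(c, np.ones(w) / w, mode="same")
    t_sig = _sustained_drop(cs, acf.t, floor, run=3 * w)
    if t_sig is None or t_sig <= t_start:
        return None
    return float(min(2.0 * t_sig, acf.t[-1]))


def choose_splice_time(
    acf,
    band: tuple[float, float] = (0.03, 0.85),
    smooth_window: int = 9,
) -> float:
    """Automatic splice point: the lag where the normalised ACF is
    flattest (smallest log-derivative magnitude) inside a mid-decay band.

    Reproducible stand-in for the visual plateau choice; override by
    passing an explicit t₁ to :func:`green_kubo_viscosity`.
    """
    c = acf.normalized
    t = acf.t
    if t.size < 6:
        raise ValueError("ACF too short to choose a splice point")
    below = np.nonzero(c < 0.5)[0]
    t_half = float(t[below[0]]) if below.size else 0.5 * float(t[-1])

    # smooth the normalised ACF to stabilise the derivative
    w = min(smooth_window, max(3, (t.size // 10) * 2 + 1))
    kernel = np.ones(w) / w
    cs = np.convolve(np.clip(c, 1e-3, None), kernel, mode="same")
    # confine the search between the half-decay point and the end of the
    # resolved signal (the flattest stretch of pure tail noise is not a
    # plateau)
    t_sig = _sustained_drop(cs, t, max(band[0], 0.05), run=3 * w)
    m = (cs >= band[0]) & (cs <= band[1]) & (t >= max(t_half, t[4]))
    m &= t <= (t_sig if t_sig is not None else t[-1])
    if m.sum() < 3:
        # fast featureless decay: no plateau band is resolved; splice
        # shortly after the half-decay time
        return float(max(t[4], 2.0 * t_half))
    slope = np.gradient(np.log(np.clip(cs, 1e-12, None)), t)
    idx = np.nonzero(m)[0]
    return float(max(t[idx[np.argmin(np.abs(slope[idx]))]], t[4]))


def stretched_exp_integral(
    C_s: float, tau: float, beta: float, t_from: float = 0.0
) -> float:
    """∫_{t_from}^∞ C_s exp[−(t/τ)^β] dt via the upper incomplete gamma:
    C_s (τ/β) Γ(1/β) Q(1/β, (t_from/τ)^β)."""
    a = 1.0 / beta
    x = (t_from / tau) ** beta
    return C_s * (tau / beta) * gamma_fn(a) * gammaincc(a, x)


@dataclass
class SplicedAcf:
    """Diagnostics of the spliced short-time/long-time ACF treatment."""

    t1: float                         # splice point, s
    t_short: np.ndarray               # uniform δt grid on [0, t1]
    acf_short: np.ndarray             # spline values on that grid
    fit: Optional[FitResult]          # C_s, tau, beta (None for raw tail)
    gap: float                        # |spline(t1) − fit(t1)|
    eta_short: float
    eta_long: float

    @property
    def eta(self) -> float:
        return self.eta_short + self.eta_long


def green_kubo_viscosity(
    acf,
    t1: Optional[float] = None,
    fit_start: Optional[float] = None,
    delta: float = 10.0,
    tail_rel: float = 1e-3,
    splice_rtol: float = 0.35,
    long_time: str = "fit",
) -> tuple[float, SplicedAcf]:
    """η̄ as the discrete (trapezoidal, δt grid) integral of the spliced
    ACF: spline segment on [0, t₁], stretched-exponential fit beyond,
    closed by the analytic incomplete-gamma tail once the remaining tail
    contributes less than ``tail_rel`` of the long-time integral.

    ``long_time="data"`` skips the fit and integrates the raw ACF beyond
    t₁ as-is (no tail extrapolation) — useful when the ACF has fully
    decayed inside the window or is not stretched-exponential shaped.

    Raises if the two segments disagree at t₁ by more than
    ``splice_rtol`` (relative to the larger segment value), which
    signals a badly placed splice point.
    """
    if t1 is None:
        t1 = choose_splice_time(acf)
    if fit_start is None:
        fit_start = t1

    if long_time == "data":
        t_short, acf_short = smooth_short_time(acf, t1, delta)
        eta_short = float(np.trapezoid(acf_short, t_short))
        m = acf.t >= t_short[-1]
        eta_long = float(np.trapezoid(acf.value[m], acf.t[m]))
        spliced = SplicedAcf(
            t1=t1, t_short=t_short, acf_short=acf_short, fit=None,
            gap=0.0, eta_short=eta_short, eta_long=eta_long,
        )
        return spliced.eta, spliced
    if long_time != "fit":
        raise ValueError("long_time must be 'fit' or 'data'")
    fit = fit_long_time(acf, fit_start, t_end=_signal_end(acf, fit_start))
    if not fit.converged:
        raise RuntimeError(
            f"long-time stretched-exponential fit failed: {fit.extras}"
        )
    C_s, tau, beta = fit["C_s"], fit["tau"], fit["beta"]

    t_short, acf_short = smooth_short_time(acf, t1, delta)
    v_spline = float(acf_short[-1])
    v_fit = float(stretched_exponential(t_short[-1], C_s, tau, beta))
    gap = abs(v_spline - v_fit)
    # mismatches far below the ACF amplitude are irrelevant to the integral
    scale = max(abs(v_spline), abs(v_fit), 1e-3 * abs(acf.value[0]))
    if gap > splice_rtol * scale:
        raise ValueError(
            f"spliced ACF discontinuous at t1={t1:.6g}: spline={v_spline:.6g} "
            f"vs stretched-exponential={v_fit:.6g}"
        )

    eta_short = float(np.trapezoid(acf_short, t_short))

    # integrate the fit on the grid out to T where the analytic tail is
    # negligible, then add that tail exactly
    t1_grid = float(t_short[-1])
    total_long = stretched_exp_integral(C_s, tau, beta, t1_grid)
    T = max(t1_grid + delta, tau)
    while stretched_exp_integral(C_s, tau, beta, T) > tail_rel * max(
        total_long, 1e-300
    ):
        T *= 1.5
    n_grid = int((T - t1_grid) / delta) + 2
    if n_grid > 4_000_000:          # extremely slow decay: coarsen the grid
        delta_eff = (T - t1_grid) / 4_000_000
    else:
        delta_eff = delta
    t_long = np.arange(t1_grid, T + 0.5 * delta_eff, delta_eff)
    eta_long = float(
        np.trapezoid(stretched_exponential(t_long, C_s, tau, beta), t_long)
    ) + stretched_exp_integral(C_s, tau, beta, float(t_long[-1]))

    spliced = SplicedAcf(
        t1=t1, t_short=t_short, acf_short=acf_short, fit=fit, gap=gap,
        eta_short=eta_short, eta_long=eta_long,
    )
    return spliced.eta, spliced


def _compatible(a: SimParams, b: SimParams) -> bool:
    keys = ("n_cells", "elastic_modulus_E", "poisson_nu", "gamma0",
            "mu_activity", "dt", "target_phi")
    return all(getattr(a, k) == getattr(b, k) for k in keys)


def viscosity_vs_phi(
    trajs: Sequence[TrajectoryStore], **gk_kwargs
) -> pd.DataFrame:
    """Replicate-averaged η̄ per packing fraction.

    Groups trajectories by their target ϕ (runs within a group must
    share all physical parameters), computes η̄ per replicate and
    returns a table (phi, eta_mean, eta_std, n_replicates).
    """
    groups: dict[float, list[TrajectoryStore]] = {}
    for traj in trajs:
        if traj.params is None:
            raise ValueError("trajectory lacks params metadata")
        groups.setdefault(traj.params.target_phi, []).append(traj)

    rows = []
    for phi in sorted(groups):
        runs = groups[phi]
        ref = runs[0].params
        for other in runs[1:]:
            if not _compatible(ref, other.params):
                raise ValueError(
                    f"mixed physical parameters among runs at phi={phi}"
                )
        etas = []
        for traj in runs:
            acf = stress_autocorrelation(traj)
            eta, _ = green_kubo_viscosity(acf, **gk_kwargs)
            etas.append(eta)
        etas = np.asarray(etas)
        rows.append(
            {
                "phi": phi,
                "eta_mean": etas.mean(),
                "eta_std": etas.std(ddof=1) if etas.size > 1 else 0.0,
                "n_replicates": etas.size,
            }
        )
    return pd.DataFrame(rows)
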