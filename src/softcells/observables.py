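"""Structural and dynamical observables computed from trajectories.

* pair correlation function g(r) and its first-peak position (which sets
  the probing wavevector q = 2π/r_max),
* isotropic self-intermediate scattering function Fs(q,t) from unwrapped
  displacements, globally, per cell, and restricted to chosen waiting
  times,
* α-relaxation times τα defined by Fs(q, τα) = 1/e,
* cell–cell overlap statistics P(h_ij), ⟨h_ij⟩.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.special import j0

from .trajectory import TrajectoryStore

__all__ = [
    "CorrelationSeries",
    "RadialDistribution",
    "pair_correlation",
    "first_peak_position",
    "self_intermediate_scattering",
    "relaxation_time",
    "per_cell_relaxation_times",
    "log_tau_histogram",
    "LogTauHistogram",
    "waiting_time_fs",
    "overlap_distribution",
    "OverlapStats",
]

INV_E = float(np.exp(-1.0))


@dataclass
class CorrelationSeries:
    """A (lag time, value) series with the number of time origins per lag."""

    t: np.ndarray
    value: np.ndarray
    n_origins: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("lag times must strictly increase from 0")
        if np.any(self.n_origins < 1):
            raise ValueError("each lag needs at least one origin")

    @property
    def normalized(self) -> np.ndarray:
        return self.value / self.value[0]


@dataclass
class RadialDistribution:
    r: np.ndarray          # bin centres, µm
    g: np.ndarray
    bin_width: float


# ----------------------------------------------------------------------
# structure


def pair_correlation(
    traj: TrajectoryStore,
    bin_width: float = 0.5,
    r_max: Optional[float] = None,
) -> RadialDistribution:
    """Radial distribution function g(r), averaged over frames.

    Shell- and density-normalised histogram of all minimum-image pair
    distances (all cells, regardless of radius):

        g(r) = (1/ρ) ⟨ (1/N) Σ_i Σ_{j≠i} δ(r − |r_i − r_j|) ⟩,  ρ = N/L².
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    L = traj.box_length
    if r_max is None:
        r_max = 0.499 * L
    if r_max > 0.5 * L:
        raise ValueError("r_max must not exceed L/2 (minimum image)")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    wrapped = traj.positions_wrapped
    N = traj.n_cells
    for k in range(traj.n_frames):
        tree = cKDTree(np.mod(wrapped[k], L), boxsize=L)
        pairs = tree.query_pairs(edges[-1], output_type="ndarray")
        if pairs.size == 0:
            continue
        dr = wrapped[k][pairs[:, 0]] - wrapped[k][pairs[:, 1]]
        dr -= L * np.round(dr / L)
        d = np.hypot(dr[:, 0], dr[:, 1])
        counts += np.histogram(d, bins=edges)[0]

    rho = N / L**2
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    # factor 2: query_pairs counts unordered pairs, g uses ordered sums
    g = 2.0 * counts / (traj.n_frames * N * rho * shell)
    centres = 0.5 * (edges[1:] + edges[:-1])
    return RadialDistribution(r=centres, g=g, bin_width=bin_width)


def first_peak_position(
    g: RadialDistribution,
    prominence_frac: float = 0.05,
    smooth_bins: int = 3,
) -> float:
    """Position of the first local maximum of g(r), sub-bin refined.

    The histogram is lightly smoothed (``smooth_bins``-bin moving
    average) before peak finding so that single-bin sampling noise on
    the rising flank cannot masquerade as the first peak; peaks must
    then exceed a prominence of ``prominence_frac`` times the g-range,
    and a parabola through the peak bin and its neighbours refines the
    position below the bin width.
    """
    y = g.g
    if smooth_bins > 1:
        pad = smooth_bins // 2
        padded = np.concatenate([
            np.full(pad, y[0]), y, np.full(pad, y[-1])
        ])
        y = np.convolve(
            padded, np.ones(smooth_bins) / smooth_bins, mode="valid"
        )[: y.size]
    rng = float(y.max() - y.min())
    idx, _ = find_peaks(y, prominence=prominence_frac * rng)
    if idx.size == 0:
        raise ValueError("no peak exceeding the prominence threshold")
    k = int(idx[0])
    if 0 < k < y.size - 1:
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0.0:
            shift = 0.5 * (y0 - y2) / denom
            return float(g.r[k] + np.clip(shift, -0.5, 0.5) * g.bin_width)
    return float(g.r[k])


# ----------------------------------------------------------------------
# self-intermediate scattering function


def _log_lags(n_frames: int, per_decade: int = 12) -> np.ndarray:
    """Logarithmically spaced frame-index lags, always including 0 and 1."""
    max_lag = n_frames - 1
    if max_lag < 1:
        return np.array([0])
    n_pts = max(2, int(np.ceil(per_decade * np.log10(max_lag + 1))))
    lags = np.unique(
        np.round(np.geomspace(1, max_lag, n_pts)).astype(int)
    )
    return np.concatenate(([0], lags))


def _fs_per_cell(
    traj: TrajectoryStore,
    q: float,
    lags: Optional[np.ndarray] = None,
    max_origins: int = 200,
    origin_window: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell isotropic Fs on a set of frame lags.

    The isotropic estimator uses the 2D closed form: averaging
    exp(−i q·Δr) over all directions of q gives J0(q |Δr|).

    Returns (lag indices, per-cell matrix of shape (n_lags, N),
    origins per lag).  ``origin_window`` restricts admissible time
    origins to a frame-index range [i0, i1).
    """
    if q <= 0:
        raise ValueError("q must be positive")
    F = traj.n_frames
    if lags is None:
        lags = _log_lags(F)
    pos = traj.positions_unwrapped
    i0, i1 = (0, F) if origin_window is None else origin_window

    keep, values, n_origins = [], [], []
    for lag in lags:
        hi = min(i1, F - lag)
        if hi <= i0:
            continue
        origins = np.arange(i0, hi)
        if origins.size > max_origins:
            stride = int(np.ceil(origins.size / max_origins))
            origins = origins[::stride]
        dr = pos[origins + lag] - pos[origins]       # (n_o, N, 2)
        r = np.hypot(dr[..., 0], dr[..., 1])
        values.append(j0(q * r).mean(axis=0))
        n_origins.append(origins.size)
        keep.append(lag)
    return np.asarray(keep), np.asarray(values), np.asarray(n_origins)


def self_intermediate_scattering(
    traj: TrajectoryStore,
    q: float,
    per_decade: int = 12,
    max_origins: int = 200,
) -> CorrelationSeries:
    """Isotropic Fs(q,t) averaged over cells and time origins.

    Uses unwrapped displacements (wrapped coordinates would saturate the
    decay at the box scale).  Fs(q, 0) = 1 exactly; |Fs| ≤ 1.
    """
    lags, per_cell, n_or = _fs_per_cell(
        traj, q, _log_lags(traj.n_frames, per_decade), max_origins
    )
    dt_frame = np.diff(traj.frame_times).mean() if traj.n_frames > 1 else 0.0
    return CorrelationSeries(
        t=lags * dt_frame, value=per_cell.mean(axis=1), n_origins=n_or
    )


def relaxation_time(fs: CorrelationSeries) -> Optional[float]:
    """First crossing of 1/e, or None if the series never relaxes.

    Interpolates log-linearly (linear in ln t) between the bracketing
    lags; falls back to linear interpolation when the left bracket is
    t = 0.
    """
    below = np.nonzero(fs.value < INV_E)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    if k == 0:
        return float(fs.t[0])
    t0, t1 = fs.t[k - 1], fs.t[k]
    v0, v1 = fs.value[k - 1], fs.value[k]
    frac = (v0 - INV_E) / (v0 - v1)
    if t0 <= 0.0:
        return float(t0 + frac * (t1 - t0))
    return float(np.exp(np.log(t0) + frac * (np.log(t1) - np.log(t0))))


def per_cell_relaxation_times(
    traj: TrajectoryStore,
    q: float,
    per_decade: int = 12,
    max_origins: int = 200,
) -> pd.DataFrame:
    """Single-cell τα spectrum: columns radius, tau_alpha, relaxed.

    Each cell's own Fs (averaged over time origins only) is crossed at
    1/e.  Cells whose Fs never reaches 1/e within the window are
    censored: relaxed=False and tau_alpha=NaN.  The mean over cells of
    the per-cell Fs equals the global estimator by construction.
    """
    lags, per_cell, n_or = _fs_per_cell(
        traj, q, _log_lags(traj.n_frames, per_decade), max_origins
    )
    dt_frame = np.diff(traj.frame_times).mean()
    taus = np.full(traj.n_cells, np.nan)
    relaxed = np.zeros(traj.n_cells, dtype=bool)
    for i in range(traj.n_cells):
        series = CorrelationSeries(
            t=lags * dt_frame, value=per_cell[:, i], n_origins=n_or
        )
        tau = relaxation_time(series)
        if tau is not None:
            taus[i] = tau
            relaxed[i] = True
    return pd.DataFrame(
        {"radius": traj.radii, "tau_alpha": taus, "relaxed": relaxed}
    )


@dataclass
class LogTauHistogram:
    """Normalised histogram of ln τα and its peak-scaled master form."""

    centers: np.ndarray      # ln(τα)
    density: np.ndarray      # P(ln τα), integrates to 1
    scaled: np.ndarray       # P / P_max
    n_finite: int
    n_censored: int


def log_tau_histogram(
    taus: np.ndarray, bins: int | str = "fd"
) -> LogTauHistogram:
    """Distribution of ln τα over cells; censored cells are excluded
    from the histogram but counted."""
    taus = np.asarray(taus, dtype=float)
    finite = taus[np.isfinite(taus) & (taus > 0)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite relaxation times")
    log_tau = np.log(finite)
    density, edges = np.histogram(log_tau, bins=bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return LogTauHistogram(
        centers=centers,
        density=density,
        scaled=density / density.max(),
        n_finite=int(finite.size),
        n_censored=int(taus.size - finite.size),
    )


def waiting_time_fs(
    traj: TrajectoryStore,
    q: float,
    tau_w_list: Sequence[float],
    origin_span: float | None = None,
    per_decade: int = 12,
    max_origins: int = 200,
) -> dict[float, CorrelationSeries]:
    """Fs(q, t) with time origins restricted to start near each waiting
    time τω — the aging diagnostic.  For stationary dynamics all curves
    collapse; aging shows up as slower decay at larger τω.

    ``origin_span`` is the width (in seconds) of the origin window
    following each τω (default: one frame, i.e. a single origin per
    curve would be noisy — defaults to 5% of the trajectory length).
    """
    dt_frame = float(np.diff(traj.frame_times).mean())
    total = traj.frame_times[-1]
    if origin_span is None:
        origin_span = 0.05 * total
    out: dict[float, CorrelationSeries] = {}
    for tau_w in tau_w_list:
        if tau_w + origin_span >= total:
            raise ValueError(
                f"waiting time {tau_w} + origin span exceeds the trajectory"
            )
        i0 = int(np.searchsorted(traj.frame_times, tau_w))
        i1 = max(i0 + 1,
                 int(np.searchsorted(traj.frame_times, tau_w + origin_span)))
        max_lag = traj.n_frames - 1 - i1
        if max_lag < 1:
            raise ValueError("insufficient trajectory beyond the last origin")
        lags, per_cell, n_or = _fs_per_cell(
            traj, q, _log_lags(max_lag + 1, per_decade), max_origins,
            origin_window=(i0, i1),
        )
        out[float(tau_w)] = CorrelationSeries(
            t=lags * dt_frame, value=per_cell.mean(axis=1), n_origins=n_or
        )
    return out


# ----------------------------------------------------------------------
# overlaps


@dataclass
class OverlapStats:
    bin_centers: np.ndarray   # µm
    density: np.ndarray       # P(h) over contacting pairs, integrates to 1
    mean_h: float             # ⟨h_ij⟩ = ∫ h P(h) dh, µm
    n_pairs: int              # contacting pair-frame samples


def overlap_distribution(
    traj: TrajectoryStore, bins: int | str = "fd", every: int = 1
) -> OverlapStats:
    """P(h_ij) over all contacting pairs (h > 0) and frames, plus ⟨h_ij⟩.

    An empty histogram (no contacts anywhere) yields mean 0.
    """
    L = traj.box_length
    rmax = 2.0 * float(traj.radii.max())
    wrapped = traj.positions_wrapped
    hs = []
    for k in range(0, traj.n_frames, every):
        tree = cKDTree(np.mod(wrapped[k], L), boxsize=L)
        pairs = tree.query_pairs(rmax, output_type="ndarray")
        if pairs.size == 0:
            continue
        dr = wrapped[k][pairs[:, 0]] - wrapped[k][pairs[:, 1]]
        dr -= L * np.round(dr / L)
        d = np.hypot(dr[:, 0], dr[:, 1])
        h = traj.radii[pairs[:, 0]] + traj.radii[pairs[:, 1]] - d
        hs.append(h[h > 0])
    if not hs:
        return OverlapStats(np.empty(0), np.empty(0), 0.0, 0)
    h_all = np.concatenate(hs)
    density, edges = np.histogram(h_all, bins=bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return OverlapStats(
        bin_centers=centers,
        density=density,
        mean_h=float(h_all.mean()),
        n_pairs=int(h_all.size),
    )
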