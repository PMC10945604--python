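"""Small deterministic fixtures for tests and demos.

Every fixture is generated programmatically (no data files) and is
bit-reproducible for a given seed.  The synthetic trajectories are
labelled synthetic: they are constructed stochastic processes with known
closed-form statistics, not simulation output.
"""

from __future__ import annotations

import numpy as np

from .params import RadiusDistributionSpec, SimParams
from .population import CellPopulation
from .trajectory import TrajectoryStore

__all__ = ["make_fixture", "gaussian_series_with_acf", "FIXTURE_NAMES"]


def gaussian_series_with_acf(
    acf: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian series with a prescribed autocovariance.

    Circulant-embedding construction: the target ACF (lags 0..n−1) is
    embedded in a circulant covariance whose eigenvalues are its FFT;
    negative eigenvalues (embedding not strictly valid) are clipped,
    which is harmless for smooth decaying ACFs.
    """
    acf = np.asarray(acf, dtype=float)
    n = acf.size
    circ = np.concatenate([acf, acf[-2:0:-1]])
    m = circ.size
    lam = np.clip(np.fft.fft(circ).real, 0.0, None)
    xi = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    z = np.fft.fft(np.sqrt(lam / m) * xi)
    return z.real[:n]


def _pair_h1() -> CellPopulation:
    # two R=8.5 cells at centre distance 16 -> overlap h = 1 µm exactly
    pos = np.array([[42.0, 50.0], [58.0, 50.0]])
    return CellPopulation(
        radii=np.array([8.5, 8.5]), positions=pos, box_length=100.0
    )


def _lattice16() -> CellPopulation:
    # 4x4 square lattice, spacing 20 > 2R = 17: no overlaps, zero forces
    xs = np.arange(4) * 20.0 + 10.0
    gx, gy = np.meshgrid(xs, xs)
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    return CellPopulation(
        radii=np.full(16, 8.5), positions=pos, box_length=80.0
    )


def _random10(seed: int = 1234) -> CellPopulation:
    params = SimParams(n_cells=10, target_phi=0.5, rng_seed=seed)
    return CellPopulation.random(params, RadiusDistributionSpec(), seed)


def _gauss_traj(seed: int = 1234) -> TrajectoryStore:
    """Synthetic free-diffusion trajectory: independent Gaussian steps
    of per-component std 0.5 µm per frame (frame spacing 10 s), so the
    displacement variance per component after t is 0.025·t µm².
    Closed form: Fs(q,t) = exp(−q² σ²(t) / 2)."""
    rng = np.random.default_rng(seed)
    n_frames, n_cells, sigma_step = 512, 200, 0.5
    steps = rng.normal(0.0, sigma_step, size=(n_frames - 1, n_cells, 2))
    pos = np.concatenate(
        [np.zeros((1, n_cells, 2)), np.cumsum(steps, axis=0)], axis=0
    )
    pos += 500.0  # start mid-box
    return TrajectoryStore(
        frame_times=np.arange(n_frames) * 10.0,
        positions_unwrapped=pos,
        radii=np.full(n_cells, 8.5),
        box_length=1000.0,
    )


def _acf_stretch_b06(seed: int = 1234) -> TrajectoryStore:
    """Synthetic stress series whose ACF is exp[−(t/300 s)^0.6]
    (unit variance), carried by a minimal two-frame trajectory."""
    rng = np.random.default_rng(seed)
    n, dt = 16384, 10.0
    t = np.arange(n) * dt
    target = np.exp(-((t / 300.0) ** 0.6))
    series = gaussian_series_with_acf(target, rng)
    return TrajectoryStore(
        frame_times=np.array([0.0, dt]),
        positions_unwrapped=np.full((2, 1, 2), 50.0),
        radii=np.array([8.5]),
        box_length=100.0,
        stress_times=np.arange(1, n + 1) * dt,
        stress_xy=series,
    )


_REGISTRY = {
    "pair_h1": _pair_h1,
    "lattice16": _lattice16,
    "random10": _random10,
    "gauss_traj": _gauss_traj,
    "acf_stretch_b06": _acf_stretch_b06,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str, **kwargs):
    """Build a named deterministic fixture.

    Available: pair_h1, lattice16, random10 (CellPopulation);
    gauss_traj, acf_stretch_b06 (synthetic TrajectoryStore).
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder(**kwargs)
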