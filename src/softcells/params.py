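"""Model parameters and cell-radius distributions.

The model describes a non-confluent 2D tissue as N polydisperse soft disks
in a periodic square box. All lengths are in micrometres, times in seconds,
elastic moduli in MPa and friction in kg/(µm·s); with these choices the
overdamped velocity F/γ comes out directly in µm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["SimParams", "RadiusDistributionSpec", "sample_radii"]


@dataclass
class SimParams:
    """Physical and numerical parameters of a simulation run.

    Defaults are the reference parameter set of the model: timestep
    Δt = 10 s, self-propulsion amplitude µ = 0.045 µm/√s, friction
    prefactor γ0 = 0.1 kg/(µm·s), elastic modulus E = 10⁻³ MPa and
    Poisson ratio ν = 0.5.  The friction of cell i is γ0·R_i, so small
    cells are more mobile.

    Note on units of µ: the noise is delta-correlated, so in the
    Euler–Maruyama discretisation the per-step kick is µ·√Δt·ξ with
    ξ ~ N(0,1) per component; dimensional consistency then requires µ
    in µm/√s (the characteristic time ⟨R⟩²/µ² is a time only with this
    convention).  The numeric value is kept as printed.
    """

    n_cells: int = 500
    target_phi: float = 0.93
    elastic_modulus_E: float = 1e-3   # MPa
    poisson_nu: float = 0.5
    gamma0: float = 0.1               # kg/(µm·s)
    mu_activity: float = 0.045        # µm/√s
    dt: float = 10.0                  # s
    box_length_L: Optional[float] = None  # µm; derived from radii if None
    rng_seed: int = 0
    n_steps_grow: int = 5_000
    n_steps_equil: int = 20_000
    n_steps_prod: int = 10_000
    save_every: int = 100
    stress_every: int = 1
    max_step_disp: Optional[float] = None  # µm; default: max radius

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 < self.target_phi < 1.0:
            raise ValueError("target_phi must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("elastic_modulus_E", "gamma0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_activity < 0:
            raise ValueError("mu_activity must be non-negative")
        if not 0.0 <= self.poisson_nu < 1.0:
            raise ValueError("poisson_nu must lie in [0, 1)")
        for name in ("n_steps_grow", "n_steps_equil", "n_steps_prod"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.save_every < 1 or self.stress_every < 1:
            raise ValueError("save_every and stress_every must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class RadiusDistributionSpec:
    """Specification of the cell-radius distribution.

    kind:
        "monodisperse" — all radii equal to ``mean_radius`` (reference
        value 8.5 µm).
        "binary"       — 1:1 mixture of two radii with large/small ratio
        ``size_ratio`` and mean ``mean_radius``.
        "polydisperse" — log-normal in radius truncated to
        [min_radius, max_radius]; the location parameter is solved so the
        truncated mean equals ``mean_radius``.  The default bounds give a
        max/min size ratio of 8, mimicking the broad spread of projected
        cell sizes seen in embryonic tissue.
    """

    kind: str = "polydisperse"
    mean_radius: float = 8.5     # µm
    sigma_log: float = 0.40      # log-normal shape (polydisperse)
    size_ratio: float = 1.4      # large/small (binary)
    min_radius: float = 3.0      # µm (polydisperse truncation)
    max_radius: float = 24.0     # µm

    def __post_init__(self) -> None:
        if self.kind not in ("monodisperse", "binary", "polydisperse"):
            raise ValueError(f"unknown radius distribution kind {self.kind!r}")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.kind == "polydisperse":
            if not 0 < self.min_radius < self.max_radius:
                raise ValueError("need 0 < min_radius < max_radius")
            if not self.min_radius < self.mean_radius < self.max_radius:
                raise ValueError("mean_radius must lie inside the bounds")
            if self.sigma_log <= 0:
                raise ValueError("sigma_log must be positive")
        if self.kind == "binary" and self.size_ratio <= 0:
            raise ValueError("size_ratio must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadiusDistributionSpec":
        return cls(**d)


def _truncated_lognormal_mean(mu_ln: float, sigma: float,
                              a: float, b: float) -> float:
    # E[R | a < R < b] for ln R ~ N(mu_ln, sigma^2)
    la, lb = np.log(a), np.log(b)
    z_a, z_b = (la - mu_ln) / sigma, (lb - mu_ln) / sigma
    mass = norm.cdf(z_b) - norm.cdf(z_a)
    num = np.exp(mu_ln + 0.5 * sigma**2) * (
        norm.cdf(z_b - sigma) - norm.cdf(z_a - sigma)
    )
    return num / mass


def _solve_lognormal_location(spec: RadiusDistributionSpec) -> float:
    """Location µ_ln of the underlying normal such that the truncated
    mean equals spec.mean_radius."""
    target = spec.mean_radius

    def f(mu_ln: float) -> float:
        return _truncated_lognormal_mean(
            mu_ln, spec.sigma_log, spec.min_radius, spec.max_radius
        ) - target

    lo = np.log(spec.min_radius) - 3 * spec.sigma_log
    hi = np.log(spec.max_radius) + 3 * spec.sigma_log
    return brentq(f, lo, hi, xtol=1e-12)


def sample_radii(spec: RadiusDistributionSpec, n: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` cell radii (µm) from the configured distribution.

    Deterministic given the seed.  Polydisperse radii are rejection-sampled
    from the truncated log-normal, so every radius lies inside
    [min_radius, max_radius] exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    if spec.kind == "monodisperse":
        return np.full(n, spec.mean_radius)

    if spec.kind == "binary":
        # 1:1 composition is forced, not sampled
        r_small = 2.0 * spec.mean_radius / (1.0 + spec.size_ratio)
        r_large = spec.size_ratio * r_small
        radii = np.empty(n)
        radii[0::2] = r_small
        radii[1::2] = r_large
        return radii

    mu_ln = _solve_lognormal_location(spec)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu_ln, spec.sigma_log, size=2 * (n - filled) + 8)
        keep = draw[(draw >= spec.min_radius) & (draw <= spec.max_radius)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out
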