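"""The simulation state: radii and positions of N cells on a 2D torus."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import RadiusDistributionSpec, SimParams, sample_radii

__all__ = [
    "CellPopulation",
    "box_length_for_phi",
    "packing_fraction",
    "pair_overlap",
    "minimum_image",
]


def box_length_for_phi(radii: np.ndarray, phi: float) -> float:
    """Box side L such that Σ πR_i² / L² equals ``phi`` exactly."""
    return float(np.sqrt(np.sum(np.pi * radii**2) / phi))


@dataclass
class CellPopulation:
    """Radii and (wrapped) positions of N cells in a periodic square box.

    ``positions`` live in the primary image [0, L)²; ``positions_unwrapped``
    accumulate true displacements and are required by displacement-based
    observables (mean-squared displacement, Fs(q,t)).
    """

    radii: np.ndarray
    positions: np.ndarray
    box_length: float
    positions_unwrapped: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.radii.size, 2):
            raise ValueError("positions must have shape (N, 2)")
        if self.box_length <= 2.0 * self.radii.max():
            raise ValueError("box must be larger than twice the largest cell")
        self.positions = np.mod(self.positions, self.box_length)
        if self.positions_unwrapped is None:
            self.positions_unwrapped = self.positions.copy()

    @property
    def n_cells(self) -> int:
        return self.radii.size

    @property
    def phi(self) -> float:
        return packing_fraction(self)

    @classmethod
    def random(
        cls,
        params: SimParams,
        spec: RadiusDistributionSpec | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> "CellPopulation":
        """Radii sampled from ``spec``, positions uniform in the box.

        The box length is taken from ``params.box_length_L`` or derived
        from the radii so the packing fraction equals ``params.target_phi``.
        """
        if spec is None:
            spec = RadiusDistributionSpec()
        if rng is None:
            rng = np.random.default_rng(params.rng_seed)
        elif not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        radii = sample_radii(spec, params.n_cells, rng)
        L = params.box_length_L or box_length_for_phi(radii, params.target_phi)
        pos = rng.uniform(0.0, L, size=(params.n_cells, 2))
        return cls(radii=radii, positions=pos, box_length=L)

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            radii=self.radii.copy(),
            positions=self.positions.copy(),
            box_length=self.box_length,
            positions_unwrapped=self.positions_unwrapped.copy(),
        )


def packing_fraction(pop: CellPopulation) -> float:
    """ϕ = Σ πR_i² / L²  (area fraction; cells may overlap, so ϕ can
    exceed the hard-disk close-packing value)."""
    return float(np.sum(np.pi * pop.radii**2) / pop.box_length**2)


def minimum_image(dr: np.ndarray, L: float) -> np.ndarray:
    """Map displacement vectors into the minimum-image convention."""
    return dr - L * np.round(dr / L)


def pair_overlap(pop: CellPopulation, i: int, j: int) -> float:
    """Overlap h_ij = max(0, R_i + R_j − d_ij), d_ij minimum-image.

    h_ij measures how far the two soft disks interpenetrate; it is the
    argument of the Hertzian contact force.
    """
    if i == j:
        raise ValueError("pair_overlap requires i != j")
    dr = minimum_image(pop.positions[i] - pop.positions[j], pop.box_length)
    d = float(np.hypot(dr[0], dr[1]))
    return max(0.0, float(pop.radii[i] + pop.radii[j]) - d)
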