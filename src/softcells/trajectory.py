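"""Trajectory container and persistence (HDF5 + tidy CSV export)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import RadiusDistributionSpec, SimParams
from .population import CellPopulation

__all__ = ["TrajectoryStore"]


@dataclass
class TrajectoryStore:
    """Time-ordered production frames of one simulation run.

    Positions are stored unwrapped (continuous displacements from the
    start of production); the wrapped primary-image coordinates are
    recovered on demand as ``positions % L``.  The off-diagonal virial
    stress P_xy is stored on its own (usually finer) time grid for the
    Green–Kubo analysis.
    """

    frame_times: np.ndarray            # (F,) seconds
    positions_unwrapped: np.ndarray    # (F, N, 2) µm
    radii: np.ndarray                  # (N,) µm
    box_length: float                  # µm
    params: Optional[SimParams] = None
    spec: Optional[RadiusDistributionSpec] = None
    stress_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    stress_xy: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.positions_unwrapped = np.asarray(
            self.positions_unwrapped, dtype=float
        )
        if self.frame_times.ndim != 1:
            raise ValueError("frame_times must be 1-D")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        F = self.frame_times.size
        if self.positions_unwrapped.shape[0] != F:
            raise ValueError("positions and frame_times disagree on length")
        if self.stress_xy.size != self.stress_times.size:
            raise ValueError("stress series and times disagree on length")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def n_cells(self) -> int:
        return self.radii.size

    @property
    def positions_wrapped(self) -> np.ndarray:
        return np.mod(self.positions_unwrapped, self.box_length)

    def frame_population(self, k: int) -> CellPopulation:
        """The simulation state at frame ``k`` (wrapped coordinates)."""
        return CellPopulation(
            radii=self.radii,
            positions=np.mod(self.positions_unwrapped[k], self.box_length),
            box_length=self.box_length,
            positions_unwrapped=self.positions_unwrapped[k].copy(),
        )

    # -- persistence ----------------------------------------------------

    def save(self, path: str) -> None:
        """Write a single hierarchical HDF5 file for this run."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["box_length"] = self.box_length
            if self.params is not None:
                f.attrs["params_json"] = json.dumps(self.params.to_dict())
            if self.spec is not None:
                f.attrs["spec_json"] = json.dumps(self.spec.to_dict())
            f.create_dataset("radii", data=self.radii)
            f.create_dataset("frame_times", data=self.frame_times)
            f.create_dataset(
                "positions_unwrapped", data=self.positions_unwrapped
            )
            f.create_dataset("positions_wrapped", data=self.positions_wrapped)
            f.create_dataset("stress_times", data=self.stress_times)
            f.create_dataset("stress_xy", data=self.stress_xy)

    @classmethod
    def load(cls, path: str) -> "TrajectoryStore":
        import h5py

        with h5py.File(path, "r") as f:
            params = None
            spec = None
            if "params_json" in f.attrs:
                params = SimParams.from_dict(json.loads(f.attrs["params_json"]))
            if "spec_json" in f.attrs:
                spec = RadiusDistributionSpec.from_dict(
                    json.loads(f.attrs["spec_json"])
                )
            return cls(
                frame_times=f["frame_times"][:],
                positions_unwrapped=f["positions_unwrapped"][:],
                radii=f["radii"][:],
                box_length=float(f.attrs["box_length"]),
                params=params,
                spec=spec,
                stress_times=f["stress_times"][:],
                stress_xy=f["stress_xy"][:],
            )

    def to_frame_table(self) -> pd.DataFrame:
        """Tidy table: one row per cell per frame (wrapped coordinates)."""
        F, N = self.n_frames, self.n_cells
        wrapped = self.positions_wrapped
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(F), N),
                "time_s": np.repeat(self.frame_times, N),
                "cell_id": np.tile(np.arange(N), F),
                "x_um": wrapped[:, :, 0].ravel(),
                "y_um": wrapped[:, :, 1].ravel(),
                "radius_um": np.tile(self.radii, F),
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame_table().to_csv(path, index=False)
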