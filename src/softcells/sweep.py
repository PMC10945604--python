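"""Replicate sweeps over packing fraction with aggregated tables."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunManifest, objects_to_config, spawn_seeds
from .dynamics import run_simulation
from .free_area import free_area_fraction, voronoi_frames
from .observables import (
    first_peak_position,
    pair_correlation,
    relaxation_time,
    self_intermediate_scattering,
)
from .params import RadiusDistributionSpec, SimParams
from .trajectory import TrajectoryStore
from .viscosity import green_kubo_viscosity, stress_autocorrelation

__all__ = ["SweepResult", "sweep", "aggregate"]

logger = logging.getLogger(__name__)


@dataclass
class SweepResult:
    per_run: pd.DataFrame            # one row per (phi, replicate)
    aggregate: pd.DataFrame          # one row per phi, means and spreads
    manifest: RunManifest
    trajectories: Optional[list[TrajectoryStore]] = None


def _analyze_run(
    traj: TrajectoryStore,
    q_fixed: Optional[float],
    voronoi_every: int,
) -> dict:
    row: dict = {}
    gr = pair_correlation(traj)
    r_max = first_peak_position(gr)
    row["r_max"] = r_max
    q = q_fixed if q_fixed is not None else 2.0 * np.pi / r_max
    row["q"] = q
    fs = self_intermediate_scattering(traj, q)
    tau = relaxation_time(fs)
    row["tau_alpha"] = np.nan if tau is None else tau
    row["relaxed"] = tau is not None
    try:
        acf = stress_autocorrelation(traj)
        eta, _ = green_kubo_viscosity(acf)
        row["eta"] = eta
    except (ValueError, RuntimeError) as err:
        row["eta"] = np.nan
        row["eta_error"] = str(err)
    row["phi_free"] = free_area_fraction(
        voronoi_frames(traj, every=voronoi_every)
    )
    return row


def aggregate(per_run: pd.DataFrame) -> pd.DataFrame:
    """Per-ϕ means and across-replicate standard deviations."""
    def spread(x):
        return x.std(ddof=1) if x.notna().sum() > 1 else 0.0

    out = per_run.groupby("phi").agg(
        eta_mean=("eta", "mean"),
        eta_std=("eta", spread),
        tau_mean=("tau_alpha", "mean"),
        tau_std=("tau_alpha", spread),
        phi_free_mean=("phi_free", "mean"),
        phi_free_std=("phi_free", spread),
        n_replicates=("replicate", "count"),
    )
    return out.reset_index()


def sweep(
    phis: Sequence[float],
    replicates: int,
    params: SimParams,
    spec: Optional[RadiusDistributionSpec] = None,
    master_seed: int = 0,
    q_fixed: Optional[float] = None,
    voronoi_every: int = 1,
    keep_trajectories: bool = False,
) -> SweepResult:
    """Run ``replicates`` independent simulations at each ϕ and
    aggregate η̄, τα and ϕ_free with across-replicate spreads.

    Child seeds are spawned deterministically from ``master_seed`` and
    recorded in the manifest.  A failing run is logged and recorded in
    the manifest's errors without aborting the sweep.  By default q is
    recomputed per run from that run's g(r) first peak; pass
    ``q_fixed`` to hold the probing wavevector constant across ϕ.
    """
    if spec is None:
        spec = RadiusDistributionSpec()
    phis = list(phis)
    seeds = spawn_seeds(master_seed, len(phis) * replicates)
    manifest = RunManifest(
        config=objects_to_config(params, spec),
        master_seed=master_seed,
        child_seeds=seeds,
        software_version=__version__,
    )

    rows = []
    trajs: list[TrajectoryStore] = []
    k = 0
    for phi in phis:
        for rep in range(replicates):
            seed = seeds[k]
            k += 1
            run_params = replace(params, target_phi=phi, rng_seed=seed)
            label = f"phi={phi:.3f} rep={rep} seed={seed}"
            t0 = time.perf_counter()
            try:
                traj = run_simulation(run_params, spec)
                row = _analyze_run(traj, q_fixed, voronoi_every)
            except Exception as err:  # keep sweeping on partial failure
                logger.warning("run failed (%s): %s", label, err)
                manifest.errors[label] = repr(err)
                continue
            manifest.wall_times_s[label] = time.perf_counter() - t0
            row.update({"phi": phi, "replicate": rep, "seed": seed})
            rows.append(row)
            if keep_trajectories:
                trajs.append(traj)

    per_run = pd.DataFrame(rows)
    agg = aggregate(per_run) if not per_run.empty else pd.DataFrame()
    return SweepResult(
        per_run=per_run,
        aggregate=agg,
        manifest=manifest,
        trajectories=trajs if keep_trajectories else None,
    )
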