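"""Time evolution: overdamped active Langevin dynamics of soft cells.

Each cell obeys

    dr_i/dt = F_i / (γ0 R_i) + µ W_i(t),

with F_i the sum of pairwise Hertzian repulsions and W_i a unit-variance
white noise (⟨W_iα(t) W_jβ(t')⟩ = δ(t−t') δ_ij δ_αβ).  There is no
thermal motion: all dynamics is driven by the self-propulsion term µ.
The integrator is explicit Euler–Maruyama,

    Δr_i = F_i/(γ0 R_i) Δt + µ √Δt ξ_i,   ξ_i ~ N(0, 1)²,

which is the unique consistent discretisation of delta-correlated noise.

``run_simulation`` initialises cells at random positions and removes the
resulting catastrophic overlaps by growing the radii from 50% to full
size over a ramp, then equilibrates, then records production frames and
the per-step off-diagonal virial stress.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

from .params import RadiusDistributionSpec, SimParams, sample_radii
from .population import CellPopulation, box_length_for_phi
from .trajectory import TrajectoryStore

__all__ = ["step", "run_simulation"]

logger = logging.getLogger(__name__)

_STATUS_OK = 0
_STATUS_COINCIDENT = 1
_STATUS_BLOWUP = 2


@njit(cache=True, fastmath=True)
def _forces_stress_scaled(pos, radii, scale, L, coef):  # pragma: no cover
    """Forces + off-diagonal virial sum at radii scaled by ``scale``.

    Cell-linked lists with cutoff 2·max(scaled radius) and a half
    stencil (each pair visited once); falls back to the all-pairs
    minimum-image loop when the box holds fewer than 3 link cells per
    side.  Returns (forces, s_xy, bad_index).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    sxy = 0.0
    bad = -1
    half = 0.5 * L

    rmax = 0.0
    for i in range(n):
        ri = radii[i] * scale
        if ri > rmax:
            rmax = ri
    cutoff = 2.0 * rmax
    ncell = int(L / cutoff)

    if ncell < 3:
        for i in range(n):
            ri = radii[i] * scale
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                if dx > half:
                    dx -= L
                elif dx < -half:
                    dx += L
                if dy > half:
                    dy -= L
                elif dy < -half:
                    dy += L
                rj = radii[j] * scale
                rsum = ri + rj
                d2 = dx * dx + dy * dy
                if d2 < rsum * rsum:
                    if d2 < 1e-24:
                        bad = i
                        continue
                    d = np.sqrt(d2)
                    h = rsum - d
                    fmag = coef * h * np.sqrt(h) * np.sqrt(
                        ri * rj / rsum
                    )
                    fx = fmag * dx / d
                    fy = fmag * dy / d
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    sxy += dx * fy
        return forces, sxy, bad

    cell_size = L / ncell
    ncell2 = ncell * ncell
    head = -np.ones(ncell2, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    cellof = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_size)
        cy = int(pos[i, 1] / cell_size)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        c = cy * ncell + cx
        cellof[i] = c
        nxt[i] = head[c]
        head[c] = i

    # half stencil: self, E, NE, N, NW — each unordered pair once
    for i in range(n):
        c = cellof[i]
        cy = c // ncell
        cx = c - cy * ncell
        ri = radii[i] * scale
        xi = pos[i, 0]
        yi = pos[i, 1]
        for s in range(5):
            if s == 0:
                ox, oy = 0, 0
            elif s == 1:
                ox, oy = 1, 0
            elif s == 2:
                ox, oy = 1, 1
            elif s == 3:
                ox, oy = 0, 1
            else:
                ox, oy = -1, 1
            ccx = cx + ox
            if ccx == ncell:
                ccx = 0
            elif ccx == -1:
                ccx = ncell - 1
            ccy = cy + oy
            if ccy == ncell:
                ccy = 0
            j = head[ccy * ncell + ccx]
            while j >= 0:
                if s > 0 or j < i:
                    dx = xi - pos[j, 0]
                    dy = yi - pos[j, 1]
                    if dx > half:
                        dx -= L
                    elif dx < -half:
                        dx += L
                    if dy > half:
                        dy -= L
                    elif dy < -half:
                        dy += L
                    rj = radii[j] * scale
                    rsum = ri + rj
                    d2 = dx * dx + dy * dy
                    if d2 < rsum * rsum:
                        if d2 < 1e-24:
                            bad = i
                        else:
                            d = np.sqrt(d2)
                            h = rsum - d
                            fmag = coef * h * np.sqrt(h) * np.sqrt(
                                ri * rj / rsum
                            )
                            fx = fmag * dx / d
                            fy = fmag * dy / d
                            forces[i, 0] += fx
                            forces[i, 1] += fy
                            forces[j, 0] -= fx
                            forces[j, 1] -= fy
                            sxy += dx * fy
                j = nxt[j]
    return forces, sxy, bad


@njit(cache=True)
def _advance(pos, unwrapped, radii, L, coef, gamma0, dt, mu_sqrt_dt,
             noise, scale0, dscale, stress_out, max_disp):  # pragma: no cover
    """Advance ``noise.shape[0]`` steps in place.

    Radii are scaled by scale0 + k·dscale at step k (growth ramp; use
    dscale=0 for fixed radii).  Per-step s_xy/A is written to stress_out.
    Returns (status, step_index).
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    area = L * L
    for k in range(n_steps):
        scale = scale0 + dscale * k
        forces, sxy, bad = _forces_stress_scaled(pos, radii, scale, L, coef)
        if bad >= 0:
            return _STATUS_COINCIDENT, k
        stress_out[k] = sxy / area
        for i in range(n):
            inv_gamma = 1.0 / (gamma0 * radii[i] * scale)
            ddx = forces[i, 0] * inv_gamma * dt + mu_sqrt_dt * noise[k, i, 0]
            ddy = forces[i, 1] * inv_gamma * dt + mu_sqrt_dt * noise[k, i, 1]
            if np.sqrt(ddx * ddx + ddy * ddy) > max_disp:
                return _STATUS_BLOWUP, k
            x = pos[i, 0] + ddx
            y = pos[i, 1] + ddy
            pos[i, 0] = x - L * np.floor(x / L)
            pos[i, 1] = y - L * np.floor(y / L)
            unwrapped[i, 0] += ddx
            unwrapped[i, 1] += ddy
    return _STATUS_OK, n_steps


def _hertz_coef(params: SimParams) -> float:
    return params.elastic_modulus_E / (1.5 * (1.0 - params.poisson_nu**2))


def _raise_status(status: int, k: int, params: SimParams) -> None:
    if status == _STATUS_COINCIDENT:
        raise FloatingPointError(
            f"coincident cell centres at step {k}: force direction undefined"
        )
    if status == _STATUS_BLOWUP:
        raise FloatingPointError(
            f"per-step displacement exceeded the sanity bound at step {k}; "
            f"dt={params.dt} is likely unstable for this configuration"
        )


def _advance_steps(
    pop: CellPopulation,
    params: SimParams,
    rng: np.random.Generator,
    n_steps: int,
    scale0: float = 1.0,
    scale1: float = 1.0,
) -> np.ndarray:
    """Advance ``n_steps`` in place; returns the per-step P_xy series."""
    if n_steps == 0:
        return np.empty(0)
    coef = _hertz_coef(params)
    mu_sqrt_dt = params.mu_activity * np.sqrt(params.dt)
    max_disp = params.max_step_disp or float(pop.radii.max())
    stress = np.empty(n_steps)
    if params.mu_activity > 0:
        noise = rng.standard_normal((n_steps, pop.n_cells, 2))
    else:
        noise = np.zeros((n_steps, pop.n_cells, 2))
    dscale = (scale1 - scale0) / n_steps if n_steps > 1 else 0.0
    status, k = _advance(
        pop.positions, pop.positions_unwrapped, pop.radii, pop.box_length,
        coef, params.gamma0, params.dt, mu_sqrt_dt, noise,
        scale0, dscale, stress, max_disp,
    )
    _raise_status(status, k, params)
    return stress


def step(
    pop: CellPopulation, params: SimParams, rng: np.random.Generator
) -> CellPopulation:
    """One Euler–Maruyama step; mutates and returns ``pop``.

    Deterministic given the state of ``rng``.  Raises FloatingPointError
    if any displacement exceeds ``params.max_step_disp`` (default: the
    largest radius), the signature of an unstable timestep.
    """
    _advance_steps(pop, params, rng, 1)
    return pop


def run_simulation(
    params: SimParams,
    spec: RadiusDistributionSpec | None = None,
    rng: np.random.Generator | None = None,
) -> TrajectoryStore:
    """Full pipeline: initialise → grow → equilibrate → record.

    Cells are placed uniformly at random; radii are then ramped from 50%
    to full size over ``n_steps_grow`` steps (removing the catastrophic
    overlaps that random placement produces at high ϕ), followed by
    ``n_steps_equil`` steps at full size.  Production records a frame
    every ``save_every`` steps (including the frame at t=0) and the
    off-diagonal virial stress every ``stress_every`` steps.
    Fully reproducible from ``params.rng_seed``.
    """
    if spec is None:
        spec = RadiusDistributionSpec()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    radii = sample_radii(spec, params.n_cells, rng)
    L = params.box_length_L or box_length_for_phi(radii, params.target_phi)
    pos = rng.uniform(0.0, L, size=(params.n_cells, 2))
    pop = CellPopulation(radii=radii, positions=pos, box_length=L)

    if params.n_steps_grow > 0:
        logger.info(
            "growth ramp: %d steps (phi_eff %.3f -> %.3f)",
            params.n_steps_grow, 0.25 * pop.phi, pop.phi,
        )
        _advance_steps(pop, params, rng, params.n_steps_grow,
                       scale0=0.5, scale1=1.0)
    if params.n_steps_equil > 0:
        logger.info("equilibration: %d steps (%.3g s)",
                    params.n_steps_equil, params.n_steps_equil * params.dt)
        chunk = 50_000
        done = 0
        while done < params.n_steps_equil:
            todo = min(chunk, params.n_steps_equil - done)
            _advance_steps(pop, params, rng, todo)
            done += todo
            logger.info("  equilibrated %d / %d steps",
                        done, params.n_steps_equil)

    # production: displacements measured from the start of production
    pop.positions_unwrapped = pop.positions.copy()
    n_prod = params.n_steps_prod
    frame_idx = np.arange(0, n_prod + 1, params.save_every)
    n_frames = frame_idx.size
    frames = np.empty((n_frames, params.n_cells, 2))
    frames[0] = pop.positions_unwrapped
    stress_parts = []

    logger.info("production: %d steps, %d frames", n_prod, n_frames)
    done = 0
    for k in range(1, n_frames):
        todo = int(frame_idx[k] - frame_idx[k - 1])
        stress_parts.append(_advance_steps(pop, params, rng, todo))
        frames[k] = pop.positions_unwrapped
        done += todo
    # trailing steps that do not complete a frame interval
    if done < n_prod:
        stress_parts.append(_advance_steps(pop, params, rng, n_prod - done))

    if stress_parts:
        stress_all = np.concatenate(stress_parts)
    else:
        stress_all = np.empty(0)
    sl = slice(None, None, params.stress_every)
    stress_times = (np.arange(1, n_prod + 1) * params.dt)[sl]

    return TrajectoryStore(
        frame_times=frame_idx * params.dt,
        positions_unwrapped=frames,
        radii=radii,
        box_length=L,
        params=params,
        spec=spec,
        stress_times=stress_times,
        stress_xy=stress_all[sl],
    )
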