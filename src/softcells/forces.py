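"""Hertzian contact forces and the pairwise virial stress.

The repulsive force between two overlapping soft disks is Hertzian,

    F_ij = h_ij^{3/2} / [ (3/2) ((1-ν²)/E) sqrt(1/R_i + 1/R_j) ],

acting along the centre-to-centre unit vector.  Forces are strictly
pairwise and antisymmetric, so total momentum input is exactly zero.

The hot loop is a numba-compiled cell-linked-list kernel with cutoff
2·R_max (no pair can interact beyond it).  For boxes too small to hold a
3×3 grid of link cells the kernel falls back to an all-pairs
minimum-image loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import SimParams
from .population import CellPopulation

__all__ = ["hertz_force_magnitude", "total_forces", "forces_and_stress"]


def hertz_force_magnitude(
    h: float | np.ndarray,
    R_i: float,
    R_j: float,
    E: float,
    nu: float,
) -> float | np.ndarray:
    """Magnitude of the Hertzian repulsion for overlap ``h`` (µm).

    Zero at zero overlap, grows as h^{3/2}, symmetric in the two radii.
    Units: with E in MPa and lengths in µm the force comes out in µN.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("overlap h must be non-negative")
    denom = 1.5 * ((1.0 - nu**2) / E) * np.sqrt(1.0 / R_i + 1.0 / R_j)
    out = h**1.5 / denom
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _pair_kernel_brute(pos, radii, L, coef):  # pragma: no cover - jit
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    bad = -1
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dx -= L * np.round(dx / L)
            dy -= L * np.round(dy / L)
            d = np.sqrt(dx * dx + dy * dy)
            h = radii[i] + radii[j] - d
            if h > 0.0:
                if d < 1e-12:
                    bad = i
                    continue
                fmag = coef * h * np.sqrt(h) * np.sqrt(
                    radii[i] * radii[j] / (radii[i] + radii[j])
                )
                fx = fmag * dx / d
                fy = fmag * dy / d
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                sxx += dx * fx
                syy += dy * fy
                sxy += dx * fy
    return forces, sxx, syy, sxy, bad


@njit(cache=True)
def _pair_kernel_cells(pos, radii, L, coef, cutoff):  # pragma: no cover - jit
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    bad = -1

    ncell = int(L / cutoff)
    cell_size = L / ncell
    head = -np.ones(ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_size)
        cy = int(pos[i, 1] / cell_size)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        c = cy * ncell + cx
        nxt[i] = head[c]
        head[c] = i

    for i in range(n):
        cx = int(pos[i, 0] / cell_size)
        cy = int(pos[i, 1] / cell_size)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                c = ((cy + oy) % ncell) * ncell + (cx + ox) % ncell
                j = head[c]
                while j >= 0:
                    if j > i:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dx -= L * np.round(dx / L)
                        dy -= L * np.round(dy / L)
                        d = np.sqrt(dx * dx + dy * dy)
                        h = radii[i] + radii[j] - d
                        if h > 0.0:
                            if d < 1e-12:
                                bad = i
                            else:
                                fmag = coef * h * np.sqrt(h) * np.sqrt(
                                    radii[i] * radii[j]
                                    / (radii[i] + radii[j])
                                )
                                fx = fmag * dx / d
                                fy = fmag * dy / d
                                forces[i, 0] += fx
                                forces[i, 1] += fy
                                forces[j, 0] -= fx
                                forces[j, 1] -= fy
                                sxx += dx * fx
                                syy += dy * fy
                                sxy += dx * fy
                    j = nxt[j]
    return forces, sxx, syy, sxy, bad


def forces_and_stress(
    pop: CellPopulation, params: SimParams
) -> tuple[np.ndarray, dict]:
    """Forces on every cell plus the instantaneous virial stress.

    Returns ``(forces, stress)`` where ``forces`` is (N, 2) in µN and
    ``stress`` maps components to P_µν = (1/A) Σ_{i<j} r_ij,µ f_ij,ν with
    A = L² and minimum-image r_ij.  For central forces P_xy = P_yx, so a
    single off-diagonal value is stored under both keys.

    Raises on coincident centres within an interacting pair (the force
    direction is undefined there).
    """
    # fmag = coef * h^{3/2} * sqrt(Ri Rj / (Ri+Rj)); note
    # 1/sqrt(1/Ri + 1/Rj) = sqrt(Ri Rj/(Ri+Rj))
    coef = params.elastic_modulus_E / (1.5 * (1.0 - params.poisson_nu**2))
    L = pop.box_length
    cutoff = 2.0 * float(pop.radii.max())
    pos = np.ascontiguousarray(pop.positions)
    radii = np.ascontiguousarray(pop.radii)

    if L / cutoff >= 3.0:
        forces, sxx, syy, sxy, bad = _pair_kernel_cells(
            pos, radii, L, coef, cutoff
        )
    else:
        forces, sxx, syy, sxy, bad = _pair_kernel_brute(pos, radii, L, coef)
    if bad >= 0:
        raise FloatingPointError(
            f"coincident cell centres involving cell {bad}: "
            "force direction undefined (unstable configuration?)"
        )
    A = L * L
    stress = {
        "xx": sxx / A,
        "yy": syy / A,
        "xy": sxy / A,
        "yx": sxy / A,
    }
    return forces, stress


def total_forces(pop: CellPopulation, params: SimParams) -> np.ndarray:
    """Net Hertzian force on every cell, shape (N, 2)."""
    forces, _ = forces_and_stress(pop, params)
    return forces
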