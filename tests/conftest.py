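"""Shared fixtures and independent oracles.

The force oracle here is deliberately naive: an explicit double loop over
all pairs and all 9 periodic images, with no neighbour lists, no
minimum-image shortcut and no shared code with the package kernels.
"""

from __future__ import annotations

import numpy as np
import pytest

from softcells import (
    CellPopulation,
    RadiusDistributionSpec,
    SimParams,
    make_fixture,
)


@pytest.fixture
def pair_h1() -> CellPopulation:
    return make_fixture("pair_h1")


@pytest.fixture
def lattice16() -> CellPopulation:
    return make_fixture("lattice16")


@pytest.fixture
def default_spec() -> RadiusDistributionSpec:
    return RadiusDistributionSpec()


def brute_force_forces(pop: CellPopulation, params: SimParams) -> np.ndarray:
    """O(N² · 9) reference: for each ordered pair, take the closest of the
    nine periodic images of j and apply the Hertzian force if overlapping."""
    n = pop.n_cells
    L = pop.box_length
    out = np.zeros((n, 2))
    coef = 1.0 / (
        1.5 * ((1.0 - params.poisson_nu**2) / params.elastic_modulus_E)
    )
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = None
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    image = pop.positions[j] + np.array([ix * L, iy * L])
                    d = np.linalg.norm(pop.positions[i] - image)
                    if best is None or d < best[0]:
                        best = (d, image)
            d, image = best
            h = pop.radii[i] + pop.radii[j] - d
            if h > 0:
                fmag = coef * h**1.5 / np.sqrt(
                    1.0 / pop.radii[i] + 1.0 / pop.radii[j]
                )
                out[i] += fmag * (pop.positions[i] - image) / d
    return out
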