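"""Shared fixtures: toy world grids and small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest
import xarray as xr

from ar_overshoot.synthetic import REGIONS


def make_toy_grid(
    n_cells: int,
    cell_area: float | np.ndarray = 100.0,
    forest: float | np.ndarray = 0.0,
    pasture: float | np.ndarray = 0.5,
    rangeland: float | np.ndarray = 0.0,
    cropland: float | np.ndarray = 0.0,
    natural_grass: float | np.ndarray = 0.0,
    potential: float | np.ndarray = 0.6,
    forest_1850: float | np.ndarray | None = None,
    grs: float | np.ndarray = 1.0,
    atl: float | np.ndarray = 1.0,
    vlhi: int | np.ndarray = 0,
    lhi: int | np.ndarray = 1,
    region: int | np.ndarray = 0,
) -> xr.Dataset:
    """Hand-built 1 x n world grid with explicit per-cell values.

    Fractions are given directly; potentials are fractions of cell area
    (``grs``/``atl``).  Defaults make every cell a single-region cell with
    ample pasture and unconstrained restoration potential.
    """

    def arr(v, dtype=float):
        a = np.broadcast_to(np.asarray(v, dtype=dtype), (n_cells,)).copy()
        return a[None, :]

    forest = arr(forest)
    if forest_1850 is None:
        forest_1850 = forest.copy()
    else:
        forest_1850 = arr(forest_1850)
    data = {
        "cell_area": arr(cell_area),
        "frac_forest": forest,
        "frac_pasture": arr(pasture),
        "frac_rangeland": arr(rangeland),
        "frac_cropland": arr(cropland),
        "frac_natural_grass": arr(natural_grass),
        "frac_potential_forest": arr(potential),
        "frac_forest_1850": forest_1850,
        "grs_potential": arr(grs),
        "atl_potential": np.maximum(arr(atl), arr(grs)),
        "vlhi_mask": arr(vlhi, np.int8),
        "lhi_agreement": arr(lhi, np.int16),
        "region_id": arr(region, np.int16),
    }
    other = 1.0 - (
        data["frac_forest"] + data["frac_pasture"] + data["frac_rangeland"]
        + data["frac_cropland"] + data["frac_natural_grass"]
    )
    if np.any(other < -1e-12):
        raise ValueError("toy grid cover fractions exceed 1")
    data["frac_other"] = np.clip(other, 0.0, 1.0)
    ds = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in data.items()},
        coords={"lat": [0.0], "lon": np.arange(n_cells, dtype=float)},
        attrs={"region_names": ",".join(REGIONS)},
    )
    return ds


def water_filling(capacities: np.ndarray, target: float) -> np.ndarray:
    """Independent oracle for iterative uniform allocation with caps.

    Equal-split iteration with per-cell caps converges to the water-filling
    solution alloc_i = min(c_i, lam) with lam chosen so the total meets the
    target (or every capacity saturates).  Solved here by bisection.
    """
    c = np.asarray(capacities, dtype=float)
    if target >= c.sum():
        return c.copy()
    lo, hi = 0.0, target
    for _ in range(200):
        lam = 0.5 * (lo + hi)
        if np.minimum(c, lam).sum() < target:
            lo = lam
        else:
            hi = lam
    return np.minimum(c, 0.5 * (lo + hi))


def epsilon_step_allocation(
    capacities: np.ndarray, target: float, step: float = 1e-3
) -> np.ndarray:
    """Brute-force simulation: hand out the target in tiny equal shares."""
    c = np.asarray(capacities, dtype=float)
    alloc = np.zeros_like(c)
    remaining = min(target, c.sum())
    while remaining > 1e-9:
        open_cells = np.flatnonzero(alloc < c - 1e-12)
        share = min(step, remaining / open_cells.size)
        take = np.minimum(share, c[open_cells] - alloc[open_cells])
        alloc[open_cells] += take
        remaining -= take.sum()
    return alloc


@pytest.fixture(scope="session")
def small_world():
    from ar_overshoot.synthetic import gen_world_grid

    return gen_world_grid(8, 16, seed=42)


@pytest.fixture(scope="session")
def small_db():
    from ar_overshoot.synthetic import gen_scenario_db

    return gen_scenario_db(80, seed=43)
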