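"""Seeded synthetic-world generators.

Every input the pipeline needs is generated here with the statistical structure
the downstream analysis assumes: a scenario database with lognormal forest-area
increment spread, a spatially smooth gridded world with restoration-potential
and human-influence layers, ensembles built as a forced trajectory plus AR(1)
internal variability, and mass-conserving carbon-pool trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

#: The five world economic regions typically used in integrated assessment
#: models (OECD90+EU; Eastern Europe & reforming economies of the former
#: Soviet Union; Latin America; Middle East & Africa; Asia).
REGIONS: tuple[str, ...] = ("ASIA", "EEU_REFSU", "LAC", "MAF", "OECD90")

#: Scope label for globally aggregated scenario records.
WORLD_SCOPE = "WORLD"

EARTH_RADIUS_KM = 6371.0
KM2_PER_MHA = 1.0e4  # 1 Mha = 10^4 km^2

COVER_VARS = (
    "frac_forest",
    "frac_pasture",
    "frac_rangeland",
    "frac_cropland",
    "frac_natural_grass",
    "frac_other",
)


# ---------------------------------------------------------------------------
# Ensemble containers
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSeries:
    """Member x year matrix of an annual-mean global quantity.

    ``values[m, t]`` is member ``m`` in calendar year ``years[t]``.
    """

    experiment: str
    variable: str
    units: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.years.size:
            raise ValueError(
                f"values has {self.values.shape[1]} years, expected {self.years.size}"
            )
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_members(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        """Ensemble-mean series."""
        return self.values.mean(axis=0)

    def sel_years(self, years: Sequence[int]) -> np.ndarray:
        """Member x year block for the requested calendar years."""
        idx = np.searchsorted(self.years, years)
        if np.any(self.years[idx] != np.asarray(years)):
            raise KeyError("requested years not in series")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        """Long-format records: member, scope, variable, year, value."""
        m, t = np.meshgrid(np.arange(1, self.n_members + 1), self.years, indexing="ij")
        return pd.DataFrame(
            {
                "member": m.ravel(),
                "scope": self.experiment,
                "variable": self.variable,
                "year": t.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, experiment: str | None = None, units: str = "") -> "EnsembleSeries":
        df = pd.read_csv(path)
        if experiment is not None:
            df = df[df["scope"] == experiment]
        if df.empty:
            raise ValueError("no records for requested experiment")
        wide = df.pivot(index="member", columns="year", values="value").sort_index()
        return cls(
            experiment=str(df["scope"].iloc[0]),
            variable=str(df["variable"].iloc[0]),
            units=units,
            years=wide.columns.to_numpy(int),
            values=wide.to_numpy(float),
        )


@dataclass
class GriddedEnsemble:
    """Member x year x (lat, lon) annual-mean field on a :func:`gen_world_grid` grid."""

    experiment: str
    variable: str
    units: str
    years: np.ndarray
    values: np.ndarray  # (member, year, lat, lon)
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (member, year, lat, lon)")
        if self.values.shape[1] != self.years.size:
            raise ValueError("year dimension mismatch")
        if self.values.shape[2:] != (len(self.lat), len(self.lon)):
            raise ValueError("grid shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_members(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[2] * self.values.shape[3]

    def stacked(self) -> np.ndarray:
        """Values reshaped to (member, year, cell), row-major lat-then-lon."""
        m, t = self.values.shape[:2]
        return self.values.reshape(m, t, -1)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {self.variable: (("member", "year", "lat", "lon"), self.values)},
            coords={
                "member": np.arange(1, self.n_members + 1),
                "year": self.years,
                "lat": self.lat,
                "lon": self.lon,
            },
            attrs={"experiment": self.experiment, "units": self.units},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "GriddedEnsemble":
        ds = xr.load_dataset(path, engine="scipy")
        name = [v for v in ds.data_vars][0]
        return cls(
            experiment=ds.attrs.get("experiment", ""),
            variable=name,
            units=ds.attrs.get("units", ""),
            years=ds["year"].values,
            values=ds[name].values,
            lat=ds["lat"].values,
            lon=ds["lon"].values,
        )


@dataclass
class ForcedTrajectory:
    """Deterministic forced trajectory with known threshold crossings.

    ``known_crossings`` maps a threshold to ``(up_year, down_year)`` — the
    first and last calendar year with value at or above the threshold — and is
    the ground truth for overshoot-duration recovery tests.
    """

    years: np.ndarray
    values: np.ndarray
    known_crossings: dict[float, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError("years/values length mismatch")
        for thr, (up, down) in self.known_crossings.items():
            above = self.years[self.values >= thr]
            if above.size == 0 or above[0] != up or above[-1] != down:
                raise ValueError(f"crossings inconsistent with values at {thr}")

    @classmethod
    def overshoot(
        cls,
        *,
        years: Sequence[int] = range(2015, 2101),
        t_start: float = 1.2,
        threshold: float = 1.5,
        up_year: int = 2035,
        peak_year: int = 2058,
        peak_value: float = 2.06,
        down_year: int = 2099,
        t_end: float | None = None,
    ) -> "ForcedTrajectory":
        """Piecewise-smooth rise–peak–decline overshoot trajectory.

        A shape-preserving cubic Hermite interpolant through anchor points
        placed so that ``up_year`` and ``down_year`` are exactly the first and
        last years at or above ``threshold`` (the curve crosses the threshold
        half a year outside each).
        """
        years = np.asarray(list(years), dtype=int)
        y0, y1 = years[0], years[-1]
        if not (y0 <= up_year < peak_year < down_year <= y1):
            raise ValueError("require start <= up < peak < down <= end")
        if not (t_start < threshold < peak_value):
            raise ValueError("require t_start < threshold < peak_value")
        if t_end is None:
            # continue the mean decline rate linearly past the down-crossing,
            # so the tail carries no curvature kink
            slope = (peak_value - threshold) / (down_year + 0.5 - peak_year)
            t_end = threshold - slope * (y1 - (down_year + 0.5))
        if t_end >= threshold and down_year < y1:
            raise ValueError("t_end must be below threshold")
        knots_x = [y0, up_year - 0.5, peak_year, down_year + 0.5]
        knots_y = [t_start, threshold, peak_value, threshold]
        if down_year + 0.5 < y1:
            knots_x.append(y1)
            knots_y.append(t_end)
        else:  # overshoot runs to the end of record
            knots_x.append(y1 + 1.0)
            knots_y.append(t_end)
        interp = PchipInterpolator(knots_x, knots_y)
        values = interp(years.astype(float))
        return cls(years=years, values=values, known_crossings={threshold: (up_year, down_year)})


# ---------------------------------------------------------------------------
# World grid
# ---------------------------------------------------------------------------


@dataclass
class GridConfig:
    """Targets and texture of the synthetic world grid.

    Global land-cover totals are in Mha and are hit exactly by construction.
    Defaults approximate present-day magnitudes: ~4 Gha forest, ~0.8 Gha
    heavily managed pasture, ~2 Gha rangeland, ~1.55 Gha cropland.
    """

    forest_total: float = 4000.0
    pasture_total: float = 800.0
    rangeland_total: float = 2000.0
    cropland_total: float = 1550.0
    natural_grass_total: float = 1200.0
    cover_budget: float = 0.9  # max per-cell sum of cover fractions before rescaling
    smoothness: float = 1.5  # gaussian correlation length, in gridcells
    vlhi_fraction: float = 0.2  # share of cells flagged Very Low Human Influence
    hist_deforestation_total: float = 850.0  # Mha of pre-1850 forest now cleared
    potential_headroom: float = 0.5  # mean extra climatically sustainable forest fraction
    grs_total: float = 400.0  # Mha of global GRS restoration potential
    atl_total: float = 800.0  # Mha of global ATL restoration potential


def _smooth_field(rng: np.random.Generator, nlat: int, nlon: int, sigma: float) -> np.ndarray:
    """Standardized spatially smooth random field (periodic in longitude)."""
    raw = rng.standard_normal((nlat, nlon))
    sm = gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros_like(sm)
    return (sm - sm.mean()) / sd


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def cell_areas_mha(lat_edges: np.ndarray, nlon: int) -> np.ndarray:
    """Spherical cell areas (Mha) for latitude bands split into nlon columns."""
    phi = np.deg2rad(lat_edges)
    band = 2.0 * np.pi * EARTH_RADIUS_KM**2 * np.diff(np.sin(phi)) / nlon
    return band / KM2_PER_MHA


def gen_world_grid(
    nlat: int,
    nlon: int,
    seed: int,
    config: GridConfig | None = None,
) -> xr.Dataset:
    """Generate a static synthetic world grid.

    Returns an :class:`xarray.Dataset` on a regular lat-lon grid with cell
    areas (Mha), land-cover fractions hitting the configured global totals
    exactly, potential/pre-industrial forest fractions, GRS/ATL restoration
    potentials (GRS a subset of ATL), a VLHI exclusion mask, an LHI
    agreement count (0–4) and one of five region IDs per cell.
    Deterministic given ``seed``.
    """
    if nlat < 2 or nlon < 2:
        raise ValueError("nlat and nlon must be >= 2")
    cfg = config or GridConfig()
    if not (0 < cfg.cover_budget <= 1):
        raise ValueError("cover_budget must be in (0, 1]")
    rng = np.random.default_rng(seed)

    lat_edges = np.linspace(-90.0, 90.0, nlat + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = (np.arange(nlon) + 0.5) * 360.0 / nlon - 180.0
    area_band = cell_areas_mha(lat_edges, nlon)
    area = np.repeat(area_band[:, None], nlon, axis=1)

    # Per-cell cover shares from smooth positive weights; a slack weight keeps
    # the per-cell cover sum strictly below the budget in most cells.
    targets = {
        "frac_forest": cfg.forest_total,
        "frac_pasture": cfg.pasture_total,
        "frac_rangeland": cfg.rangeland_total,
        "frac_cropland": cfg.cropland_total,
        "frac_natural_grass": cfg.natural_grass_total,
    }
    for name, tot in targets.items():
        if tot < 0:
            raise ValueError(f"{name} total must be >= 0")
    weights = {
        name: np.exp(1.2 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
        for name in targets
    }
    slack = np.exp(1.2 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
    wsum = sum(weights.values()) + slack
    fracs = {name: cfg.cover_budget * w / wsum for name, w in weights.items()}

    # Rescale each cover type globally to hit its total exactly; scaling is
    # only ever downward, so per-cell sums stay below the budget.
    for name, tot in targets.items():
        cur = float((fracs[name] * area).sum())
        alpha = tot / cur
        if alpha > 1.0 + 1e-12:
            raise ValueError(
                f"target {name}={tot} Mha unreachable (max {cur:.1f} Mha); "
                "raise cover_budget or lower the target"
            )
        fracs[name] = fracs[name] * min(alpha, 1.0)

    cover_sum = sum(fracs.values())
    fracs["frac_other"] = 1.0 - cover_sum

    # Maximum climatically sustainable forest fraction and pre-1850 forest.
    headroom_field = _sigmoid(1.5 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
    potential = np.clip(
        fracs["frac_forest"] + 2.0 * cfg.potential_headroom * headroom_field * fracs["frac_other"],
        0.0,
        0.95,
    )
    defor_w = _sigmoid(1.5 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
    defor_room = np.clip(potential - fracs["frac_forest"], 0.0, None)
    raw_defor = defor_w * defor_room
    cur_defor = float((raw_defor * area).sum())
    if cur_defor > 0:
        raw_defor *= min(1.0, cfg.hist_deforestation_total / cur_defor)
    forest_1850 = fracs["frac_forest"] + raw_defor

    # Restoration potentials: GRS is a subset of ATL.
    atl_u = _sigmoid(1.5 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
    grs_u = _sigmoid(1.5 * _smooth_field(rng, nlat, nlon, cfg.smoothness))
    atl = atl_u * defor_room
    grs = grs_u * atl
    # Scale both to their configured global totals (restoration maps cover far
    # less land than the raw climatic headroom); GRS stays a subset of ATL.
    atl_cur = float((atl * area).sum())
    if atl_cur > 0:
        atl *= min(1.0, cfg.atl_total / atl_cur)
    grs_cur = float((grs * area).sum())
    if grs_cur > 0:
        grs *= min(1.0, cfg.grs_total / grs_cur)
    grs = np.minimum(grs, atl)

    # Human-influence layers.
    vlhi_field = _smooth_field(rng, nlat, nlon, cfg.smoothness)
    vlhi = vlhi_field > np.quantile(vlhi_field, 1.0 - cfg.vlhi_fraction)
    lhi_field = _smooth_field(rng, nlat, nlon, cfg.smoothness)
    edges = np.quantile(lhi_field, [0.2, 0.4, 0.6, 0.8])
    lhi = np.digitize(lhi_field, edges)  # 0..4

    # Five contiguous longitude-band regions.
    region = (np.arange(nlon) * len(REGIONS)) // nlon
    region_id = np.broadcast_to(region[None, :], (nlat, nlon)).copy()

    ds = xr.Dataset(
        {
            "cell_area": (("lat", "lon"), area, {"units": "Mha"}),
            **{
                name: (("lat", "lon"), arr, {"units": "1"})
                for name, arr in fracs.items()
            },
            "frac_potential_forest": (("lat", "lon"), potential, {"units": "1"}),
            "frac_forest_1850": (("lat", "lon"), forest_1850, {"units": "1"}),
            "grs_potential": (("lat", "lon"), grs, {"units": "1"}),
            "atl_potential": (("lat", "lon"), atl, {"units": "1"}),
            "vlhi_mask": (("lat", "lon"), vlhi.astype(np.int8)),
            "lhi_agreement": (("lat", "lon"), lhi.astype(np.int16)),
            "region_id": (("lat", "lon"), region_id.astype(np.int16)),
        },
        coords={"lat": ("lat", lat, {"units": "degrees_north"}),
                "lon": ("lon", lon, {"units": "degrees_east"})},
        attrs={"region_names": ",".join(REGIONS), "Conventions": "CF-1.8"},
    )
    validate_world_grid(ds)
    return ds


def validate_world_grid(ds: xr.Dataset) -> None:
    """Raise ``ValueError`` on any violated world-grid invariant."""
    for name in COVER_VARS + ("frac_potential_forest", "frac_forest_1850",
                              "grs_potential", "atl_potential"):
        arr = ds[name].values
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"{name} outside [0, 1]")
    cover = sum(ds[name].values for name in COVER_VARS)
    if np.any(cover > 1 + 1e-9):
        raise ValueError("cover fractions sum above 1")
    if np.any(ds["grs_potential"].values > ds["atl_potential"].values + 1e-12):
        raise ValueError("grs_potential exceeds atl_potential")
    if np.any(ds["cell_area"].values <= 0):
        raise ValueError("cell_area must be positive")
    lhi = ds["lhi_agreement"].values
    if np.any((lhi < 0) | (lhi > 4)):
        raise ValueError("lhi_agreement outside 0..4")
    rid = ds["region_id"].values
    if np.any((rid < 0) | (rid >= len(REGIONS))):
        raise ValueError("region_id outside range")


# ---------------------------------------------------------------------------
# Scenario database
# ---------------------------------------------------------------------------


@dataclass
class ScenarioShape:
    """Shape of the synthetic scenario database.

    Forest-area increments per 5-year step are drawn lognormally, with a step
    profile chosen so the pooled 90th percentile declines linearly from
    ``q90_first`` to ``q90_last`` Mha per step — which cumulates to ~595 Mha
    by 2060 and ~935 Mha by 2100 on the default 2015–2100 grid, the ambition
    level of total country pledges.  ``shift`` subtracts a constant from every
    increment so part of the pooled distribution can be negative.
    """

    q90_first: float = 77.2
    q90_last: float = 32.7
    sigma: float = 0.8
    shift: float = 0.0
    base_forest: float = 4000.0
    base_pasture: float = 3000.0
    base_cropland: float = 1550.0
    pasture_coupling: float = 0.8  # Mha pasture lost per Mha forest gained
    coupling_noise: float = 5.0
    cropland_noise: float = 3.0
    regional_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "ASIA": 0.173,
            "EEU_REFSU": 0.108,
            "LAC": 0.274,
            "MAF": 0.230,
            "OECD90": 0.215,
        }
    )


def gen_scenario_db(
    n_scenarios: int,
    scopes: Sequence[str] = (WORLD_SCOPE,) + REGIONS,
    years: Sequence[int] = tuple(range(2015, 2101, 5)),
    seed: int = 0,
    shape: ScenarioShape | None = None,
) -> pd.DataFrame:
    """Generate a long-format scenario database.

    Columns: ``scenario_id, scope, variable, year, value`` with land areas in
    Mha on a 5-year grid, one forest / pasture / cropland trajectory per
    scenario and scope.  Deterministic given ``seed``.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    shp = shape or ScenarioShape()
    years = np.asarray(list(years), dtype=int)
    if years.size < 2:
        raise ValueError("need at least two years")
    nsteps = years.size - 1
    rng = np.random.default_rng(seed)

    # Per-step lognormal location so the pooled 90th percentile follows the
    # configured linear profile: q90 = exp(mu + 1.2816*sigma) - shift.
    q90 = np.linspace(shp.q90_first, shp.q90_last, nsteps)
    z90 = 1.2815515655446004

    records = []
    for scope in scopes:
        share = 1.0 if scope == WORLD_SCOPE else shp.regional_shares.get(scope)
        if share is None:
            raise ValueError(f"no regional share configured for scope {scope!r}")
        mu = np.log(np.maximum(q90 * share + shp.shift * share, 1e-9)) - z90 * shp.sigma
        inc = rng.lognormal(mean=mu, sigma=shp.sigma, size=(n_scenarios, nsteps))
        inc = inc - shp.shift * share
        forest = shp.base_forest * share + np.concatenate(
            [np.zeros((n_scenarios, 1)), np.cumsum(inc, axis=1)], axis=1
        )
        pasture_inc = (
            -shp.pasture_coupling * inc
            + rng.normal(0.0, shp.coupling_noise * share, size=inc.shape)
        )
        pasture = shp.base_pasture * share + np.concatenate(
            [np.zeros((n_scenarios, 1)), np.cumsum(pasture_inc, axis=1)], axis=1
        )
        crop_inc = rng.normal(0.0, shp.cropland_noise * share, size=inc.shape)
        cropland = shp.base_cropland * share + np.concatenate(
            [np.zeros((n_scenarios, 1)), np.cumsum(crop_inc, axis=1)], axis=1
        )
        for vname, vals in (
            ("forest", forest),
            ("pasture", np.clip(pasture, 0.0, None)),
            ("cropland", np.clip(cropland, 0.0, None)),
        ):
            for s in range(n_scenarios):
                records.append(
                    pd.DataFrame(
                        {
                            "scenario_id": f"S{s:04d}",
                            "scope": scope,
                            "variable": vname,
                            "year": years,
                            "value": np.clip(vals[s], 0.0, None),
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# ESM-like ensembles
# ---------------------------------------------------------------------------


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_steps: int, phi: float, sigma: float
) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_series, n_steps).

    The first value is drawn from the stationary distribution
    N(0, sigma^2/(1-phi^2)) so early years carry no spin-up artifact.
    """
    if sigma == 0.0:
        return np.zeros((n_series, n_steps))
    x = np.empty((n_series, n_steps))
    x[:, 0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2), size=n_series)
    innov = rng.normal(0.0, sigma, size=(n_series, n_steps - 1))
    for t in range(1, n_steps):
        x[:, t] = phi * x[:, t - 1] + innov[:, t - 1]
    return x


def gen_esm_ensemble(
    forced: ForcedTrajectory,
    phi: float,
    sigma: float,
    n_members: int,
    seed: int,
    grid: xr.Dataset | None = None,
    cell_signal: np.ndarray | None = None,
    cell_offset_scale: float = 0.5,
    offset_seed: int | None = None,
    experiment: str = "REF",
    variable: str = "tas",
    units: str = "degC",
) -> EnsembleSeries | GriddedEnsemble:
    """Ensemble = forced trajectory + stationary AR(1) internal variability.

    Without ``grid`` an :class:`EnsembleSeries` is returned.  With ``grid``
    each cell receives a static smooth offset (scale ``cell_offset_scale``),
    an optional deterministic ``cell_signal`` (shape (lat, lon) or
    (year, lat, lon)), and independent per-cell AR(1) noise.  Experiments to
    be compared cell-by-cell should share ``offset_seed`` so they share the
    same base climatology (defaults to ``seed``).
    """
    if abs(phi) >= 1:
        raise ValueError("|phi| must be < 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    nt = forced.years.size

    if grid is None:
        noise = _ar1_noise(rng, n_members, nt, phi, sigma)
        return EnsembleSeries(
            experiment=experiment,
            variable=variable,
            units=units,
            years=forced.years,
            values=forced.values[None, :] + noise,
        )

    nlat, nlon = grid.sizes["lat"], grid.sizes["lon"]
    ncell = nlat * nlon
    offset_rng = np.random.default_rng(seed if offset_seed is None else offset_seed)
    offset = cell_offset_scale * _smooth_field(offset_rng, nlat, nlon, 1.5)
    base = forced.values[None, :, None] + offset.ravel()[None, None, :]
    if cell_signal is not None:
        sig = np.asarray(cell_signal, dtype=float)
        if sig.shape == (nlat, nlon):
            base = base + sig.ravel()[None, None, :]
        elif sig.shape == (nt, nlat, nlon):
            base = base + sig.reshape(nt, ncell)[None, :, :]
        else:
            raise ValueError("cell_signal shape mismatch")
    noise = _ar1_noise(rng, n_members * ncell, nt, phi, sigma)
    noise = noise.reshape(n_members, ncell, nt).transpose(0, 2, 1)
    values = (base + noise).reshape(n_members, nt, nlat, nlon)
    return GriddedEnsemble(
        experiment=experiment,
        variable=variable,
        units=units,
        years=forced.years,
        values=values,
        lat=grid["lat"].values,
        lon=grid["lon"].values,
    )


# ---------------------------------------------------------------------------
# Carbon pools
# ---------------------------------------------------------------------------


def ssp534os_like_emissions(years: Sequence[int]) -> np.ndarray:
    """Yearly net CO2 emissions (GtCO2/yr) shaped like a high-overshoot pathway.

    High emissions rise to 2040, rapid decarbonization reaching net zero
    around 2070, net-negative (~-3.8 GtCO2/yr) thereafter.
    """
    years = np.asarray(list(years), dtype=float)
    return np.interp(years, [2015, 2040, 2070, 2075, 2100], [40.0, 55.0, 0.0, -3.8, -3.8])


def gen_carbon_pools(
    emissions: np.ndarray,
    years: Sequence[int],
    partition: tuple[float, float, float] = (0.45, 0.30, 0.25),
    seed: int = 0,
    noise_sd: float = 0.0,
    n_members: int = 1,
    extra_land_sink: np.ndarray | None = None,
    ocean_offset_frac: float = 0.26,
    experiment: str = "REF",
    initial_pools: Mapping[str, float] | None = None,
) -> dict[str, EnsembleSeries]:
    """Mass-conserving atmosphere/land/ocean carbon-pool deltas (GtCO2 vs year 0).

    Cumulative emissions are split by ``partition`` (atmosphere, land, ocean;
    must sum to 1).  Member noise is added to the land pool and subtracted
    from the atmosphere so conservation holds exactly: for every member and
    year the three pool deltas sum to cumulative emissions.

    ``extra_land_sink`` (GtCO2/yr) models additional AR-driven land uptake: it
    accumulates into the land pool, with a fraction ``ocean_offset_frac``
    compensated by reduced ocean uptake and the remainder drawn from the
    atmosphere, preserving the conservation identity.
    """
    years = np.asarray(list(years), dtype=int)
    emissions = np.asarray(emissions, dtype=float)
    if emissions.size != years.size:
        raise ValueError("emissions/years length mismatch")
    fa, fl, fo = partition
    if abs(fa + fl + fo - 1.0) > 1e-9:
        raise ValueError("partition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(emissions)
    cum = cum - cum[0]  # pool deltas relative to the first year

    atmo = np.tile(fa * cum, (n_members, 1))
    land = np.tile(fl * cum, (n_members, 1))
    ocean = np.tile(fo * cum, (n_members, 1))
    if noise_sd > 0:
        wiggle = np.cumsum(rng.normal(0.0, noise_sd, size=(n_members, years.size)), axis=1)
        wiggle -= wiggle[:, :1]
        land += wiggle
        atmo -= wiggle
    if extra_land_sink is not None:
        extra = np.cumsum(np.asarray(extra_land_sink, dtype=float))
        extra = extra - extra[0]
        land += extra
        ocean -= ocean_offset_frac * extra
        atmo -= (1.0 - ocean_offset_frac) * extra

    if initial_pools is not None:
        for name, delta in (("atmosphere", atmo), ("land", land), ("ocean", ocean)):
            base = initial_pools.get(name)
            if base is not None and np.any(delta + base < 0):
                warnings.warn(f"{name} pool goes negative", stacklevel=2)

    out = {}
    for name, delta in (("atmosphere", atmo), ("land", land), ("ocean", ocean)):
        out[name] = EnsembleSeries(
            experiment=experiment,
            variable=f"c_{name}",
            units="GtCO2",
            years=years,
            values=delta,
        )
    return out
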