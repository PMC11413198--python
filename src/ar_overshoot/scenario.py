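"""AR scenario construction: percentile targets and constrained allocation.

The scenario pipeline turns a scenario database plus a world grid into an
annual gridded afforestation/reforestation (AR) land-use trajectory:

1. pool per-scenario forest-area changes and take a high percentile as the
   global and regional yearly AR targets;
2. rescale regional targets so they sum to the global one;
3. annualize the 5-year series with shape-preserving cubic Hermite (PCHIP)
   interpolation of the cumulative curve;
4. distribute each region-year target across gridcells with an iterative
   uniform allocation, prioritized first by GRS restoration potential, then
   ATL, then any remaining eligible cell, converting pasture before
   rangeland and less biodiverse rangeland before more biodiverse.

AR only ever replaces grazing land; cropland and natural grassy biomes are
untouched, and the reference comparator holds land use constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import PchipInterpolator

from .synthetic import REGIONS, validate_world_grid

logger = logging.getLogger(__name__)

TIERS = ("GRS", "ATL", "other")
SOURCES = ("pasture", "rangeland_g1", "rangeland_g2", "rangeland_g3", "rangeland_g4")

_ATOL = 1e-6  # Mha tolerance for target attainment and conservation
_EPS = 1e-9  # Mha floor below which an allocation pass counts as stalled


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


@dataclass
class TargetSeries:
    """Yearly new-forest targets for one scope.

    ``increments[i]`` is the Mha of new forest added during ``years[i]``;
    ``increments[0]`` is 0 by convention (the base year).  Negative pooled
    percentiles are floored at zero upstream (AR-only scenario).
    """

    scope: str
    years: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.increments = np.asarray(self.increments, dtype=float)
        if self.years.size != self.increments.size:
            raise ValueError("years/increments length mismatch")
        if np.any(self.increments < -1e-12):
            raise ValueError("increments must be >= 0")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def increment_at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in target series")
        return float(self.increments[idx[0]])


def pooled_percentile_increments(
    db: pd.DataFrame,
    scope: str,
    percentile: float,
    variable: str = "forest",
) -> TargetSeries:
    """Percentile of pooled per-scenario area changes, per 5-year step.

    For each step the change from the previous database year is computed
    scenario-wise, all scenario changes are pooled, and the requested
    percentile (linear-interpolation quantile) is taken.  Scenarios missing
    either endpoint of a step are skipped for that step.  Negative pooled
    percentiles are floored at zero.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    sub = db[(db["scope"] == scope) & (db["variable"] == variable)]
    if sub.empty:
        raise ValueError(f"no scenarios for scope {scope!r}")
    wide = sub.pivot_table(index="scenario_id", columns="year", values="value")
    years = wide.columns.to_numpy(int)
    increments = np.zeros(years.size)
    for k in range(1, years.size):
        pair = wide[[years[k - 1], years[k]]].dropna()
        if len(pair) < len(wide):
            logger.info(
                "step %d-%d: skipped %d scenario(s) with missing years",
                years[k - 1], years[k], len(wide) - len(pair),
            )
        if pair.empty:
            raise ValueError(f"no complete scenario for step {years[k-1]}-{years[k]}")
        changes = pair[years[k]].to_numpy() - pair[years[k - 1]].to_numpy()
        increments[k] = max(float(np.percentile(changes, percentile)), 0.0)
    return TargetSeries(scope=scope, years=years, increments=increments)


def rescale_regional(
    regional: Mapping[str, TargetSeries], global_target: TargetSeries
) -> dict[str, TargetSeries]:
    """Rescale regional targets so their sum matches the global target each year.

    Relative magnitudes among regions are preserved exactly:
    ``out_r = r * global / sum_r``.
    """
    names = sorted(regional)
    years = global_target.years
    for r in names:
        if not np.array_equal(regional[r].years, years):
            raise ValueError("regional and global year grids differ")
    inc = np.vstack([regional[r].increments for r in names])
    total = inc.sum(axis=0)
    g = global_target.increments
    factor = np.ones_like(g)
    pos = total > 0
    factor[pos] = g[pos] / total[pos]
    bad = (~pos) & (g > 0)
    if np.any(bad):
        raise ValueError(
            f"all regional increments zero in year(s) {years[bad].tolist()} "
            "with a positive global target"
        )
    return {
        r: TargetSeries(scope=r, years=years.copy(), increments=inc[i] * factor)
        for i, r in enumerate(names)
    }


def interpolate_yearly(series: TargetSeries) -> TargetSeries:
    """Annualize a 5-year target series via PCHIP on the cumulative curve.

    The shape-preserving Hermite interpolant passes through the knots exactly
    and preserves monotonicity, so annual increments of a non-decreasing
    cumulative series stay non-negative.
    """
    if series.years.size < 2:
        raise ValueError("need at least two knots")
    cum = series.cumulative
    interp = PchipInterpolator(series.years.astype(float), cum)
    years = np.arange(series.years[0], series.years[-1] + 1)
    annual_cum = interp(years.astype(float))
    increments = np.diff(annual_cum, prepend=annual_cum[0])
    increments = np.clip(increments, 0.0, None)  # guard fp wiggle at machine scale
    return TargetSeries(scope=series.scope, years=years, increments=increments)


# ---------------------------------------------------------------------------
# Allocation configuration and rangeland classification
# ---------------------------------------------------------------------------


@dataclass
class AllocationConfig:
    """Constraint switches for the allocation engine.

    ``yearly_cap_frac`` is constraint (c): forest cover may rise by at most
    this fraction of cell area within a calendar year.  ``min_forest_frac``
    is constraint (d): the cell must historically have held, or potentially
    sustain, at least this forest cover.  The ``use_*`` switches reproduce
    the sensitivity configurations (drop biodiversity maps, GRS-only, no
    maps at all).
    """

    yearly_cap_frac: float = 0.10
    min_forest_frac: float = 0.20
    use_grs: bool = True
    use_atl: bool = True
    use_biodiversity: bool = True
    max_iterations: int = 10_000


def sensitivity_config(name: str) -> AllocationConfig:
    """Named sensitivity configurations for the scenario development."""
    if name == "default":
        return AllocationConfig()
    if name == "no_biodiversity":  # restoration maps only
        return AllocationConfig(use_biodiversity=False)
    if name == "grs_only":  # GRS + biodiversity maps, no ATL tier
        return AllocationConfig(use_atl=False)
    if name == "no_maps":  # neither restoration nor biodiversity maps
        return AllocationConfig(use_grs=False, use_atl=False, use_biodiversity=False)
    raise ValueError(f"unknown sensitivity configuration {name!r}")


def classify_rangelands(
    grid: xr.Dataset, config: AllocationConfig | None = None
) -> xr.Dataset:
    """Augment a world grid with the per-cell available grazing composition.

    Rangeland in Very Low Human Influence (VLHI) cells is considered close to
    pristine and excluded from availability.  Remaining rangeland is assigned
    to one of four biodiversity groups from the LHI agreement count (higher
    agreement = likely more biodiverse, converted later); an agreement count
    of 0 joins group 1.  Pasture is always fully available; natural grassy
    biomes are never part of availability.  With biodiversity maps switched
    off, no rangeland is excluded and all of it lands in group 1.
    """
    cfg = config or AllocationConfig()
    validate_world_grid(grid)
    out = grid.copy()
    rangeland = grid["frac_rangeland"].values
    if cfg.use_biodiversity:
        excluded = np.where(grid["vlhi_mask"].values.astype(bool), rangeland, 0.0)
        available = rangeland - excluded
        group = np.maximum(grid["lhi_agreement"].values, 1)
    else:
        excluded = np.zeros_like(rangeland)
        available = rangeland
        group = np.ones_like(grid["lhi_agreement"].values)
    out["frac_rangeland_excluded"] = (("lat", "lon"), excluded, {"units": "1"})
    for g in range(1, 5):
        out[f"frac_rangeland_g{g}"] = (
            ("lat", "lon"),
            np.where(group == g, available, 0.0),
            {"units": "1"},
        )
    return out


# ---------------------------------------------------------------------------
# Allocation state
# ---------------------------------------------------------------------------


@dataclass
class AllocationState:
    """Mutable per-cell bookkeeping of the allocation, in Mha.

    ``range_avail`` has one row per biodiversity group (1..4).  Ledger
    records accumulate in ``records`` (one dict per year/region) and the
    running totals in the ``tier_total`` / ``source_total`` /
    ``reforestation`` / ``afforestation`` fields.
    """

    year: int
    area: np.ndarray
    forest: np.ndarray
    pasture: np.ndarray
    range_avail: np.ndarray  # (4, ncell)
    range_excluded: np.ndarray
    grs: np.ndarray
    atl: np.ndarray
    forest_1850: np.ndarray
    eligible_d: np.ndarray
    region: np.ndarray
    config: AllocationConfig
    gain_this_year: np.ndarray = field(default=None)  # type: ignore[assignment]
    tier_total: dict = field(default_factory=lambda: {t: 0.0 for t in TIERS})
    source_total: dict = field(default_factory=lambda: {s: 0.0 for s in SOURCES})
    reforestation: float = 0.0
    afforestation: float = 0.0
    shortfall: dict = field(default_factory=dict)
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gain_this_year is None:
            self.gain_this_year = np.zeros_like(self.forest)

    @classmethod
    def from_grid(
        cls, grid: xr.Dataset, config: AllocationConfig | None = None, year: int = 2015
    ) -> "AllocationState":
        cfg = config or AllocationConfig()
        aug = classify_rangelands(grid, cfg)
        area = aug["cell_area"].values.ravel()
        to_mha = lambda name: aug[name].values.ravel() * area
        potential = aug["frac_potential_forest"].values.ravel()
        f1850 = aug["frac_forest_1850"].values.ravel()
        eligible_d = np.maximum(potential, f1850) >= cfg.min_forest_frac
        grs = to_mha("grs_potential") if cfg.use_grs else np.zeros_like(area)
        atl = to_mha("atl_potential") if cfg.use_atl else np.zeros_like(area)
        return cls(
            year=year,
            area=area,
            forest=to_mha("frac_forest"),
            pasture=to_mha("frac_pasture"),
            range_avail=np.vstack([to_mha(f"frac_rangeland_g{g}") for g in range(1, 5)]),
            range_excluded=to_mha("frac_rangeland_excluded"),
            grs=grs,
            atl=atl,
            forest_1850=f1850 * area,
            eligible_d=eligible_d,
            region=aug["region_id"].values.ravel().astype(int),
            config=cfg,
        )

    @property
    def rangeland(self) -> np.ndarray:
        """Total rangeland per cell (available groups + excluded), Mha."""
        return self.range_avail.sum(axis=0) + self.range_excluded

    @property
    def grazing_available(self) -> np.ndarray:
        return self.pasture + self.range_avail.sum(axis=0)

    def total_gain(self) -> float:
        return float(sum(self.tier_total.values()))

    def start_year(self, year: int) -> None:
        """Reset the within-calendar-year gain (constraint c) for a new year."""
        self.year = year
        self.gain_this_year = np.zeros_like(self.forest)


def _stage_stock(state: AllocationState, stage: int) -> np.ndarray:
    """Per-cell grazing stock convertible at source ``stage``.

    Stage 0 is pasture only; stage g adds rangeland biodiversity groups up
    to g.  Conversion proceeds region-wide from stage 0 upward, so less
    biodiverse rangeland anywhere in a region is consumed before more
    biodiverse rangeland is touched.
    """
    stock = state.pasture.copy()
    for g in range(stage):
        stock += state.range_avail[g]
    return stock


def _apply_take(
    state: AllocationState, idx: np.ndarray, take: np.ndarray, max_stage: int
) -> dict:
    """Convert ``take`` Mha of grazing land to forest in cells ``idx``.

    Within each cell, pasture is converted first, then rangeland groups in
    ascending biodiversity order up to ``max_stage``.  Returns the Mha
    converted per source and the reforestation/afforestation split.
    """
    by_source = {s: 0.0 for s in SOURCES}
    remaining = take.copy()
    pasture_take = np.minimum(remaining, state.pasture[idx])
    state.pasture[idx] -= pasture_take
    remaining -= pasture_take
    by_source["pasture"] = float(pasture_take.sum())
    for g in range(max_stage):
        g_take = np.minimum(remaining, state.range_avail[g, idx])
        state.range_avail[g, idx] -= g_take
        remaining -= g_take
        by_source[f"rangeland_g{g + 1}"] = float(g_take.sum())
    if np.any(remaining > _ATOL):
        raise RuntimeError("allocation exceeded grazing availability")

    reforest = np.clip(
        np.minimum(state.forest_1850[idx] - state.forest[idx], take), 0.0, None
    )
    afforest = take - reforest
    state.forest[idx] += take
    state.gain_this_year[idx] += take
    # GRS is a subset of ATL: any conversion consumes both potentials.
    state.grs[idx] = np.maximum(state.grs[idx] - take, 0.0)
    state.atl[idx] = np.maximum(state.atl[idx] - take, 0.0)
    by_source["reforestation"] = float(reforest.sum())
    by_source["afforestation"] = float(afforest.sum())
    return by_source


def allocate_year(
    state: AllocationState, regional_targets: Mapping[str, float]
) -> AllocationState:
    """Distribute one year's regional AR targets across gridcells, in place.

    Per region, three sequential tiers: cells with remaining GRS potential,
    then remaining ATL potential, then any cell passing the base constraints.
    Within a tier, sources open progressively region-wide — pasture first,
    then rangeland biodiversity groups in ascending order — and within each
    source stage the remaining target is split in equal Mha over currently
    eligible cells, each application capped by the cell's binding constraint
    (convertible grazing stock, tier potential, the within-year cap), the
    residual carried to the next iteration until the target is met or no
    cell can take more.  Infeasible targets produce a logged shortfall,
    never an exception.
    """
    cfg = state.config
    for r_idx, region in enumerate(REGIONS):
        target = float(regional_targets.get(region, 0.0))
        if target < 0:
            raise ValueError("targets must be >= 0")
        if target == 0.0:
            continue
        in_region = state.region == r_idx
        remaining = target
        tier_order = [t for t, use in zip(TIERS, (cfg.use_grs, cfg.use_atl, True)) if use]
        for tier in tier_order:
            for stage in range(5):  # pasture, then rangeland groups 1..4
                n_iter = 0
                while remaining > _ATOL:
                    n_iter += 1
                    if n_iter > cfg.max_iterations:
                        warnings.warn(
                            f"allocation hit iteration cap in {region} ({tier} tier)",
                            stacklevel=2,
                        )
                        break
                    cap_room = cfg.yearly_cap_frac * state.area - state.gain_this_year
                    capacity = np.minimum(_stage_stock(state, stage), cap_room)
                    if tier == "GRS":
                        capacity = np.minimum(capacity, state.grs)
                    elif tier == "ATL":
                        capacity = np.minimum(capacity, state.atl)
                    capacity = np.where(in_region & state.eligible_d, capacity, 0.0)
                    idx = np.flatnonzero(capacity > _EPS)
                    if idx.size == 0:
                        break
                    share = remaining / idx.size
                    take = np.minimum(share, capacity[idx])
                    applied = float(take.sum())
                    if applied <= _EPS:
                        break
                    by_source = _apply_take(state, idx, take, stage)
                    remaining -= applied
                    state.tier_total[tier] += applied
                    for s in SOURCES:
                        state.source_total[s] += by_source[s]
                    state.reforestation += by_source["reforestation"]
                    state.afforestation += by_source["afforestation"]
                    state.records.append(
                        {
                            "year": state.year,
                            "region": region,
                            "tier": tier,
                            "Mha": applied,
                            **{s: by_source[s] for s in SOURCES},
                            "reforestation": by_source["reforestation"],
                            "afforestation": by_source["afforestation"],
                        }
                    )
                if remaining <= _ATOL:
                    break
            if remaining <= _ATOL:
                break
        if remaining > _ATOL:
            logger.info(
                "year %d region %s: shortfall %.3f Mha", state.year, region, remaining
            )
            state.shortfall[(state.year, region)] = (
                state.shortfall.get((state.year, region), 0.0) + remaining
            )
    return state


# ---------------------------------------------------------------------------
# Full trajectory
# ---------------------------------------------------------------------------


@dataclass
class LandUseTrajectory:
    """Annual gridded AR land-use trajectory with conversion accounting."""

    dataset: xr.Dataset  # dims (year, lat, lon): forest/pasture/rangeland fractions
    ledger: pd.DataFrame  # year, region, tier, Mha, per-source and reforest split
    shortfall: pd.DataFrame  # year, region, Mha of unmet target
    tier_total: dict
    source_total: dict
    reforestation: float
    afforestation: float
    region_cumulative: pd.DataFrame  # year x region cumulative forest gain, Mha

    @property
    def years(self) -> np.ndarray:
        return self.dataset["year"].values

    def ar_area_series(self) -> pd.Series:
        """Global cumulative AR area (Mha) by year."""
        return self.region_cumulative.sum(axis=1)

    def ar_per_cell(self, year: int | None = None) -> np.ndarray:
        """Forest gain since the base year per cell (Mha), flattened."""
        year = int(self.years[-1]) if year is None else year
        area = self.dataset["cell_area"].values
        delta = (
            self.dataset["frac_forest"].sel(year=year).values
            - self.dataset["frac_forest"].isel(year=0).values
        )
        return (delta * area).ravel()

    def to_netcdf(self, path) -> None:
        self.dataset.to_netcdf(path, engine="scipy")

    def ledger_to_csv(self, path) -> None:
        self.ledger.to_csv(path, index=False)


def build_scenario(
    grid: xr.Dataset,
    regional_targets: Mapping[str, TargetSeries],
    config: AllocationConfig | None = None,
) -> LandUseTrajectory:
    """Apply :func:`allocate_year` over all years and assemble the trajectory.

    ``regional_targets`` maps each region name to its annual
    :class:`TargetSeries` (first year = base year, zero increment).  Regions
    are processed in fixed alphabetical order inside each year.
    """
    cfg = config or AllocationConfig()
    names = sorted(regional_targets)
    years = regional_targets[names[0]].years
    for r in names:
        if not np.array_equal(regional_targets[r].years, years):
            raise ValueError("regional target year grids differ")
    state = AllocationState.from_grid(grid, cfg, year=int(years[0]))
    nlat, nlon = grid.sizes["lat"], grid.sizes["lon"]
    shape = (nlat, nlon)
    area = state.area.reshape(shape)

    nyears = years.size
    forest = np.empty((nyears,) + shape)
    pasture = np.empty_like(forest)
    rangeland = np.empty_like(forest)
    region_cum = np.zeros((nyears, len(REGIONS)))

    forest0 = state.forest.copy()

    def snapshot(k: int) -> None:
        forest[k] = (state.forest / state.area).reshape(shape)
        pasture[k] = (state.pasture / state.area).reshape(shape)
        rangeland[k] = (state.rangeland / state.area).reshape(shape)
        gain = state.forest - forest0
        for i in range(len(REGIONS)):
            region_cum[k, i] = gain[state.region == i].sum()

    snapshot(0)
    for k in range(1, nyears):
        year = int(years[k])
        state.start_year(year)
        targets = {r: regional_targets[r].increment_at(year) for r in names}
        allocate_year(state, targets)
        snapshot(k)

    ds = xr.Dataset(
        {
            "frac_forest": (("year", "lat", "lon"), forest, {"units": "1"}),
            "frac_pasture": (("year", "lat", "lon"), pasture, {"units": "1"}),
            "frac_rangeland": (("year", "lat", "lon"), rangeland, {"units": "1"}),
            "frac_cropland": (("lat", "lon"), grid["frac_cropland"].values, {"units": "1"}),
            "frac_natural_grass": (
                ("lat", "lon"),
                grid["frac_natural_grass"].values,
                {"units": "1"},
            ),
            "cell_area": (("lat", "lon"), area, {"units": "Mha"}),
            "region_id": (("lat", "lon"), grid["region_id"].values),
        },
        coords={"year": years, "lat": grid["lat"].values, "lon": grid["lon"].values},
        attrs={"region_names": ",".join(REGIONS), "Conventions": "CF-1.8"},
    )
    ledger_cols = ["year", "region", "tier", "Mha", *SOURCES, "reforestation", "afforestation"]
    ledger = (
        pd.DataFrame(state.records, columns=ledger_cols)
        .groupby(["year", "region", "tier"], as_index=False)
        .sum()
        if state.records
        else pd.DataFrame(columns=ledger_cols)
    )
    shortfall = pd.DataFrame(
        [
            {"year": y, "region": r, "Mha": v}
            for (y, r), v in sorted(state.shortfall.items())
        ],
        columns=["year", "region", "Mha"],
    )
    return LandUseTrajectory(
        dataset=ds,
        ledger=ledger,
        shortfall=shortfall,
        tier_total=dict(state.tier_total),
        source_total=dict(state.source_total),
        reforestation=state.reforestation,
        afforestation=state.afforestation,
        region_cumulative=pd.DataFrame(region_cum, index=years, columns=list(REGIONS)),
    )


# ---------------------------------------------------------------------------
# Overlays
# ---------------------------------------------------------------------------


def overlay_indicator(
    traj: LandUseTrajectory,
    indicator: np.ndarray,
    threshold: float,
    direction: str = ">",
) -> tuple[float, float]:
    """(percent of total AR, Mha of AR) over cells where the indicator crosses.

    The AR area is the forest gain at the final year.  ``direction`` is the
    qualifying comparison of indicator against threshold (``">"`` or ``"<"``).
    """
    indicator = np.asarray(indicator, dtype=float)
    nlat = traj.dataset.sizes["lat"]
    nlon = traj.dataset.sizes["lon"]
    if indicator.shape != (nlat, nlon):
        raise ValueError("indicator grid shape mismatch")
    if direction == ">":
        qualifying = indicator.ravel() > threshold
    elif direction == "<":
        qualifying = indicator.ravel() < threshold
    else:
        raise ValueError("direction must be '>' or '<'")
    ar = traj.ar_per_cell()
    total = float(ar.sum())
    mha = float(ar[qualifying].sum())
    pct = 100.0 * mha / total if total > 0 else 0.0
    return pct, mha


def composite_governance(
    components: pd.DataFrame, subregion: pd.Series | None = None
) -> pd.Series:
    """Composite governance indicator: arithmetic mean of six components.

    ``components`` has one row per country and six indicator columns.
    Missing country values are filled with the arithmetic mean of the
    country's subregion (per component) before averaging; a component that
    is missing for an entire subregion with no fallback raises.
    """
    if components.shape[1] != 6:
        raise ValueError("expected six governance components")
    filled = components.copy()
    if subregion is not None:
        sub = subregion.reindex(components.index)
        for col in filled.columns:
            means = filled[col].groupby(sub).transform("mean")
            filled[col] = filled[col].fillna(means)
    if filled.isna().any().any():
        bad = filled.index[filled.isna().any(axis=1)].tolist()
        raise ValueError(f"components missing after subregion fill for: {bad}")
    return filled.mean(axis=1)
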