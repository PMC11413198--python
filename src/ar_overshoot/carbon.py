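"""Carbon budgets, unit conversions and CDR-efficiency arithmetic.

All budgets are tracked in GtCO2; conversions to PgC use the CO2:C molar
mass ratio 44/12 and to ppm the standard 2.124 PgC per ppm of atmospheric
CO2.  Efficiency metrics express the carbon-cycle response to
afforestation/reforestation: how much of the extra land sink is offset by
reduced ocean uptake, the net atmospheric removal per unit land
sequestration, and temperature reduction per unit carbon or area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import EnsembleSeries

GTCO2_PER_PGC = 44.0 / 12.0
PGC_PER_PPM = 2.124

POOLS = ("atmosphere", "land", "ocean")


def convert_carbon_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between GtCO2, PgC and ppm (atmospheric CO2 equivalent)."""
    units = {"GtCO2", "PgC", "ppm"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be one of {sorted(units)}")
    value = float(value)
    # normalize to PgC
    if from_unit == "GtCO2":
        pgc = value / GTCO2_PER_PGC
    elif from_unit == "ppm":
        pgc = value * PGC_PER_PPM
    else:
        pgc = value
    if to_unit == "GtCO2":
        return pgc * GTCO2_PER_PGC
    if to_unit == "ppm":
        return pgc / PGC_PER_PPM
    return pgc


def round_printed(value: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention used for printed figures."""
    factor = 10.0**ndigits
    return np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor


@dataclass
class CarbonBudget:
    """AR-REF carbon-pool differences re-based to a baseline year.

    ``deltas[pool]`` is the per-year AR-REF ensemble-mean difference in
    GtCO2, zero at ``baseline_year``.  Optional AR area (Mha) and
    temperature difference (degC) series enable the efficiency metrics.
    """

    years: np.ndarray
    deltas: dict  # pool -> np.ndarray, GtCO2
    baseline_year: int
    ar_area: np.ndarray | None = None  # Mha
    dt: np.ndarray | None = None  # degC, AR-REF
    units: str = "GtCO2"

    def at(self, year: int) -> dict:
        i = int(np.flatnonzero(self.years == year)[0])
        out = {pool: float(self.deltas[pool][i]) for pool in self.deltas}
        if self.ar_area is not None:
            out["ar_area"] = float(self.ar_area[i])
        if self.dt is not None:
            out["dt"] = float(self.dt[i])
        return out


def budget_deltas(
    ar_pools: Mapping[str, EnsembleSeries],
    ref_pools: Mapping[str, EnsembleSeries],
    baseline_year: int,
    ar_area: np.ndarray | None = None,
    dt: np.ndarray | None = None,
) -> CarbonBudget:
    """Per-year ensemble-mean AR-REF pool differences, re-based.

    Both experiments must cover the same years; the difference at the
    baseline year is exactly zero by construction.
    """
    pools = sorted(set(ar_pools) & set(ref_pools))
    if not pools:
        raise ValueError("no common pools")
    years = ar_pools[pools[0]].years
    for p in pools:
        if not (
            np.array_equal(ar_pools[p].years, years)
            and np.array_equal(ref_pools[p].years, years)
        ):
            raise ValueError("pool series years mismatch")
    if baseline_year not in years:
        raise ValueError("baseline year outside record")
    i0 = int(np.flatnonzero(years == baseline_year)[0])
    deltas = {}
    for p in pools:
        d = ar_pools[p].mean() - ref_pools[p].mean()
        deltas[p] = d - d[i0]
    return CarbonBudget(
        years=years.copy(),
        deltas=deltas,
        baseline_year=baseline_year,
        ar_area=None if ar_area is None else np.asarray(ar_area, dtype=float),
        dt=None if dt is None else np.asarray(dt, dtype=float),
    )


@dataclass
class EfficiencyMetrics:
    """CDR-efficiency arithmetic at a reference year.

    Percent metrics relate the pools: the ocean offset is the share of the
    extra land sink compensated by reduced ocean uptake, and the net removal
    efficiency the share actually removed from the atmosphere; under mass
    conservation the two add to 100%.  Rates divide cumulative totals by the
    elapsed years of the record.
    """

    at_year: int
    dc_land: float
    dc_ocean: float
    dc_atmo: float
    ocean_offset_pct: float | None
    net_removal_efficiency_pct: float | None
    degc_per_100gtco2_land: float | None
    degc_per_100gtco2_atmo: float | None
    degc_per_100mha: float | None
    gtco2_land_per_100mha: float | None
    mean_land_rate_gtco2_yr: float
    mean_atmo_removal_rate_gtco2_yr: float
    elapsed_years: int
    flags: list = field(default_factory=list)


def efficiency_metrics(budget: CarbonBudget, at_year: int) -> EfficiencyMetrics:
    """Compute the efficiency metrics record at ``at_year``.

    Ratios are undefined (None, with a flag) when the extra land sink is
    zero.  Mean annual rates use the elapsed years from the baseline year.
    """
    vals = budget.at(at_year)
    land = vals.get("land")
    ocean = vals.get("ocean")
    atmo = vals.get("atmosphere")
    if land is None or ocean is None or atmo is None:
        raise ValueError("budget must carry land, ocean and atmosphere deltas")
    elapsed = at_year - budget.baseline_year
    if elapsed <= 0:
        raise ValueError("at_year must be after the baseline year")
    flags = []
    area = vals.get("ar_area")
    dt = vals.get("dt")

    def ratio(num, den, scale=100.0):
        if den is None or den == 0:
            return None
        return scale * num / den

    if land == 0:
        flags.append("dc_land is zero: ratio metrics undefined")
        ocean_offset = net_eff = degc_land = gtco2_area = None
    else:
        ocean_offset = -100.0 * ocean / land
        net_eff = -100.0 * atmo / land
        degc_land = ratio(-dt, land) if dt is not None else None
        gtco2_area = ratio(land, area) if area else None
    degc_atmo = ratio(dt, atmo) if (dt is not None and atmo) else None
    degc_area = ratio(-dt, area) if (dt is not None and area) else None
    if dt is None:
        flags.append("no temperature series: degC metrics undefined")
    if area is None:
        flags.append("no AR area series: per-area metrics undefined")
    return EfficiencyMetrics(
        at_year=at_year,
        dc_land=land,
        dc_ocean=ocean,
        dc_atmo=atmo,
        ocean_offset_pct=ocean_offset,
        net_removal_efficiency_pct=net_eff,
        degc_per_100gtco2_land=degc_land,
        degc_per_100gtco2_atmo=degc_atmo,
        degc_per_100mha=degc_area,
        gtco2_land_per_100mha=gtco2_area,
        mean_land_rate_gtco2_yr=land / elapsed,
        mean_atmo_removal_rate_gtco2_yr=-atmo / elapsed,
        elapsed_years=elapsed,
        flags=flags,
    )


def sink_transition_year(
    pool_series: np.ndarray,
    years: np.ndarray,
    smooth_window: int = 11,
    polyorder: int = 3,
) -> int | None:
    """First year the smoothed pool's year-on-year rate turns negative for good.

    The pool series (GtCO2) is smoothed with a Savitzky-Golay filter (order
    3, even windows rounded up to odd); the transition is the first year
    whose rate of change is strictly negative and stays negative through the
    end of the record.  Returns None if the stock never becomes a source
    (a flat stock, rate 0, is not a source).
    """
    y = np.asarray(pool_series, dtype=float).ravel()
    years = np.asarray(years, dtype=int)
    if y.size != years.size:
        raise ValueError("series/years length mismatch")
    wl = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    if y.size < wl:
        raise ValueError("series shorter than smoothing window")
    sm = savgol_filter(y, wl, min(polyorder, wl - 1))
    rate = np.diff(sm)
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))  # flat stock is not a source
    neg = rate < -tol
    if not neg[-1]:
        return None
    nonneg_idx = np.flatnonzero(~neg)
    first = int(nonneg_idx[-1]) + 1 if nonneg_idx.size else 0
    return int(years[first + 1])


def pools_to_frame(pools: Mapping[str, Mapping[str, EnsembleSeries]]) -> pd.DataFrame:
    """Long-format pool table: experiment, pool, year, value (ensemble mean)."""
    rows = []
    for exp, by_pool in pools.items():
        for pool, series in by_pool.items():
            mean = series.mean()
            for yr, v in zip(series.years, mean):
                rows.append({"experiment": exp, "pool": pool, "year": int(yr), "GtCO2": v})
    return pd.DataFrame(rows)
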