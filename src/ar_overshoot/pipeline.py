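"""End-to-end orchestration: generate -> build scenario -> diagnose.

A single :class:`RunConfig` drives the whole desk-scale pipeline on
synthetic inputs: world grid and scenario database, percentile AR targets,
constrained allocation, forced-plus-AR(1) temperature ensembles for the AR
and REF experiments, emergence/duration/peak diagnostics, gridcell field
significance, and the carbon budget with efficiency metrics.  Every stage
seed is explicit and the run manifest carries a content checksum per
artifact, so reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import carbon, fieldsig, overshoot, scenario, synthetic
from .synthetic import REGIONS, WORLD_SCOPE, ForcedTrajectory


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Statistical draw counts default to desk-scale values (200 bootstrap and
    null draws); the per-operation defaults of the library functions remain
    1000 when called directly.
    """

    seed: int = 7
    # world and scenario database
    nlat: int = 16
    nlon: int = 32
    n_scenarios: int = 200
    percentile: float = 90.0
    start_year: int = 2015
    end_year: int = 2100
    # allocation constraints
    yearly_cap_frac: float = 0.10
    min_forest_frac: float = 0.20
    sensitivity: str = "default"
    # ensembles
    n_members: int = 10
    phi: float = 0.5
    sigma: float = 0.08
    # forced overshoot trajectories (REF and AR experiments)
    t_start: float = 1.2
    threshold: float = 1.5
    ref_up_year: int = 2035
    ref_peak_year: int = 2058
    ref_peak: float = 2.06
    ref_down_year: int = 2099
    ref_eoc: float = 1.49
    ar_up_year: int = 2036
    ar_peak_year: int = 2058
    ar_peak: float = 1.98
    ar_down_year: int = 2087
    ar_eoc: float = 1.31
    # statistics
    emergence_windows: tuple = (5, 6, 7, 8, 9, 10)
    duration_windows: tuple = (5, 6, 7, 8, 9, 10)
    field_windows: tuple = (1, 2, 3, 4, 5)
    field_consec: tuple = (1, 2, 3)
    n_boot: int = 200
    n_null: int = 200
    alpha: float = 0.05
    # carbon cycle
    land_seq_rate_per_mha: float = 0.008  # GtCO2/yr per Mha of standing AR
    ocean_offset_frac: float = 0.26
    pool_noise_sd: float = 0.2
    # per-stage seeds; filled deterministically from `seed` when omitted
    seed_grid: int | None = None
    seed_db: int | None = None
    seed_ens: int | None = None
    seed_stats: int | None = None
    seed_pools: int | None = None

    def __post_init__(self) -> None:
        for i, name in enumerate(
            ("seed_grid", "seed_db", "seed_ens", "seed_stats", "seed_pools")
        ):
            if getattr(self, name) is None:
                setattr(self, name, (self.seed * 1000 + i) % (2**31))
        for name in ("emergence_windows", "duration_windows", "field_windows", "field_consec"):
            setattr(self, name, tuple(int(v) for v in getattr(self, name)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(cfg: RunConfig) -> list[str]:
    """Range-check a config; returns a human-readable list of errors."""
    errors = []

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    check(0 < cfg.percentile < 100, f"percentile must be in (0, 100), got {cfg.percentile}")
    check(0 < cfg.alpha < 1, f"alpha must be in (0, 1), got {cfg.alpha}")
    check(abs(cfg.phi) < 1, f"|phi| must be < 1, got {cfg.phi}")
    check(cfg.sigma >= 0, f"sigma must be >= 0, got {cfg.sigma}")
    check(cfg.nlat >= 2 and cfg.nlon >= 2, "grid must be at least 2x2")
    check(cfg.n_scenarios >= 1, "n_scenarios must be >= 1")
    check(cfg.n_members >= 2, "n_members must be >= 2")
    check(cfg.start_year < cfg.end_year, "start_year must precede end_year")
    check(0 < cfg.yearly_cap_frac <= 1, "yearly_cap_frac must be in (0, 1]")
    check(0 <= cfg.min_forest_frac <= 1, "min_forest_frac must be in [0, 1]")
    for name in ("emergence_windows", "duration_windows", "field_windows", "field_consec"):
        check(all(w >= 1 for w in getattr(cfg, name)), f"{name} must all be >= 1")
    check(cfg.n_boot >= 1 and cfg.n_null >= 1, "draw counts must be >= 1")
    try:
        scenario.sensitivity_config(cfg.sensitivity)
    except ValueError as exc:
        errors.append(str(exc))
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summary(obj):
    """JSON-serializable view of a dataclass result, drop bulky traces."""
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if f.name in ("traces", "pvalues", "reject"):
                continue
            out[f.name] = _summary(v)
        return out
    if isinstance(obj, dict):
        return {str(k): _summary(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_summary(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    artifacts: dict[str, Path] = {}

    # --- stage 1: synthetic world and scenario database -------------------
    grid = synthetic.gen_world_grid(cfg.nlat, cfg.nlon, seed=cfg.seed_grid)
    grid.to_netcdf(outdir / "grid.nc", engine="scipy")
    artifacts["grid"] = outdir / "grid.nc"
    db = synthetic.gen_scenario_db(
        cfg.n_scenarios,
        years=range(cfg.start_year, cfg.end_year + 1, 5),
        seed=cfg.seed_db,
    )
    db.to_csv(outdir / "scenario_db.csv", index=False)
    artifacts["scenario_db"] = outdir / "scenario_db.csv"

    # --- stage 2: AR targets and allocation --------------------------------
    global_target = scenario.pooled_percentile_increments(db, WORLD_SCOPE, cfg.percentile)
    regional = {
        r: scenario.pooled_percentile_increments(db, r, cfg.percentile) for r in REGIONS
    }
    regional = scenario.rescale_regional(regional, global_target)
    annual = {r: scenario.interpolate_yearly(t) for r, t in regional.items()}
    alloc_cfg = scenario.sensitivity_config(cfg.sensitivity)
    alloc_cfg.yearly_cap_frac = cfg.yearly_cap_frac
    alloc_cfg.min_forest_frac = cfg.min_forest_frac
    traj = scenario.build_scenario(grid, annual, alloc_cfg)
    traj.to_netcdf(outdir / "trajectory.nc")
    traj.ledger_to_csv(outdir / "ledger.csv")
    artifacts["trajectory"] = outdir / "trajectory.nc"
    artifacts["ledger"] = outdir / "ledger.csv"
    ar_area = traj.ar_area_series().to_numpy()

    # --- stage 3: temperature ensembles ------------------------------------
    forced_ref = ForcedTrajectory.overshoot(
        years=years, t_start=cfg.t_start, threshold=cfg.threshold,
        up_year=cfg.ref_up_year, peak_year=cfg.ref_peak_year,
        peak_value=cfg.ref_peak, down_year=cfg.ref_down_year, t_end=cfg.ref_eoc,
    )
    forced_ar = ForcedTrajectory.overshoot(
        years=years, t_start=cfg.t_start, threshold=cfg.threshold,
        up_year=cfg.ar_up_year, peak_year=cfg.ar_peak_year,
        peak_value=cfg.ar_peak, down_year=cfg.ar_down_year, t_end=cfg.ar_eoc,
    )
    ens_ref = synthetic.gen_esm_ensemble(
        forced_ref, cfg.phi, cfg.sigma, cfg.n_members, seed=cfg.seed_ens,
        experiment="REF",
    )
    ens_ar = synthetic.gen_esm_ensemble(
        forced_ar, cfg.phi, cfg.sigma, cfg.n_members, seed=cfg.seed_ens + 1,
        experiment="AR",
    )
    ens_ref.to_csv(outdir / "tas_ref.csv")
    ens_ar.to_csv(outdir / "tas_ar.csv")
    artifacts["tas_ref"] = outdir / "tas_ref.csv"
    artifacts["tas_ar"] = outdir / "tas_ar.csv"

    # --- stage 4: global diagnostics ----------------------------------------
    emergence = overshoot.detect_emergence(
        ens_ref, ens_ar, windows=cfg.emergence_windows, n_boot=cfg.n_boot,
        n_null=cfg.n_null, alpha=cfg.alpha, seed=cfg.seed_stats,
    )
    dur_ref = overshoot.overshoot_duration(
        ens_ref, cfg.threshold, windows=cfg.duration_windows,
        n_boot=cfg.n_boot, seed=cfg.seed_stats + 1,
    )
    dur_ar = overshoot.overshoot_duration(
        ens_ar, cfg.threshold, windows=cfg.duration_windows,
        n_boot=cfg.n_boot, seed=cfg.seed_stats + 2,
    )
    peak_ref = overshoot.peak_and_eoc_stats(
        ens_ref, eoc_years=(cfg.end_year - 4, cfg.end_year),
        thresholds=(cfg.threshold, 2.0),
    )
    peak_ar = overshoot.peak_and_eoc_stats(
        ens_ar, eoc_years=(cfg.end_year - 4, cfg.end_year),
        thresholds=(cfg.threshold, 2.0),
    )

    # --- stage 5: gridded field significance --------------------------------
    frac_gain = (
        traj.dataset["frac_forest"].values
        - traj.dataset["frac_forest"].values[0][None, :, :]
    )
    cooling = -0.5 * frac_gain  # local extra cooling at forestation sites
    grid_ref = synthetic.gen_esm_ensemble(
        forced_ref, cfg.phi, cfg.sigma, cfg.n_members, seed=cfg.seed_ens + 2,
        grid=grid, offset_seed=cfg.seed_ens, experiment="REF",
    )
    grid_ar = synthetic.gen_esm_ensemble(
        forced_ar, cfg.phi, cfg.sigma, cfg.n_members, seed=cfg.seed_ens + 3,
        grid=grid, offset_seed=cfg.seed_ens, cell_signal=cooling, experiment="AR",
    )
    sig = fieldsig.field_significance(
        grid_ar, grid_ref, alpha=cfg.alpha,
        windows=cfg.field_windows, consec=cfg.field_consec,
    )

    # --- stage 6: carbon budget ---------------------------------------------
    emissions = synthetic.ssp534os_like_emissions(years)
    ref_pools = synthetic.gen_carbon_pools(
        emissions, years, seed=cfg.seed_pools, noise_sd=cfg.pool_noise_sd,
        n_members=cfg.n_members, experiment="REF",
    )
    extra_sink = cfg.land_seq_rate_per_mha * ar_area
    ar_pools = synthetic.gen_carbon_pools(
        emissions, years, seed=cfg.seed_pools, noise_sd=cfg.pool_noise_sd,
        n_members=cfg.n_members, extra_land_sink=extra_sink,
        ocean_offset_frac=cfg.ocean_offset_frac, experiment="AR",
    )
    carbon.pools_to_frame({"REF": ref_pools, "AR": ar_pools}).to_csv(
        outdir / "pools.csv", index=False
    )
    artifacts["pools"] = outdir / "pools.csv"
    budget = carbon.budget_deltas(
        ar_pools, ref_pools, baseline_year=cfg.start_year,
        ar_area=ar_area, dt=forced_ar.values - forced_ref.values,
    )
    metrics = carbon.efficiency_metrics(budget, at_year=cfg.end_year)
    transition = {
        exp: carbon.sink_transition_year(pools["land"].mean(), years)
        for exp, pools in (("REF", ref_pools), ("AR", ar_pools))
    }

    summary = {
        "targets": {
            "global_cumulative_2060": float(
                global_target.cumulative[global_target.years <= 2060][-1]
            ),
            "global_cumulative_final": float(global_target.cumulative[-1]),
        },
        "scenario": {
            "total_ar_mha": float(traj.ar_area_series().iloc[-1]),
            "tier_total": traj.tier_total,
            "source_total": traj.source_total,
            "reforestation_mha": traj.reforestation,
            "afforestation_mha": traj.afforestation,
            "shortfall_mha": float(traj.shortfall["Mha"].sum())
            if len(traj.shortfall) else 0.0,
        },
        "emergence": _summary(emergence),
        "duration": {"REF": _summary(dur_ref), "AR": _summary(dur_ar)},
        "peak_eoc": {"REF": _summary(peak_ref), "AR": _summary(peak_ar)},
        "field_significance": {
            "alpha_cell": sig.alpha_cell,
            "emergence": {f"w{w}_k{k}": y for (w, k), y in sig.emergence.items()},
        },
        "carbon": {
            "metrics": _summary(metrics),
            "sink_transition_year": transition,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts["summary"] = outdir / "summary.json"
    cfg.to_yaml(outdir / "config.yaml")
    artifacts["config"] = outdir / "config.yaml"

    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in dataclasses.asdict(cfg).items()},
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()
        },
        "headline": {
            "emergence_year": summary["emergence"]["emergence_year"],
            "duration_ref": dur_ref.duration_mean,
            "duration_ar": dur_ar.duration_mean,
            "peak_reduction": peak_ref.peak_mean - peak_ar.peak_mean,
            "eoc_reduction": peak_ref.eoc_mean - peak_ar.eoc_mean,
            "total_ar_mha": summary["scenario"]["total_ar_mha"],
            "net_removal_efficiency_pct": metrics.net_removal_efficiency_pct,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
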