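"""Stage orchestration: simulate -> flux -> tracer -> kinetics -> lag -> report.

Interchange is plain CSV (there is no domain-standard binary container for
chamber or pool tables); every stage validates its input schema up front and
names any missing columns.  A run writes a manifest (canonical config, its
SHA-256 hash, package version, seed) so that config + seed fully determine
every stochastic output: two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._errors import SchemaError
from .isotope import atom_fraction_to_delta, keeling_intercept
from .fluxes import correct_geogenic
from .kinetics import FIRST_CYCLE_H, fit_exponential, prepare_sr_series
from .lags import lag_scan, permutation_anova
from .simulate import (
    PlotDesign,
    SimConfig,
    default_design,
    ground_truth,
    sample_pools,
    simulate_drivers,
    simulate_sr_observations,
)
from .tracer import cumulative_sr_excess, excess_table, sr_excess_rate

logger = logging.getLogger(__name__)

SR_SERIES_COLUMNS = ("plot_id", "time_h", "sr_total_flux", "sr_delta_permil",
                     "sr13_excess_rate_mg_h", "par", "soil_temp_c", "swc_vol_pct")
DRIVER_NAMES = ("par", "soil_temp_c", "swc_vol_pct")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-loadable and hashable."""

    outdir: str = "isopulse_out"
    seed: int = 0
    duration_d: float = 10.0
    sr_step_h: float = 2.4
    qc_r2_min: float = 0.9
    noiseless: bool = False
    stages: tuple = ("simulate", "flux", "tracer", "mrt", "lag", "report")
    sim: dict = field(default_factory=dict)   # SimConfig field overrides
    warming_high_threshold: float = 5.1       # grouping for the lag ANOVA
    warming_low_threshold: float = 1.5
    n_perm: int = 9999

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def canonical_json(self) -> str:
        # the hashable identity covers the computation, not the destination
        d = dataclasses.asdict(self)
        d.pop("outdir")
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _json_sanitize(obj):
    """Replace non-finite floats with None so emitted JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (np.floating, np.integer)):
        return _json_sanitize(float(obj))
    return obj


def require_columns(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required columns: {missing}")


def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate design, pool, SR-series tables and the ground-truth JSON."""
    sim = config.sim_config()
    designs = default_design()
    rng = np.random.default_rng(config.seed)

    design_df = pd.DataFrame([dataclasses.asdict(d) for d in designs])
    pools = sample_pools(sim, designs, noiseless=config.noiseless, rng=rng)

    sr_rows = []
    for d in designs:
        obs = simulate_sr_observations(sim, d, duration_d=config.duration_d,
                                       step_h=config.sr_step_h,
                                       noiseless=config.noiseless, rng=rng)
        drv = simulate_drivers(sim, d, noiseless=config.noiseless,
                               t_h=obs["t_h"], rng=rng)
        # geogenic admixture dilutes the biogenic signature toward -4.7 permil
        f_geo = sim.geogenic_flux / np.maximum(obs["sr_total_flux"], 1e-12)
        f_geo = np.clip(f_geo, 0.0, 1.0)
        sr_delta = f_geo * sim.delta_geogenic + (1 - f_geo) * sim.delta_biogenic
        sr_rows.append(pd.DataFrame({
            "plot_id": d.plot_id, "time_h": obs["t_h"],
            "sr_total_flux": obs["sr_total_flux"],
            "sr_delta_permil": sr_delta,
            "sr13_excess_rate_mg_h": obs["sr13_excess_rate_mg_h"],
            "par": drv["par"],
            "soil_temp_c": drv["soil_temp_c"],
            "swc_vol_pct": drv["swc_vol_pct"],
        }))
    sr_df = pd.concat(sr_rows, ignore_index=True)

    design_df.to_csv(outdir / "design.csv", index=False)
    pools.to_csv(outdir / "pools.csv", index=False)
    sr_df.to_csv(outdir / "sr_series.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth(sim, designs), fh, indent=2, sort_keys=True)
    return {"design": design_df, "pools": pools, "sr_series": sr_df}


def flux_stage(config: RunConfig, outdir: Path, sr_df: pd.DataFrame) -> pd.DataFrame:
    """Geogenic-correct the SR series via the two-pool mixing model."""
    require_columns(sr_df, ("plot_id", "time_h", "sr_total_flux",
                            "sr_delta_permil"), "sr_series")
    bio, fgeo, clipped = [], [], []
    for tot, dlt in zip(sr_df["sr_total_flux"], sr_df["sr_delta_permil"]):
        b, mix = correct_geogenic(float(tot), float(dlt))
        bio.append(b)
        fgeo.append(mix.f_geo)
        clipped.append(mix.clipped)
    out = sr_df.copy()
    out["sr_bio_flux"] = bio
    out["f_geo"] = fgeo
    out["mixing_clipped"] = clipped
    out.to_csv(outdir / "sr_flux_corrected.csv", index=False)
    logger.info("flux stage: %d records, %d clipped mixing fractions",
                len(out), int(np.sum(clipped)))
    return out


def tracer_stage(config: RunConfig, outdir: Path, pools: pd.DataFrame,
                 sr_df: pd.DataFrame) -> dict:
    """Excess/recovery table for pools plus cumulative SR recovery per plot."""
    exc = excess_table(pools)
    exc.to_csv(outdir / "excess_table.csv", index=False)

    require_columns(sr_df, ("plot_id", "time_h", "sr13_excess_rate_mg_h"), "sr_series")
    shoot_t0 = (exc[(exc["pool"] == "shoot") & (exc["day_since_label"] == 0)]
                .set_index("plot_id")["excess_mg_m2"])
    rows = []
    for plot, grp in sr_df.groupby("plot_id", sort=True):
        t = grp["time_h"].to_numpy()
        cum = cumulative_sr_excess(t, grp["sr13_excess_rate_mg_h"].to_numpy())
        denom = shoot_t0.get(plot, float("nan"))
        rows.append({"plot_id": plot, "cum_sr_excess_mg_m2": float(cum[-1]),
                     "cum_sr_recovery_pct": float(100.0 * cum[-1] / denom)
                     if np.isfinite(denom) and denom > 0 else float("nan")})
    sr_rec = pd.DataFrame(rows)
    sr_rec.to_csv(outdir / "sr_recovery.csv", index=False)
    return {"excess": exc, "sr_recovery": sr_rec}


def mrt_stage(config: RunConfig, outdir: Path, exc: pd.DataFrame,
              sr_df: pd.DataFrame) -> pd.DataFrame:
    """Per-plot exponential decay fits: shoots (days) and SR 13C (hours)."""
    rows = []
    for plot, grp in exc[exc["pool"] == "shoot"].groupby("plot_id", sort=True):
        g = grp.dropna(subset=["excess_mg_m2"]).sort_values("day_since_label")
        if len(g) < 3:
            continue
        fit = fit_exponential(g["day_since_label"].to_numpy(),
                              g["excess_mg_m2"].to_numpy(), units="d")
        rows.append({"plot_id": plot, "pool": "shoot", "A": fit.A, "b": fit.b,
                     "mrt": fit.mrt, "units": fit.units, "rss": fit.rss,
                     "n_points": fit.n_points, "converged": fit.converged})
    for plot, grp in sr_df.groupby("plot_id", sort=True):
        t, y = prepare_sr_series(grp["time_h"].to_numpy(),
                                 grp["sr13_excess_rate_mg_h"].to_numpy())
        fit = fit_exponential(t, y, units="h")
        rows.append({"plot_id": plot, "pool": "sr", "A": fit.A, "b": fit.b,
                     "mrt": fit.mrt, "units": fit.units, "rss": fit.rss,
                     "n_points": fit.n_points, "converged": fit.converged})
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "decay_fits.csv", index=False)
    return fits


def lag_stage(config: RunConfig, outdir: Path, sr_df: pd.DataFrame,
              design_df: pd.DataFrame) -> dict:
    """Per-plot per-driver lag scans and permutation tests on best lags."""
    require_columns(sr_df, SR_SERIES_COLUMNS[:3] + ("par", "soil_temp_c",
                                                    "swc_vol_pct"), "sr_series")
    scan_rows, best_rows = [], []
    for plot, grp in sr_df.groupby("plot_id", sort=True):
        t = grp["time_h"].to_numpy()
        for response in ("sr_total_flux", "sr13_excess_rate_mg_h"):
            for driver in DRIVER_NAMES:
                try:
                    scan = lag_scan(t, grp[response].to_numpy(),
                                    grp[driver].to_numpy(), step_h=config.sr_step_h,
                                    detrend="diel")
                except Exception as err:  # flat SWC etc. -> undefined scan
                    logger.info("lag scan skipped (%s, %s vs %s): %s",
                                plot, response, driver, err)
                    continue
                for s, c in zip(scan.shifts, scan.coefficients):
                    scan_rows.append({"plot_id": plot, "response": response,
                                      "driver": driver, "shift_h": s,
                                      "coefficient": c})
                best_rows.append({"plot_id": plot, "response": response,
                                  "driver": driver, "best_lag_h": scan.best_lag,
                                  "best_coefficient": scan.best_coefficient})
    scans = pd.DataFrame(scan_rows)
    best = pd.DataFrame(best_rows)
    scans.to_csv(outdir / "lag_scans.csv", index=False)
    best.to_csv(outdir / "lag_best.csv", index=False)

    # permutation ANOVA of PAR->SR best lags: warming group and N addition
    meta = design_df.set_index("plot_id")
    tests = {}
    sel = best[(best["driver"] == "par") & (best["response"] == "sr_total_flux")]
    if len(sel) >= 4:
        lags_v = sel["best_lag_h"].to_numpy()
        warm = meta.loc[sel["plot_id"], "warming_dt"].to_numpy()
        nadd = meta.loc[sel["plot_id"], "n_addition"].to_numpy()
        keep = (warm <= config.warming_low_threshold) | (warm >= config.warming_high_threshold)
        wlab = np.where(warm >= config.warming_high_threshold, "high", "low")
        if len(set(wlab[keep])) == 2:
            res = permutation_anova(lags_v[keep], wlab[keep],
                                    n_perm=config.n_perm, seed=config.seed)
            tests["warming"] = dataclasses.asdict(res)
        if len(set(nadd)) == 2:
            res = permutation_anova(lags_v, nadd, n_perm=config.n_perm,
                                    seed=config.seed)
            tests["n_addition"] = dataclasses.asdict(res)
    with open(outdir / "permutation_tests.json", "w") as fh:
        json.dump(_json_sanitize(tests), fh, indent=2, sort_keys=True)
    return {"scans": scans, "best": best, "tests": tests}


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages end to end; returns the in-memory artifacts.

    Idempotent for a given config + seed: all randomness flows from the seed
    and output tables carry no timestamps.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    if "simulate" in config.stages:
        artifacts.update(simulate_stage(config, outdir))
    else:
        artifacts["design"] = pd.read_csv(outdir / "design.csv")
        artifacts["pools"] = pd.read_csv(outdir / "pools.csv")
        artifacts["sr_series"] = pd.read_csv(outdir / "sr_series.csv")
    require_columns(artifacts["pools"],
                    ("plot_id", "pool", "day_since_label", "c_pool_gc_m2"), "pools")
    require_columns(artifacts["sr_series"], SR_SERIES_COLUMNS, "sr_series")

    if "flux" in config.stages:
        artifacts["sr_corrected"] = flux_stage(config, outdir, artifacts["sr_series"])
    if "tracer" in config.stages:
        artifacts.update(tracer_stage(config, outdir, artifacts["pools"],
                                      artifacts["sr_series"]))
    if "mrt" in config.stages:
        artifacts["decay_fits"] = mrt_stage(config, outdir, artifacts["excess"],
                                            artifacts["sr_series"])
    if "lag" in config.stages:
        artifacts["lag"] = lag_stage(config, outdir, artifacts["sr_series"],
                                     artifacts["design"])

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "isopulse_version": __version__,
        "outputs": sorted(p.name for p in outdir.glob("*.csv"))
        + sorted(p.name for p in outdir.glob("*.json") if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest
    return artifacts
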