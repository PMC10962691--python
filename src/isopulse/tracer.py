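"""Excess-13C pool accounting for a pulse-chase labeling experiment.

After a canopy is pulse-labeled with 13CO2, the tracer recovered in a pool at
time t is the rise of its 13C atom fraction over the pre-label (natural
abundance) baseline, scaled by the pool's carbon stock:

    excess13C = (x_after - x_before) * C_pool

with C_pool in g C m-2, so the excess carries the same mass-of-carbon basis
(reported here in mg m-2).  Relative recovery normalizes by the shoot excess
immediately after labeling (the canopy's total label uptake), so shoot
recovery at day 0 is 100% by construction.

Soil respiration is a flux, not a stock: its instantaneous excess-13C export
is the atom-fraction rise times the (geogenic-corrected) biogenic CO2 flux,
converted to tracer mass with the molar mass of 13C, and its cumulative
recovery is the trapezoidal integral of that rate over the chase period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import NormalizationError, PairingError, SchemaError
from .isotope import IsotopeMeasure, delta_to_atom_fraction

logger = logging.getLogger(__name__)

#: Molar mass of 13C, g mol-1, for converting molar CO2 flux to tracer mass.
M_13C = 13.00335

#: Sampling schedule (days since labeling); -1 is the natural-abundance baseline.
POOL_DAYS = (-1, 0, 1, 3, 6, 10)
POOLS = ("shoot", "root", "eoc", "microbial", "sr")

#: mg 13C m-2 h-1 per (atom-fraction unit x umol CO2 m-2 s-1):
#: 1 umol m-2 s-1 = 3.6e-3 mol m-2 h-1; x M_13C g/mol; x 1e3 mg/g.
_RATE_MG_PER_UMOL_H = 3.6e-3 * M_13C * 1e3


@dataclass(frozen=True)
class PoolSample:
    """One plot x pool x day observation of carbon stock and isotopic state."""

    plot_id: str
    pool: str
    day_since_label: float
    c_pool: float  # g C m-2 (cumulative g C m-2 over the interval for sr)
    isotope: IsotopeMeasure

    def __post_init__(self):
        if self.c_pool < 0:
            raise ValueError("pool carbon must be nonnegative")


def excess_13c(sample: PoolSample, baseline: PoolSample) -> float:
    """Absolute excess 13C of a pool sample over its pre-label baseline.

    Returns (x_after - x_before) * C_pool in the mass units of ``c_pool``
    (g m-2 for g C m-2 stocks).
    """
    if sample.plot_id != baseline.plot_id or sample.pool != baseline.pool:
        raise PairingError(
            f"baseline mismatch: sample ({sample.plot_id}, {sample.pool}) vs "
            f"baseline ({baseline.plot_id}, {baseline.pool})"
        )
    if baseline.day_since_label >= 0:
        raise PairingError("baseline must be a pre-label (day -1) record")
    return (sample.isotope.atom_fraction - baseline.isotope.atom_fraction) * sample.c_pool


def relative_recovery(excess: float, shoot_excess_t0: float) -> float:
    """Excess 13C as % of the label assimilated by the canopy (shoot at t0)."""
    if shoot_excess_t0 <= 0:
        raise NormalizationError("shoot excess at t0 must be positive")
    return 100.0 * excess / shoot_excess_t0


def sr_excess_rate(sr_bio_flux, x_sr, x_baseline):
    """Instantaneous excess-13C export by soil respiration, mg 13C m-2 h-1.

    Parameters
    ----------
    sr_bio_flux : umol CO2 m-2 s-1 (geogenic-corrected biogenic flux)
    x_sr, x_baseline : 13C atom fraction of current and pre-label SR.
    """
    sr_bio_flux = np.asarray(sr_bio_flux, dtype=float)
    x_sr = np.asarray(x_sr, dtype=float)
    out = (x_sr - x_baseline) * sr_bio_flux * _RATE_MG_PER_UMOL_H
    return float(out) if out.ndim == 0 else out


def cumulative_sr_excess(times_h, rates_mg_h):
    """Cumulative SR excess 13C (mg m-2) by trapezoidal integration.

    Returns the running integral evaluated at each time point (first = 0).
    """
    times_h = np.asarray(times_h, dtype=float)
    rates_mg_h = np.asarray(rates_mg_h, dtype=float)
    if times_h.size != rates_mg_h.size:
        raise ValueError("times and rates must have equal length")
    if times_h.size == 0:
        return np.array([])
    dt = np.diff(times_h)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    seg = 0.5 * (rates_mg_h[1:] + rates_mg_h[:-1]) * dt
    return np.concatenate([[0.0], np.cumsum(seg)])


POOL_TABLE_COLUMNS = ("plot_id", "pool", "day_since_label", "c_pool_gc_m2")


def excess_table(pool_df: pd.DataFrame, baseline_sd_mg: float = 0.0) -> pd.DataFrame:
    """Tidy excess/relative-recovery table from a pool-sample table.

    Expects columns ``plot_id, pool, day_since_label, c_pool_gc_m2`` and one of
    ``delta_permil`` or ``atom_fraction``.  For each (plot, pool), the day -1
    record is the baseline; remaining days yield

    * ``excess_mg_m2``    -- the tracer mass (x_after - x_before) * C_pool, in mg,
    * ``relative_recovery_pct`` -- normalized by that plot's shoot day-0 excess,
    * ``flag`` -- "" normally; "clamped" when a small negative excess (within
      2 standard deviations of baseline noise, ``baseline_sd_mg``) was set to
      zero; "excluded" for larger negatives (value kept as NaN).
    """
    missing = [c for c in POOL_TABLE_COLUMNS if c not in pool_df.columns]
    if missing:
        raise SchemaError(f"pool table missing required columns: {missing}")
    if "atom_fraction" in pool_df.columns:
        x = pool_df["atom_fraction"].to_numpy(dtype=float)
    elif "delta_permil" in pool_df.columns:
        x = delta_to_atom_fraction(pool_df["delta_permil"].to_numpy(dtype=float))
    else:
        raise SchemaError("pool table needs a delta_permil or atom_fraction column")

    df = pool_df.copy()
    df["_x"] = x
    rows = []
    for (plot, pool), grp in df.groupby(["plot_id", "pool"], sort=True):
        base = grp[grp["day_since_label"] < 0]
        if base.empty:
            raise PairingError(f"no day -1 baseline for plot {plot!r} pool {pool!r}")
        x0 = float(base["_x"].iloc[0])
        for _, row in grp[grp["day_since_label"] >= 0].iterrows():
            exc = (row["_x"] - x0) * row["c_pool_gc_m2"] * 1000.0  # g -> mg
            flag = ""
            if exc < 0:
                if exc >= -2.0 * baseline_sd_mg:
                    flag = "clamped"
                    exc = 0.0
                else:
                    flag = "excluded"
                    logger.warning(
                        "excluding negative excess %.3g mg m-2 (plot %s, pool %s, day %s)",
                        exc, plot, pool, row["day_since_label"])
                    exc = float("nan")
            rows.append({"plot_id": plot, "pool": pool,
                         "day_since_label": row["day_since_label"],
                         "excess_mg_m2": exc, "flag": flag})
    out = pd.DataFrame(rows)

    # normalize by shoot day-0 excess per plot
    t0 = (out[(out["pool"] == "shoot") & (out["day_since_label"] == 0)]
          .set_index("plot_id")["excess_mg_m2"])
    rel = []
    for _, row in out.iterrows():
        denom = t0.get(row["plot_id"], float("nan"))
        if not np.isfinite(denom) or denom <= 0:
            rel.append(float("nan"))
        else:
            rel.append(100.0 * row["excess_mg_m2"] / denom)
    out["relative_recovery_pct"] = rel
    return out
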