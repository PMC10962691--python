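"""Synthetic 13CO2 pulse-labeling experiment with known ground truth.

The generator emulates a geothermally warmed subarctic grassland experiment:
14 plots on a soil-warming gradient (0-8.7 degC above the 10.2 degC ambient),
half receiving 50 kg N ha-1 yr-1, pulse-labeled for about an hour at 40-60
atom-% 13CO2 and chased for 10 days with pool sampling at days 0, 1, 3, 6
and 10 (day -1 natural-abundance baseline) and soil-respiration cycles every
2.4 h.

Tracer kinetics are a linear first-order compartment chain

    shoot -> root -> EOC -> microbial biomass -> soil respiration

with a respiratory loss at each transfer: a fraction of each outflow moves
downstream, the remainder is respired (shoot respiration aboveground, soil
respiration belowground).  The chain is propagated exactly with the matrix
exponential, including running integrals of cumulative soil and shoot
respiration, so label mass is conserved to machine precision -- the anchor
for every conservation test downstream.

Treatment effects are injected multiplicatively: warming scales all rate
constants up (faster turnover, shorter residence times) and shifts allocation
from roots toward microbes; N addition slows belowground rates (longer SR
residence time) and shifts allocation toward roots.  Magnitudes are
configurable; directions default to the warming/N response pattern the
pipeline is meant to resolve.

Diel forcing (truncated-sinusoid PAR, lagged soil-temperature sinusoid, flat
soil water content) and chamber-level records (flow-through pairs and closed
accumulation ramps, with optional geogenic admixture at -4.7 permil) are
generated consistently with the flux equations, so every computation stage
can be exercised as an inverse problem with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from ._errors import ConfigError
from .isotope import DELTA_BIOGENIC, DELTA_GEOGENIC, delta_to_atom_fraction
from .fluxes import ChamberSeries, air_molar_density

#: Soil-warming increments (degC above ambient) of the unfertilized and
#: fertilized plots, and the ambient soil temperature of the unwarmed plots.
WARMING_UNFERTILIZED = (0.0, 0.5, 1.5, 6.1, 6.6, 7.7, 8.7)
WARMING_FERTILIZED = (0.3, 0.8, 1.5, 5.1, 6.5, 7.0, 8.1)
AMBIENT_SOIL_TEMP_C = 10.2
N_ADDITION_RATE = 50  # kg N ha-1 yr-1 on fertilized plots

POOL_SAMPLING_DAYS = (0, 1, 3, 6, 10)
SR_CYCLE_H = 2.4

#: Background carbon stocks (g C m-2) used to turn tracer masses into
#: pool samples; typical grassland topsoil magnitudes.
POOL_BACKGROUND_GC_M2 = {"shoot": 150.0, "root": 400.0, "eoc": 30.0, "microbial": 80.0}


@dataclass(frozen=True)
class PlotDesign:
    """One plot of the warming x N-addition design."""

    plot_id: str
    warming_dt: float            # degC above ambient soil temperature
    n_addition: int = 0          # kg N ha-1 yr-1 (0 or 50)
    sr_mode: str = "steady"      # which SR chamber system serves the plot


def default_design() -> list[PlotDesign]:
    """The 14-plot study layout: 7 warming levels x {0, 50} kg N ha-1 yr-1.

    The eight plots with mains power (steady-state SR system) are the four
    least-warmed of each N treatment; the remaining six carry the portable
    closed-chamber system.
    """
    plots = []
    for i, dt in enumerate(WARMING_UNFERTILIZED):
        plots.append(PlotDesign(f"U{i + 1}", dt, 0, "steady" if i < 4 else "closed"))
    for i, dt in enumerate(WARMING_FERTILIZED):
        plots.append(PlotDesign(f"F{i + 1}", dt, N_ADDITION_RATE,
                                "steady" if i < 4 else "closed"))
    return plots


@dataclass
class SimConfig:
    """Rate constants, treatment sensitivities, pulse and noise settings.

    Rates are first-order outflow constants (d-1) at ambient temperature;
    ``f_*`` are the fractions of each outflow transferred downstream (the
    remainder is respired).  Warming multiplies every rate by
    ``warming_k_mult`` per degC and shifts allocation fractions linearly per
    degC; N addition multiplies belowground rates by ``n_addition_k_mult``
    and adds ``n_addition_f_root_shift`` to the root allocation fraction.
    """

    # compartment chain at ambient, unfertilized conditions
    k_shoot_out: float = 0.35    # d-1 (shoot tracer MRT ~2.9 d)
    f_root: float = 0.45         # fraction of shoot outflow to roots
    k_root_out: float = 0.90     # d-1 (fast root metabolic turnover)
    f_eoc: float = 0.50          # fraction of root outflow to EOC
    k_eoc_out: float = 1.20      # d-1 (labile extract pool turns over in ~1 d)
    f_mb: float = 0.50           # fraction of EOC outflow to microbes
    k_mb_out: float = 0.30       # d-1 (slowest link; sets late SR 13C decay)

    # treatment sensitivities
    warming_k_mult: float = 1.06          # per degC, on all four rates
    warming_f_mb_shift: float = 0.012     # per degC, added to f_mb
    warming_f_root_shift: float = -0.012  # per degC, added to f_root
    n_addition_k_mult: float = 0.88       # on belowground rates when fertilized
    n_addition_f_root_shift: float = 0.05

    # pulse
    pulse_mg_13c: float = 300.0           # canopy 13C uptake, mg 13C m-2
    label_atom_fraction: float = 0.5      # chamber target 40-60 atom-% 13C
    pulse_duration_min: float = 60.0

    # soil respiration and geogenic admixture
    sr_base_flux: float = 2.5             # biogenic baseline, umol CO2 m-2 s-1
    sr_warming_flux_mult: float = 1.08    # per degC on the baseline SR flux
    geogenic_flux: float = 0.5            # umol CO2 m-2 s-1, delta -4.7 permil
    delta_geogenic: float = DELTA_GEOGENIC
    delta_biogenic: float = DELTA_BIOGENIC

    # diel forcing
    par_max: float = 800.0                # umol m-2 s-1 at solar noon
    par_week_amplitude: float = 0.4       # day-to-day (synoptic) PAR modulation
    temp_diel_amplitude: float = 1.5      # degC
    temp_lag_h: float = 2.0               # soil temperature behind PAR
    swc_mean_vol_pct: float = 40.0        # flat, > 35 vol-%
    sr_par_lag_h: float = 2.4             # SR CO2 behind PAR, unwarmed
    sr13_par_lag_h: float = 9.6           # SR 13C excess behind PAR, unwarmed
    sr_diel_amplitude: float = 0.35       # fractional diel swing of SR
    # lag responses to treatments (lags shrink toward synchrony with warming,
    # the CO2 lag lengthens under N addition); lags floor at zero
    warming_sr_lag_shift_h_per_c: float = 0.35
    warming_sr13_lag_shift_h_per_c: float = 1.2
    n_addition_sr_lag_shift_h: float = 2.4

    # back-diffusion contamination of early SR 13C (off by default)
    back_diffusion_fraction: float = 0.0  # fraction of the pulse
    back_diffusion_turnover_min: float = 25.0

    # observation noise (1 sigma); zero everywhere = noiseless truth
    pool_excess_rel_sd: float = 0.10
    sr_excess_rel_sd: float = 0.10
    chamber_ppm_sd: float = 0.3
    swc_sd: float = 0.3

    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("k_shoot_out", "k_root_out", "k_eoc_out", "k_mb_out"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("f_root", "f_eoc", "f_mb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.label_atom_fraction < 1.0:
            raise ConfigError("label_atom_fraction must lie in (0, 1)")
        if self.pulse_mg_13c <= 0:
            raise ConfigError("pulse_mg_13c must be positive")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ConfigError("stochastic output requires a seed")
        return np.random.default_rng(self.seed)


def effective_parameters(config: SimConfig, design: PlotDesign) -> dict:
    """Per-plot rate constants and allocation fractions after treatments."""
    config.validate()
    m = config.warming_k_mult ** design.warming_dt
    fert = design.n_addition > 0
    nm = config.n_addition_k_mult if fert else 1.0
    f_root = np.clip(config.f_root + config.warming_f_root_shift * design.warming_dt
                     + (config.n_addition_f_root_shift if fert else 0.0), 0.0, 1.0)
    f_mb = np.clip(config.f_mb + config.warming_f_mb_shift * design.warming_dt, 0.0, 1.0)
    return {
        "k_shoot_out": config.k_shoot_out * m,
        "k_root_out": config.k_root_out * m * nm,
        "k_eoc_out": config.k_eoc_out * m * nm,
        "k_mb_out": config.k_mb_out * m * nm,
        "f_root": float(f_root),
        "f_eoc": config.f_eoc,
        "f_mb": float(f_mb),
    }


def _chain_matrix(p: dict) -> np.ndarray:
    """Generator matrix of [shoot, root, eoc, mb, cum_sr, cum_shoot_resp].

    Columns sum to zero, so the total (pools + cumulative respiration) is an
    exact invariant of the flow.
    """
    ks, kr, ke, km = p["k_shoot_out"], p["k_root_out"], p["k_eoc_out"], p["k_mb_out"]
    fr, fe, fm = p["f_root"], p["f_eoc"], p["f_mb"]
    A = np.zeros((6, 6))
    A[0, 0] = -ks
    A[1, 0] = fr * ks
    A[1, 1] = -kr
    A[2, 1] = fe * kr
    A[2, 2] = -ke
    A[3, 2] = fm * ke
    A[3, 3] = -km
    A[4, 1] = (1 - fe) * kr     # root respiration -> SR
    A[4, 2] = (1 - fm) * ke     # EOC mineralization -> SR
    A[4, 3] = km                # microbial respiration -> SR
    A[5, 0] = (1 - fr) * ks     # shoot respiration (aboveground loss)
    return A


def simulate_tracer(config: SimConfig, design: PlotDesign, t_days) -> dict:
    """Exact tracer state of one plot at the requested days since labeling.

    Returns arrays over ``t_days``: the four pool excesses (mg 13C m-2), the
    instantaneous SR 13C export rate (mg m-2 d-1 and mg m-2 h-1), cumulative
    SR and shoot-respiration losses, and the per-plot effective parameters.
    """
    t_days = np.asarray(t_days, dtype=float)
    p = effective_parameters(config, design)
    A = _chain_matrix(p)
    y0 = np.array([config.pulse_mg_13c, 0, 0, 0, 0, 0], dtype=float)

    states = np.empty((t_days.size, 6))
    order = np.argsort(t_days)
    propagators: dict = {}  # uniform grids reuse one matrix exponential
    prev_t, y = 0.0, y0.copy()
    for i in order:
        dt = t_days[i] - prev_t
        if dt < 0:
            raise ConfigError("t_days must be nonnegative")
        if dt > 0:
            if dt not in propagators:
                propagators[dt] = expm(A * dt)
            y = propagators[dt] @ y
            prev_t = t_days[i]
        states[i] = y
    sr_rate_d = states @ A[4]  # d(cum_sr)/dt, mg m-2 d-1
    return {
        "t_days": t_days,
        "shoot": states[:, 0], "root": states[:, 1],
        "eoc": states[:, 2], "microbial": states[:, 3],
        "cum_sr": states[:, 4], "cum_shoot_resp": states[:, 5],
        "sr_rate_mg_d": sr_rate_d,
        "sr_rate_mg_h": sr_rate_d / 24.0,
        "parameters": p,
    }


def _par_shape(t_h: np.ndarray) -> np.ndarray:
    """Normalized diel PAR shape: truncated sinusoid, zero at night.

    Daylight runs 06:00-18:00 local; peak 1 at solar noon.
    """
    return np.maximum(0.0, np.sin(2.0 * np.pi * (t_h - 6.0) / 24.0))


#: Fixed irregular day-to-day insolation pattern (zero mean, range [-1, 1])
#: emulating synoptic cloudiness; deliberately anticorrelated between
#: consecutive days so a diel signal and its +/-24 h alias decorrelate.
_SYNOPTIC_PATTERN = np.array(
    [0.9, -0.8, 0.3, -1.0, 0.7, -0.4, 1.0, -0.9, 0.1, -0.5, 0.6])


def _par_signal(config: SimConfig, t_h: np.ndarray) -> np.ndarray:
    """Normalized PAR signal: diel shape times a synoptic day factor.

    The deterministic day-to-day amplitude modulation emulates weather;
    without it a purely 24 h-periodic driver makes lags s and s +/- 24 h
    indistinguishable on a +/-20 h scan grid.
    """
    day = np.floor(np.asarray(t_h, dtype=float) / 24.0).astype(int)
    factor = 1.0 + config.par_week_amplitude * _SYNOPTIC_PATTERN[
        day % _SYNOPTIC_PATTERN.size]
    return factor * _par_shape(t_h)


def effective_lags(config: SimConfig, design: PlotDesign) -> tuple[float, float]:
    """(SR CO2, SR 13C) lags behind PAR for one plot, hours, floored at 0."""
    fert = design.n_addition > 0
    lag_sr = max(0.0, config.sr_par_lag_h
                 + (config.n_addition_sr_lag_shift_h if fert else 0.0)
                 - config.warming_sr_lag_shift_h_per_c * design.warming_dt)
    lag_13 = max(0.0, config.sr13_par_lag_h
                 - config.warming_sr13_lag_shift_h_per_c * design.warming_dt)
    return lag_sr, lag_13


def simulate_drivers(config: SimConfig, design: PlotDesign, duration_d: float = 10.0,
                     step_h: float = 0.1, noiseless: bool = False,
                     t_h: Optional[np.ndarray] = None,
                     rng: Optional[np.random.Generator] = None) -> dict:
    """Diel driver series for one plot: PAR, soil temperature, SWC.

    PAR is a truncated sinusoid (zero at night); soil temperature is ambient
    plus the plot's warming increment plus a diel sinusoid lagging PAR; SWC is
    flat (no diel variation) with optional white noise.  Pass ``t_h`` to
    evaluate on an existing time grid instead of a fresh one.
    """
    if duration_d < 2 and t_h is None:
        raise ConfigError("driver simulation needs at least 2 days")
    if t_h is None:
        t_h = np.arange(0.0, duration_d * 24.0, step_h)
    else:
        t_h = np.asarray(t_h, dtype=float)
    par = config.par_max * _par_signal(config, t_h)
    temp = (AMBIENT_SOIL_TEMP_C + design.warming_dt
            + config.temp_diel_amplitude
            * np.sin(2.0 * np.pi * (t_h - 12.0 - config.temp_lag_h) / 24.0))
    swc = np.full_like(t_h, config.swc_mean_vol_pct)
    if not noiseless and config.swc_sd > 0:
        rng = rng if rng is not None else config.rng()
        swc = swc + rng.normal(0.0, config.swc_sd, t_h.size)
    return {"t_h": t_h, "par": par, "soil_temp_c": temp, "swc_vol_pct": swc}


def simulate_sr_observations(config: SimConfig, design: PlotDesign,
                             duration_d: float = 10.0, step_h: float = SR_CYCLE_H,
                             noiseless: bool = False,
                             rng: Optional[np.random.Generator] = None) -> dict:
    """Soil-respiration measurement-cycle series for one plot.

    The total SR flux is the warmed biogenic baseline plus an additive diel
    component tracking PAR at ``sr_par_lag_h`` plus the geogenic flux; the SR
    13C excess rate is the compartment-chain export with an additive diel
    component at ``sr13_par_lag_h`` and, optionally, a fast back-diffusion
    transient.  Gaussian noise is applied per observation unless noiseless.
    """
    t_h = np.arange(step_h, duration_d * 24.0 + 1e-9, step_h)
    tr = simulate_tracer(config, design, t_h / 24.0)
    signal_mean = _par_signal(config, t_h).mean()
    lag_sr, lag_13 = effective_lags(config, design)

    sr_bio = (config.sr_base_flux * config.sr_warming_flux_mult ** design.warming_dt
              * (1.0 + config.sr_diel_amplitude
                 * (_par_signal(config, t_h - lag_sr) - signal_mean)))
    sr_total = sr_bio + config.geogenic_flux

    # diel modulation proportional to the current envelope: the tracer export
    # tracks substrate supply, so its diel swing decays with the pulse
    rate13 = tr["sr_rate_mg_h"] * (
        1.0 + config.sr_diel_amplitude
        * (_par_signal(config, t_h - lag_13) - signal_mean))
    if config.back_diffusion_fraction > 0:
        tau_h = config.back_diffusion_turnover_min / 60.0
        amp = config.back_diffusion_fraction * config.pulse_mg_13c / tau_h
        rate13 = rate13 + amp * np.exp(-t_h / tau_h)
    rate13 = np.maximum(rate13, 0.0)

    if not noiseless:
        rng = rng if rng is not None else config.rng()
        sr_total = sr_total * (1.0 + config.sr_excess_rel_sd / 2
                               * rng.standard_normal(t_h.size))
        rate13 = rate13 * (1.0 + config.sr_excess_rel_sd
                           * rng.standard_normal(t_h.size))
    return {"t_h": t_h, "sr_total_flux": sr_total, "sr_bio_flux": sr_bio,
            "sr13_excess_rate_mg_h": rate13,
            "f_geo_truth": config.geogenic_flux / (config.geogenic_flux
                                                   + sr_bio.mean())}


def sample_pools(config: SimConfig, designs: Sequence[PlotDesign],
                 days: Sequence[float] = POOL_SAMPLING_DAYS,
                 noiseless: bool = False,
                 rng: Optional[np.random.Generator] = None):
    """Pool-sample table (long format) for the chase sampling schedule.

    Observed atom fractions are constructed by inverting the excess formula,
    x_after = x_nat + excess / (1000 * C_pool), so the accounting stage
    recovers the simulated tracer masses exactly in the noiseless case.
    Returns a list of record dicts (the pipeline turns them into CSV).
    """
    import pandas as pd

    x_nat = delta_to_atom_fraction(config.delta_biogenic)
    if not noiseless:
        rng = rng if rng is not None else config.rng()
    rows = []
    for design in designs:
        tr = simulate_tracer(config, design, np.asarray(days, dtype=float))
        for pool, bg in POOL_BACKGROUND_GC_M2.items():
            rows.append({"plot_id": design.plot_id, "pool": pool,
                         "day_since_label": -1, "c_pool_gc_m2": bg,
                         "atom_fraction": x_nat})
            for j, day in enumerate(days):
                exc = tr[pool][j]
                if not noiseless:
                    exc *= 1.0 + config.pool_excess_rel_sd * rng.standard_normal()
                rows.append({"plot_id": design.plot_id, "pool": pool,
                             "day_since_label": day, "c_pool_gc_m2": bg,
                             "atom_fraction": x_nat + exc / 1000.0 / bg})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chamber-level records


def steady_pair_from_flux(flux_umol_m2_s: float, x_source: float,
                          area_m2: float = np.pi * 0.0225 ** 2,
                          flow_mol_s: float = 3.464e-4,
                          buffer_ppm: float = 420.0,
                          buffer_delta: float = -9.0,
                          n_buffer: int = 72, n_chamber: int = 96,
                          dt_s: float = 5.0,
                          noise_ppm: float = 0.0,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[ChamberSeries, ChamberSeries]:
    """Invert the flow-through flux equation into a buffer/chamber pair.

    The chamber CO2 sits at buffer + flux*area/flow; isotopologue channels
    split the buffer at its own atom fraction and the added CO2 at
    ``x_source``.  Defaults mirror the field system: 4.5 cm diameter chamber,
    0.5 L min-1 at 20 degC, 6-min buffer / 8-min chamber windows at 5 s.
    """
    x_buf = delta_to_atom_fraction(buffer_delta)
    d_ppm = flux_umol_m2_s * area_m2 / flow_mol_s
    t_buf = np.arange(n_buffer) * dt_s
    t_cha = t_buf[-1] + dt_s + np.arange(n_chamber) * dt_s
    buf_ppm = np.full(n_buffer, buffer_ppm)
    cha_ppm = np.full(n_chamber, buffer_ppm + d_ppm)
    if noise_ppm > 0:
        if rng is None:
            raise ConfigError("noise requires an rng")
        buf_ppm = buf_ppm + rng.normal(0, noise_ppm, n_buffer)
        cha_ppm = cha_ppm + rng.normal(0, noise_ppm, n_chamber)
    buf13 = buf_ppm * x_buf
    cha13 = buffer_ppm * x_buf + (cha_ppm - buffer_ppm) * x_source
    buffer = ChamberSeries(t_buf, buf_ppm, mode="steady", area_m2=area_m2,
                           flow_mol_s=flow_mol_s, co2_12=buf_ppm - buf13,
                           co2_13=buf13)
    chamber = ChamberSeries(t_cha, cha_ppm, mode="steady", area_m2=area_m2,
                            flow_mol_s=flow_mol_s, co2_12=cha_ppm - cha13,
                            co2_13=cha13)
    return chamber, buffer


def closed_ramp_from_flux(flux_umol_m2_s: float, area_m2: float = 0.25,
                          volume_m3: float = 0.125, air_temp_c: float = 20.0,
                          start_ppm: float = 420.0, duration_s: float = 60.0,
                          dt_s: float = 5.0, noise_ppm: float = 0.0,
                          rng: Optional[np.random.Generator] = None,
                          source_delta: Optional[float] = None,
                          sample_times_min: Optional[Sequence[float]] = None
                          ) -> ChamberSeries:
    """Invert the closed-chamber equation into a linear concentration ramp.

    Defaults mirror the 50x50x50 cm chamber.  With ``sample_times_min`` set
    (e.g. (1, 3, 5, 15, 30) for accumulation sampling), the series is sampled
    at those minutes instead of a regular grid, and ``source_delta`` attaches
    a delta13C channel by two-member mixing of start air (at -9 permil) with
    source CO2 -- the substrate of a Keeling plot.
    """
    slope = flux_umol_m2_s / ((volume_m3 / area_m2) * air_molar_density(air_temp_c))
    if sample_times_min is not None:
        t = np.asarray(sample_times_min, dtype=float) * 60.0
    else:
        t = np.arange(0.0, duration_s + 1e-9, dt_s)
    ppm = start_ppm + slope * t
    if noise_ppm > 0:
        if rng is None:
            raise ConfigError("noise requires an rng")
        ppm = ppm + rng.normal(0, noise_ppm, t.size)
    series = ChamberSeries(t, ppm, mode="closed", area_m2=area_m2,
                           volume_m3=volume_m3, air_temp_c=air_temp_c)
    if source_delta is not None:
        x0 = delta_to_atom_fraction(-9.0)
        xs = delta_to_atom_fraction(source_delta)
        c13 = start_ppm * x0 + (ppm - start_ppm) * xs
        series.co2_13 = c13
        series.co2_12 = ppm - c13
    return series


def ground_truth(config: SimConfig, designs: Sequence[PlotDesign]) -> dict:
    """Per-plot effective parameters and headline truths, JSON-serializable."""
    out = {"pulse_mg_13c": config.pulse_mg_13c,
           "sr_par_lag_h": config.sr_par_lag_h,
           "sr13_par_lag_h": config.sr13_par_lag_h,
           "plots": {}}
    for d in designs:
        p = effective_parameters(config, d)
        out["plots"][d.plot_id] = {
            "warming_dt": d.warming_dt, "n_addition": d.n_addition,
            "shoot_b_per_d": p["k_shoot_out"],
            "shoot_mrt_d": 1.0 / p["k_shoot_out"],
            **p,
        }
    return out
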