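"""Chamber CO2 flux computation and the isotopic signature of soil respiration.

Two chamber systems are supported, mirroring common field practice:

* **steady-state (flow-through)**: a small soil chamber is flushed at a known
  flow rate; the flux follows from the CO2 enrichment of chamber air over the
  buffer (inlet) air, the flow rate and the chamber basal area,

      SR = dCO2 [umol/mol] * flow [mol s-1] / area [m2];

* **closed (accumulation)**: a static chamber accumulates CO2; the flux is
  the OLS slope of concentration vs time scaled by the effective air column
  (volume/area) and the molar density of air,

      F = dC/dt [umol mol-1 s-1] * (V/A) [m] * n_air [mol m-3].

Molar density uses the ideal gas law at 101.325 kPa and the measured air
temperature (no barometric record is assumed).  Ecosystem fluxes follow the
micrometeorological sign convention: positive NEE is a net CO2 source,
negative a net sink, and GPP is reported as a positive uptake magnitude
ER - NEE.

The 13C atom fraction of soil-respired CO2 comes from the isotopologue mass
balance of what the chamber added over the buffer.  NDVI is included at the
formula level because the field campaign pairs it with the flux record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._errors import (
    AlignmentError,
    ConfigError,
    InsufficientDataError,
    UndefinedIndexError,
    UndefinedSourceError,
)
from .isotope import IsotopeMeasure, MixingResult, geogenic_fraction

#: Standard atmospheric pressure, Pa (no barometric record assumed).
PRESSURE_PA = 101325.0
#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314462618

#: Fraction of each steady-state measurement window used for the mean
#: (trailing part, discarding the valve-switch transient).
TRAILING_FRACTION = 0.8

#: Closed-chamber QC: minimum r-squared of the concentration ramp.
QC_R2_MIN = 0.9


def air_molar_density(temp_c: float, pressure_pa: float = PRESSURE_PA) -> float:
    """Molar density of air (mol m-3), ideal gas at the given temperature."""
    return pressure_pa / (R_GAS * (temp_c + 273.15))


def flow_mol_per_s(flow_l_min: float, temp_c: float, pressure_pa: float = PRESSURE_PA) -> float:
    """Convert a volumetric flow (L min-1 at chamber conditions) to mol s-1."""
    if flow_l_min <= 0:
        raise ConfigError("flow rate must be positive")
    return pressure_pa * (flow_l_min / 1000.0 / 60.0) / (R_GAS * (temp_c + 273.15))


@dataclass
class ChamberSeries:
    """One chamber deployment: timestamped concentrations and drivers.

    Parameters
    ----------
    timestamps : array, s (strictly increasing)
    co2 : array, ppm total CO2 (> 0)
    mode : "steady" or "closed"
    area_m2 : chamber basal area
    volume_m3 : chamber volume (closed mode)
    flow_mol_s : molar flow rate (steady mode)
    co2_12, co2_13 : optional isotopologue channels, ppm
    air_temp_c : air temperature, degC (scalar or per-sample)
    par : optional PAR, umol m-2 s-1
    """

    timestamps: np.ndarray
    co2: np.ndarray
    mode: str = "steady"
    area_m2: float = float("nan")
    volume_m3: Optional[float] = None
    flow_mol_s: Optional[float] = None
    co2_12: Optional[np.ndarray] = None
    co2_13: Optional[np.ndarray] = None
    air_temp_c: float | np.ndarray = 20.0
    par: Optional[np.ndarray] = None
    plot_id: str = ""

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size != self.co2.size:
            raise ConfigError("timestamps and co2 must be 1-D and equal length")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        if np.any(self.co2 <= 0):
            raise ConfigError("CO2 concentrations must be positive")
        if self.mode not in ("steady", "closed"):
            raise ConfigError(f"unknown chamber mode {self.mode!r}")
        for name in ("co2_12", "co2_13", "par"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def mean_air_temp_c(self) -> float:
        return float(np.mean(self.air_temp_c))

    def has_isotopologues(self) -> bool:
        return self.co2_12 is not None and self.co2_13 is not None


@dataclass(frozen=True)
class FluxResult:
    """A computed CO2 flux, umol CO2 m-2 s-1, positive = release to atmosphere."""

    flux: float
    r_squared: float
    method: str
    qc_pass: bool
    flagged: bool = False


def _trailing(values: np.ndarray, fraction: float = TRAILING_FRACTION) -> np.ndarray:
    """Trailing `fraction` of a window (valve-switch transient discarded)."""
    n = values.size
    start = n - max(1, int(np.ceil(fraction * n)))
    return values[start:]


def steady_state_flux(chamber: ChamberSeries, buffer: ChamberSeries,
                      trailing_fraction: float = TRAILING_FRACTION) -> FluxResult:
    """Soil respiration from a flow-through chamber/buffer pair.

    Means are taken over the trailing part of each window; the flux is the
    chamber-over-buffer CO2 enrichment times molar flow per unit area.
    """
    if chamber.flow_mol_s is None or chamber.flow_mol_s <= 0:
        raise ConfigError("steady-state flux needs a positive molar flow rate")
    if not np.isfinite(chamber.area_m2) or chamber.area_m2 <= 0:
        raise ConfigError("steady-state flux needs a positive chamber area")
    gap = buffer.timestamps[0] - chamber.timestamps[-1]
    if gap > 3600.0 or chamber.timestamps[0] - buffer.timestamps[-1] > 3600.0:
        raise AlignmentError("chamber and buffer windows are not adjacent (>1 h apart)")
    d_ppm = float(np.mean(_trailing(chamber.co2, trailing_fraction))
                  - np.mean(_trailing(buffer.co2, trailing_fraction)))
    flux = d_ppm * chamber.flow_mol_s / chamber.area_m2
    return FluxResult(flux=flux, r_squared=float("nan"), method="steady",
                      qc_pass=True, flagged=flux < 0)


def closed_chamber_flux(series: ChamberSeries, r2_min: float = QC_R2_MIN) -> FluxResult:
    """CO2 flux from a closed-chamber concentration ramp (OLS slope).

    Needs >= 6 samples (5-s sampling over a 1-min deployment), chamber volume
    and area.  QC passes when the ramp r-squared reaches ``r2_min``; a flat
    ramp yields zero flux with undefined r-squared and fails QC.
    """
    if series.timestamps.size < 6:
        raise InsufficientDataError("closed-chamber fit needs at least 6 samples")
    if series.volume_m3 is None or series.volume_m3 <= 0:
        raise ConfigError("closed-chamber flux needs a positive volume")
    if not np.isfinite(series.area_m2) or series.area_m2 <= 0:
        raise ConfigError("closed-chamber flux needs a positive area")
    t = series.timestamps
    c = series.co2
    if np.ptp(c) == 0.0:
        return FluxResult(flux=0.0, r_squared=float("nan"), method="closed",
                          qc_pass=False, flagged=True)
    fit = stats.linregress(t, c)
    slope = float(fit.slope)  # ppm s-1 == umol mol-1 s-1
    flux = slope * (series.volume_m3 / series.area_m2) * air_molar_density(series.mean_air_temp_c)
    r2 = float(fit.rvalue ** 2)
    return FluxResult(flux=flux, r_squared=r2, method="closed",
                      qc_pass=r2 >= r2_min, flagged=flux < 0)


def gpp_from_nee_er(nee: float, er: float) -> float:
    """Gross primary productivity as a positive uptake magnitude, ER - NEE.

    With sink-negative NEE, ER - NEE is the photosynthetic uptake; a dark
    deployment (NEE == ER) gives zero.
    """
    return er - nee


def sr_atom_fraction(chamber: ChamberSeries, buffer: ChamberSeries,
                     trailing_fraction: float = TRAILING_FRACTION) -> IsotopeMeasure:
    """13C atom fraction of the CO2 the soil added between buffer and chamber.

    Isotopologue mass balance over the flow-through pair:

        x13_SR = d[13CO2] / d[12CO2 + 13CO2]

    with differences of chamber minus buffer window means.
    """
    if not (chamber.has_isotopologues() and buffer.has_isotopologues()):
        raise ConfigError("sr_atom_fraction needs isotopologue channels on both series")
    c13 = float(np.mean(_trailing(chamber.co2_13, trailing_fraction)))
    b13 = float(np.mean(_trailing(buffer.co2_13, trailing_fraction)))
    c_tot = float(np.mean(_trailing(chamber.co2_12 + chamber.co2_13, trailing_fraction)))
    b_tot = float(np.mean(_trailing(buffer.co2_12 + buffer.co2_13, trailing_fraction)))
    denom = c_tot - b_tot
    if denom == 0.0:
        raise UndefinedSourceError("chamber added no CO2 over the buffer")
    return IsotopeMeasure(atom_fraction=(c13 - b13) / denom)


def correct_geogenic(sr_total: float, sr_delta: float, **mixing_kwargs
                     ) -> tuple[float, MixingResult]:
    """Strip the geogenic component out of a measured soil-respiration flux.

    The geogenic fraction comes from two-pool delta mixing of the measured SR
    signature between the geothermal (-4.7 permil) and biogenic (-28 permil)
    end-members; the biogenic flux is sr_total * (1 - f_geo).
    """
    mix = geogenic_fraction(sr_delta, **mixing_kwargs)
    return sr_total * mix.f_bio, mix


def ndvi(rho_840: float, rho_660: float) -> float:
    """Normalized difference vegetation index (Tucker form).

    (rho_840 - rho_660) / (rho_840 + rho_660) from NIR and red reflectances
    in [0, 1]; undefined when both are zero.
    """
    r840 = np.asarray(rho_840, dtype=float)
    r660 = np.asarray(rho_660, dtype=float)
    if np.any((r840 < 0) | (r840 > 1) | (r660 < 0) | (r660 > 1)):
        raise ValueError("reflectances must lie in [0, 1]")
    denom = r840 + r660
    if np.any(denom == 0.0):
        raise UndefinedIndexError("NDVI undefined: both reflectances zero")
    out = (r840 - r660) / denom
    return float(out) if out.ndim == 0 else out
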