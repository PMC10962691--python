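"""Carbon-isotope arithmetic shared by every pipeline stage.

All heavy-isotope bookkeeping runs on two interchangeable scales:

* delta (d13C, permil vs VPDB), the reporting convention of IRMS work, and
* atom fraction x = 13C / (12C + 13C), the natural scale for enriched-label
  mass balance.

The conversion uses the 13C/12C ratio of the VPDB standard,
R_VPDB = 0.0111802 (Chang & Li), so

    R = (delta/1000 + 1) * R_VPDB,      x = R / (1 + R),

and the inverse maps back exactly.  The module also provides the two-pool
geogenic/biogenic mixing model used to strip geothermal CO2 out of soil
respiration, the Keeling-plot intercept that estimates the delta13C of a
respiration source, the fumigation-extraction mass balance for microbial
biomass, and the two-point calibration of a laser isotope analyzer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm

from ._errors import (
    DegenerateMixingError,
    InsufficientDataError,
    InvalidIsotopeError,
    SingularFitError,
)

#: 13C/12C isotope ratio of the VPDB standard (Chang & Li value).
R_VPDB = 0.0111802

#: Default end-members (permil vs VPDB) of the two-pool mixing model for
#: geothermal (geogenic) vs root/microbial (biogenic) CO2.
DELTA_GEOGENIC = -4.7
DELTA_BIOGENIC = -28.0


def delta_to_atom_fraction(delta):
    """Convert delta13C (permil vs VPDB) to 13C atom fraction.

    Parameters
    ----------
    delta : float or array-like
        delta13C in permil.  Must be > -1000 (the R = 0 boundary).

    Returns
    -------
    float or ndarray
        Atom fraction in (0, 1).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise InvalidIsotopeError(
            "delta13C must be > -1000 permil (isotope ratio must be positive)"
        )
    r = (delta / 1000.0 + 1.0) * R_VPDB
    x = r / (1.0 + r)
    return float(x) if x.ndim == 0 else x


def atom_fraction_to_delta(x):
    """Convert 13C atom fraction (strictly inside (0, 1)) to delta13C permil."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise InvalidIsotopeError("atom fraction must lie strictly in (0, 1)")
    r = x / (1.0 - x)
    delta = (r / R_VPDB - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


@dataclass(frozen=True)
class IsotopeMeasure:
    """One carbon-isotope observation, stored on both scales.

    Construct with exactly one of ``delta`` (permil vs VPDB) or
    ``atom_fraction``; the other is derived on construction and the two stay
    consistent to round-off.
    """

    delta: float
    atom_fraction: float

    def __init__(self, delta: float | None = None, atom_fraction: float | None = None):
        if (delta is None) == (atom_fraction is None):
            raise ValueError("give exactly one of delta or atom_fraction")
        if delta is not None:
            object.__setattr__(self, "delta", float(delta))
            object.__setattr__(self, "atom_fraction", delta_to_atom_fraction(delta))
        else:
            object.__setattr__(self, "atom_fraction", float(atom_fraction))
            object.__setattr__(self, "delta", atom_fraction_to_delta(atom_fraction))


@dataclass(frozen=True)
class MixingResult:
    """Partition of a mixed CO2 signal between geogenic and biogenic sources.

    ``clipped`` flags observations whose raw fraction fell outside [0, 1]
    (analytical noise past an end-member); ``raw_f_geo`` preserves the
    unclipped value for QC.
    """

    f_geo: float
    f_bio: float
    clipped: bool
    raw_f_geo: float

    def __post_init__(self):
        assert abs(self.f_geo + self.f_bio - 1.0) < 1e-12


class KeelingResult(NamedTuple):
    """OLS Keeling-plot fit: delta13C regressed on 1/[CO2]."""

    intercept_delta: float
    intercept_se: float
    slope: float
    n_points: int
    r_squared: float


class MicrobialBiomassResult(NamedTuple):
    """Fumigation-extraction difference with its mass-balance delta13C.

    ``valid`` is False when the fumigated minus non-fumigated carbon
    difference is nonpositive; such records carry NaN delta and are meant to
    be excluded downstream rather than raise.
    """

    mb_c: float
    delta_mb: float
    valid: bool


def geogenic_fraction(
    delta_mix: float,
    delta_geo: float = DELTA_GEOGENIC,
    delta_bio: float = DELTA_BIOGENIC,
    space: str = "delta",
) -> MixingResult:
    """Two-pool mixing: fraction of geogenic CO2 in a mixed signal.

    Linear in delta space by default (the convention of the geogenic
    partitioning literature); ``space="atom_fraction"`` mixes on the atom
    fraction scale instead (differs by <0.1% over this delta range).

    f_geo = (delta_mix - delta_bio) / (delta_geo - delta_bio), clipped to
    [0, 1] with the raw value retained.
    """
    if delta_geo == delta_bio:
        raise DegenerateMixingError("mixing end-members must differ")
    if space == "delta":
        raw = (delta_mix - delta_bio) / (delta_geo - delta_bio)
    elif space == "atom_fraction":
        x_mix = delta_to_atom_fraction(delta_mix)
        x_geo = delta_to_atom_fraction(delta_geo)
        x_bio = delta_to_atom_fraction(delta_bio)
        raw = (x_mix - x_bio) / (x_geo - x_bio)
    else:
        raise ValueError(f"unknown mixing space {space!r}")
    clipped = not (0.0 <= raw <= 1.0)
    f_geo = float(np.clip(raw, 0.0, 1.0))
    return MixingResult(f_geo=f_geo, f_bio=1.0 - f_geo, clipped=clipped, raw_f_geo=float(raw))


def keeling_intercept(co2, delta, method: str = "ols") -> KeelingResult:
    """Keeling-plot estimate of the source delta13C.

    Regresses measured delta13C on 1/[CO2]; the intercept (the limit of
    infinite CO2 added) is the isotopic signature of the respiration source.

    Parameters
    ----------
    co2 : array-like, ppm (> 0, not all identical)
    delta : array-like, permil
    method : "ols" (default) or "gmr" for geometric-mean regression.
    """
    co2 = np.asarray(co2, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if co2.size != delta.size:
        raise ValueError("co2 and delta must have equal length")
    if co2.size < 2:
        raise InsufficientDataError("Keeling plot needs at least 2 points")
    if np.any(co2 <= 0):
        raise SingularFitError("CO2 concentrations must be positive")
    inv = 1.0 / co2
    if np.ptp(inv) == 0.0:
        raise SingularFitError("constant CO2: Keeling regression is singular")

    if method == "gmr":
        # geometric-mean (reduced major axis) slope; SE reported from OLS
        if np.ptp(delta) == 0.0:
            r = 0.0
        else:
            r = np.corrcoef(inv, delta)[0, 1]
        slope = float(np.sign(r) * np.std(delta, ddof=1) / np.std(inv, ddof=1))
        intercept = float(np.mean(delta) - slope * np.mean(inv))
        res = sm.OLS(delta, sm.add_constant(inv)).fit()
        return KeelingResult(intercept, float(np.sqrt(res.cov_params()[0, 0])),
                             slope, int(co2.size), float(res.rsquared))
    if method != "ols":
        raise ValueError(f"unknown Keeling method {method!r}")

    res = sm.OLS(delta, sm.add_constant(inv)).fit()
    intercept, slope = res.params
    se = float(np.sqrt(res.cov_params()[0, 0])) if res.df_resid > 0 else float("nan")
    r2 = float(res.rsquared) if np.ptp(delta) > 0 else 1.0
    return KeelingResult(float(intercept), se, float(slope), int(co2.size), r2)


def microbial_biomass_isotope(
    c_fum: float, delta_fum: float, c_nonfum: float, delta_nonfum: float
) -> MicrobialBiomassResult:
    """Microbial biomass C and its delta13C from fumigation-extraction.

    The chloroform-labile carbon is the difference between fumigated and
    non-fumigated K2SO4 extracts; its delta13C follows from concentration-
    weighted mass balance:

        mb_c = c_fum - c_nonfum
        delta_mb = (c_fum*delta_fum - c_nonfum*delta_nonfum) / mb_c

    A nonpositive difference yields a flagged-invalid result (NaN delta),
    not an exception, so batch pipelines keep running.
    """
    if c_fum < 0 or c_nonfum < 0:
        raise ValueError("extract concentrations must be nonnegative")
    mb_c = c_fum - c_nonfum
    if mb_c <= 0:
        return MicrobialBiomassResult(mb_c=mb_c, delta_mb=float("nan"), valid=False)
    delta_mb = (c_fum * delta_fum - c_nonfum * delta_nonfum) / mb_c
    return MicrobialBiomassResult(mb_c=mb_c, delta_mb=delta_mb, valid=True)


class CalibrationGas(NamedTuple):
    """A reference gas: its certified values and the analyzer's raw reading."""

    true_ppm: float
    true_delta: float
    measured_ppm: float
    measured_delta: float


#: Certified values of the two calibration gases run at the end of each
#: measurement cycle (ppm, permil).
CAL_GAS_LO = (430.0, -7.6)
CAL_GAS_HI = (2926.0, -3.7)


def _two_point_map(raw, m_lo, m_hi, t_lo, t_hi):
    if m_lo == m_hi:
        raise DegenerateMixingError("identical calibration readings: degenerate calibration")
    raw = np.asarray(raw, dtype=float)
    out = t_lo + (raw - m_lo) * (t_hi - t_lo) / (m_hi - m_lo)
    return float(out) if out.ndim == 0 else out


def calibrate_analyzer(raw_ppm, raw_delta, gas_lo: CalibrationGas, gas_hi: CalibrationGas):
    """Two-point linear calibration of analyzer concentration and delta scales.

    Each scale is corrected independently by the affine map taking the
    analyzer's readings of the two reference gases to their certified values.
    Readings exactly at a reference gas map to that gas's certified values.

    Returns ``(corrected_ppm, corrected_delta)`` with the input shapes.
    """
    ppm = _two_point_map(raw_ppm, gas_lo.measured_ppm, gas_hi.measured_ppm,
                         gas_lo.true_ppm, gas_hi.true_ppm)
    dlt = _two_point_map(raw_delta, gas_lo.measured_delta, gas_hi.measured_delta,
                         gas_lo.true_delta, gas_hi.true_delta)
    return ppm, dlt
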