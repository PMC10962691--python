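"""Isotope arithmetic: conversions, mixing, Keeling plots, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isopulse import (
    R_VPDB,
    atom_fraction_to_delta,
    calibrate_analyzer,
    delta_to_atom_fraction,
    geogenic_fraction,
    keeling_intercept,
    microbial_biomass_isotope,
)
from isopulse.isotope import CalibrationGas, IsotopeMeasure
from isopulse._errors import (
    DegenerateMixingError,
    InsufficientDataError,
    InvalidIsotopeError,
    SingularFitError,
)


class TestDeltaAtomFraction:
    def test_vpdb_zero_point(self):
        # delta = 0 is the VPDB standard itself: x = R/(1+R)
        assert delta_to_atom_fraction(0.0) == pytest.approx(
            R_VPDB / (1 + R_VPDB), abs=1e-12)
        assert delta_to_atom_fraction(0.0) == pytest.approx(0.0110566, abs=5e-8)

    @pytest.mark.parametrize("delta", [-1000.0, -1500.0])
    def test_boundary_rejected(self, delta):
        with pytest.raises(InvalidIsotopeError):
            delta_to_atom_fraction(delta)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.1, 1.5])
    def test_atom_fraction_domain(self, x):
        with pytest.raises(InvalidIsotopeError):
            atom_fraction_to_delta(x)

    def test_enriched_round_trip(self):
        x = 0.05  # strongly labeled sample
        assert delta_to_atom_fraction(atom_fraction_to_delta(x)) == pytest.approx(
            x, abs=1e-12)

    @given(st.floats(min_value=-50.0, max_value=5000.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, delta):
        # natural abundance through heavy labeling: permil-scale round trip
        assert abs(atom_fraction_to_delta(delta_to_atom_fraction(delta)) - delta) < 1e-9

    def test_measure_requires_exactly_one_scale(self):
        with pytest.raises(ValueError):
            IsotopeMeasure()
        with pytest.raises(ValueError):
            IsotopeMeasure(delta=0.0, atom_fraction=0.011)
        m = IsotopeMeasure(delta=-28.0)
        assert IsotopeMeasure(atom_fraction=m.atom_fraction).delta == pytest.approx(
            -28.0, abs=1e-9)


class TestGeogenicMixing:
    @pytest.mark.parametrize("delta_mix,f_geo", [(-28.0, 0.0), (-4.7, 1.0),
                                                 (-16.35, 0.5)])
    def test_end_members_and_midpoint(self, delta_mix, f_geo):
        res = geogenic_fraction(delta_mix)
        assert res.f_geo == pytest.approx(f_geo, abs=1e-12)
        assert res.f_geo + res.f_bio == pytest.approx(1.0, abs=1e-12)
        assert not res.clipped

    def test_monotone_between_end_members(self):
        deltas = np.linspace(-28.0, -4.7, 100)
        fractions = [geogenic_fraction(d).f_geo for d in deltas]
        assert np.all(np.diff(fractions) > 0)

    @pytest.mark.parametrize("delta_mix", [-30.0, -2.0])
    def test_clipping_flag(self, delta_mix):
        res = geogenic_fraction(delta_mix)
        assert res.clipped
        assert 0.0 <= res.f_geo <= 1.0
        assert res.raw_f_geo != res.f_geo

    def test_degenerate_end_members(self):
        with pytest.raises(DegenerateMixingError):
            geogenic_fraction(-10.0, delta_geo=-5.0, delta_bio=-5.0)

    def test_atom_fraction_space_close_to_delta_space(self):
        # over this natural-abundance delta range the two conventions differ
        # by well under 0.1% in the inferred fraction
        for d in np.linspace(-27.0, -5.0, 23):
            f_d = geogenic_fraction(d).f_geo
            f_x = geogenic_fraction(d, space="atom_fraction").f_geo
            assert abs(f_d - f_x) < 1e-3


def _keeling_normal_equations(co2, delta):
    """Independent oracle: explicit normal equations of delta on 1/CO2."""
    x = 1.0 / np.asarray(co2, dtype=float)
    y = np.asarray(delta, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestKeeling:
    def test_two_point_exact(self):
        res = keeling_intercept([400.0, 800.0], [-12.0, -10.0])
        assert res.intercept_delta == pytest.approx(-8.0, abs=1e-9)
        assert res.slope == pytest.approx(-1600.0, rel=1e-9)
        assert res.n_points == 2

    def test_constant_delta(self):
        res = keeling_intercept([400.0, 500.0, 700.0], [-20.0, -20.0, -20.0])
        assert res.intercept_delta == pytest.approx(-20.0, abs=1e-9)
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_source_recovery(self):
        co2 = np.array([450.0, 600.0, 800.0, 1200.0, 2000.0])
        delta = -22.0 + (-2000.0) / co2
        res = keeling_intercept(co2, delta)
        assert res.intercept_delta == pytest.approx(-22.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        co2 = rng.uniform(380.0, 3000.0, n)
        delta = rng.normal(-15.0, 5.0, n)
        res = keeling_intercept(co2, delta)
        i0, s0 = _keeling_normal_equations(co2, delta)
        assert res.intercept_delta == pytest.approx(i0, abs=1e-9)
        assert res.slope == pytest.approx(s0, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(SingularFitError):
            keeling_intercept([500.0, 500.0, 500.0], [-10.0, -11.0, -12.0])
        with pytest.raises(InsufficientDataError):
            keeling_intercept([500.0], [-10.0])
        with pytest.raises(SingularFitError):
            keeling_intercept([500.0, -10.0], [-10.0, -12.0])

    def test_gmr_option_on_noiseless_line(self):
        co2 = np.array([450.0, 600.0, 900.0, 1500.0])
        delta = -25.0 + (-1500.0) / co2
        res = keeling_intercept(co2, delta, method="gmr")
        assert res.intercept_delta == pytest.approx(-25.0, abs=1e-9)


class TestMicrobialBiomass:
    def test_mass_balance_example(self):
        res = microbial_biomass_isotope(300.0, -20.0, 100.0, -26.0)
        assert res.mb_c == pytest.approx(200.0)
        assert res.delta_mb == pytest.approx(-17.0, abs=1e-12)
        assert res.valid

    def test_zero_difference_flagged_not_raised(self):
        res = microbial_biomass_isotope(100.0, -25.0, 100.0, -25.0)
        assert not res.valid
        assert res.mb_c == 0.0
        assert np.isnan(res.delta_mb)

    def test_no_background_extract(self):
        res = microbial_biomass_isotope(200.0, -24.0, 0.0, -99.0)
        assert res.mb_c == pytest.approx(200.0)
        assert res.delta_mb == pytest.approx(-24.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_conserves_mass(self, seed):
        rng = np.random.default_rng(seed)
        c_nf = rng.uniform(50.0, 200.0)
        c_f = c_nf + rng.uniform(10.0, 300.0)
        d_f, d_nf = rng.normal(-20.0, 5.0, 2)
        res = microbial_biomass_isotope(c_f, d_f, c_nf, d_nf)
        assert res.mb_c * res.delta_mb + c_nf * d_nf == pytest.approx(
            c_f * d_f, abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            microbial_biomass_isotope(-1.0, -20.0, 0.0, -20.0)


class TestAnalyzerCalibration:
    def _gases(self, gain=1.1, offset_ppm=-20.0, d_gain=0.95, d_offset=0.4):
        def read(ppm, dlt):
            return gain * ppm + offset_ppm, d_gain * dlt + d_offset
        lo = CalibrationGas(430.0, -7.6, *read(430.0, -7.6))
        hi = CalibrationGas(2926.0, -3.7, *read(2926.0, -3.7))
        return lo, hi, read

    def test_fixed_points(self):
        lo, hi, _ = self._gases()
        ppm, dlt = calibrate_analyzer(lo.measured_ppm, lo.measured_delta, lo, hi)
        assert (ppm, dlt) == pytest.approx((430.0, -7.6), abs=1e-9)
        ppm, dlt = calibrate_analyzer(hi.measured_ppm, hi.measured_delta, lo, hi)
        assert (ppm, dlt) == pytest.approx((2926.0, -3.7), abs=1e-9)

    def test_inverts_affine_analyzer(self):
        lo, hi, read = self._gases()
        truth_ppm = np.array([400.0, 800.0, 1500.0, 2500.0])
        truth_dlt = np.array([-28.0, -10.0, 5.0, 300.0])
        raw_ppm, raw_dlt = read(truth_ppm, truth_dlt)
        ppm, dlt = calibrate_analyzer(raw_ppm, raw_dlt, lo, hi)
        np.testing.assert_allclose(ppm, truth_ppm, atol=1e-9)
        np.testing.assert_allclose(dlt, truth_dlt, atol=1e-9)

    def test_identical_gases_rejected(self):
        g = CalibrationGas(430.0, -7.6, 430.0, -7.6)
        with pytest.raises(DegenerateMixingError):
            calibrate_analyzer(500.0, -10.0, g, g)
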