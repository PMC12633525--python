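"""Assay calculations: extinction, kinetics, densitometry, CD analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confcouple import synthetic
from confcouple.wetlab import (
    DensitometryRecord,
    ExtinctionInput,
    KineticModel,
    Timecourse,
    band_density_percent,
    efficiency_from_slope,
    extinction_coefficient,
    fit_michaelis_menten,
    fold_change,
    initial_velocity,
    ip_percent_change,
    melting_temperature,
    mm_velocity,
    normalize_plthdp,
    time_to_fraction,
)


class TestExtinctionCoefficient:
    @pytest.mark.parametrize(
        "n_trp,n_tyr,expected",
        [(4, 19, 47080), (4, 18, 45800), (0, 0, 0)],
    )
    def test_trp_tyr_composition(self, n_trp, n_tyr, expected):
        assert extinction_coefficient(ExtinctionInput(n_trp, n_tyr)) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionInput(-1, 0)

    @given(
        a=st.tuples(st.integers(0, 50), st.integers(0, 50)),
        b=st.tuples(st.integers(0, 50), st.integers(0, 50)),
    )
    def test_linearity(self, a, b):
        total = ExtinctionInput(a[0] + b[0], a[1] + b[1])
        assert extinction_coefficient(total) == extinction_coefficient(
            ExtinctionInput(*a)
        ) + extinction_coefficient(ExtinctionInput(*b))


class TestMmVelocity:
    def setup_method(self):
        self.model = KineticModel(vmax=1.0, km=50.0, enzyme_conc=0.1)

    def test_half_saturation(self):
        assert mm_velocity(self.model, 50.0) == pytest.approx(0.5)

    def test_zero_substrate(self):
        assert mm_velocity(self.model, 0.0) == 0.0

    def test_closed_form(self):
        assert mm_velocity(self.model, 100.0) == pytest.approx(2.0 / 3.0)

    def test_monotone_bounded(self):
        S = np.linspace(0, 5000, 200)
        v = mm_velocity(self.model, S)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < self.model.vmax)

    def test_kcat_consistency(self):
        assert self.model.kcat == pytest.approx(
            self.model.vmax / self.model.enzyme_conc, rel=1e-9
        )


class TestFitMichaelisMenten:
    S = np.array([5.0, 10, 25, 50, 100, 250, 500])

    def test_noiseless_exact_recovery(self):
        S, v, truth = synthetic.generate_mm_data(vmax=1.0, km=50.0, S=self.S)
        model = fit_michaelis_menten(S, v, enzyme_conc=0.1)
        assert model.vmax == pytest.approx(truth["vmax"], rel=1e-6)
        assert model.km == pytest.approx(truth["km"], rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_noiseless_recovery_over_parameter_range(self, seed):
        rng = np.random.default_rng(seed)
        vmax = float(rng.uniform(0.01, 10.0))
        km = float(rng.uniform(5.0, 1000.0))
        S = km * np.array([0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0])
        _, v, _ = synthetic.generate_mm_data(vmax=vmax, km=km, S=S)
        model = fit_michaelis_menten(S, v, enzyme_conc=1.0)
        assert model.vmax == pytest.approx(vmax, rel=1e-6)
        assert model.km == pytest.approx(km, rel=1e-6)

    def test_noisy_km_within_three_se(self):
        S, v, _ = synthetic.generate_mm_data(
            vmax=1.0, km=50.0, S=self.S, noise_sigma=0.01, seed=5
        )
        model = fit_michaelis_menten(S, v, enzyme_conc=0.1)
        assert abs(model.km - 50.0) <= 3.0 * model.km_se

    def test_all_zero_velocities_error(self):
        with pytest.raises(RuntimeError):
            fit_michaelis_menten(self.S, np.zeros_like(self.S), enzyme_conc=0.1)

    def test_narrow_range_warns(self):
        S = np.array([1.0, 2.0, 3.0])
        v = 1.0 * S / (500.0 + S)
        with pytest.warns(UserWarning, match="span"):
            fit_michaelis_menten(S, v, enzyme_conc=0.1)


class TestEfficiencyFromSlope:
    def test_small_s_slope_converges_to_kcat_over_km(self):
        """The initial-region slope approaches kcat/Km as the region
        shrinks; the residual bias is the curvature term ~ s_max/Km."""
        vmax, km, E = 1.0, 50.0, 0.1
        kcat_km = (vmax / E) / km
        # geometric dilution series, as assays use
        S = km * np.array(
            [0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1, 2, 5, 10]
        )
        v_over_E = (vmax * S / (km + S)) / E
        slope10, _ = efficiency_from_slope(S, v_over_E, s_max=km / 10)
        assert slope10 == pytest.approx(kcat_km, rel=0.10)
        slope100, _ = efficiency_from_slope(S, v_over_E, s_max=km / 100)
        assert slope100 == pytest.approx(kcat_km, rel=0.015)
        assert abs(slope100 - kcat_km) < abs(slope10 - kcat_km)

    def test_two_points_through_origin(self):
        slope, icpt = efficiency_from_slope(
            np.array([1.0, 2.0]), np.array([0.013, 0.026]), s_max=10.0
        )
        assert slope == pytest.approx(0.013)
        assert icpt == pytest.approx(0.0, abs=1e-12)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            efficiency_from_slope(
                np.array([100.0, 200.0]), np.array([1.0, 2.0]), s_max=10.0
            )


class TestInitialVelocity:
    def test_linear_decay_conversion(self):
        """A340 slope −0.001 /s with the NADPH factor gives the closed-form
        positive rate in μM/s."""
        t = np.arange(0, 120, 20.0)
        tc = Timecourse(t, 1.0 - 0.001 * t, channel="A340")
        path = 0.55
        factor = -1.0 / (6220.0 * path) * 1e6
        rate = initial_velocity(tc, (0, 120), conversion=factor)
        assert rate == pytest.approx(0.001 / (6220.0 * path) * 1e6, rel=1e-9)
        assert rate > 0

    def test_constant_signal_zero(self):
        tc = Timecourse(np.arange(5.0), np.full(5, 2.0))
        assert initial_velocity(tc, (0, 5)) == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_data_errors(self):
        tc = Timecourse(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            initial_velocity(tc, (100, 200))


class TestBandDensity:
    @pytest.mark.parametrize(
        "band,lane,expected", [(200, 200, 100.0), (50, 200, 25.0), (0, 200, 0.0)]
    )
    def test_percent(self, band, lane, expected):
        assert band_density_percent(DensitometryRecord(band, lane)) == expected

    def test_band_exceeding_lane_rejected(self):
        with pytest.raises(ValueError):
            DensitometryRecord(300, 200)


class TestIpPercentChange:
    def test_fully_formed_signal_is_zero(self):
        assert ip_percent_change(5.0, 2.0, 3.0) == pytest.approx(0.0)

    def test_time_zero_is_minus_hundred(self):
        assert ip_percent_change(2.0, 2.0, 3.0) == pytest.approx(-100.0)

    def test_direct_substitution(self):
        assert ip_percent_change(1.0, 0.0, 2.0) == pytest.approx(-50.0)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            ip_percent_change(1.0, 0.0, 0.0)

    @given(
        cd_t=st.floats(-10, 10),
        cd_0=st.floats(-10, 10),
        delta=st.floats(0.1, 10),
    )
    def test_conventions_differ_by_exactly_hundred(self, cd_t, cd_0, delta):
        printed = ip_percent_change(cd_t, cd_0, delta, "printed")
        relative = ip_percent_change(cd_t, cd_0, delta, "relative")
        assert relative - printed == pytest.approx(100.0, abs=1e-9)


class TestNormalizePlthdp:
    def test_constant_reference_zeroes_identical_signal(self):
        tc = Timecourse(np.arange(5.0), np.full(5, 1.3))
        out = normalize_plthdp(tc, 1.3)
        np.testing.assert_allclose(out.values, 0.0)

    def test_zero_reference_identity(self):
        tc = Timecourse(np.arange(5.0), np.arange(5.0) * 0.1)
        np.testing.assert_array_equal(normalize_plthdp(tc, 0.0).values, tc.values)

    def test_planted_offset_removed(self):
        tc, _ = synthetic.generate_cd_timecourse(baseline=1.3, noise_sigma=0.0)
        out = normalize_plthdp(tc, 1.3)
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)


class TestMeltingTemperature:
    def test_logistic_midpoint_sixty(self):
        tc, _ = synthetic.generate_melt_curve(tm=60.0, slope=2.0)
        assert melting_temperature(tc) == pytest.approx(60.0, abs=0.1)

    def test_wt_like_tm_74(self):
        tc, truth = synthetic.generate_melt_curve(tm=74.0, slope=2.0)
        assert melting_temperature(tc) == pytest.approx(truth["tm"], abs=0.1)

    @pytest.mark.parametrize("slope", [1.0, 2.0, 3.0, 5.0])
    def test_midpoint_recovery_across_slopes(self, slope):
        tc, _ = synthetic.generate_melt_curve(tm=65.0, slope=slope)
        assert melting_temperature(tc) == pytest.approx(65.0, abs=0.2)

    def test_linear_ramp_no_transition(self):
        tc = Timecourse(np.arange(20.0, 88.0), -20 + 0.1 * np.arange(68.0))
        with pytest.raises(ValueError, match="no transition"):
            melting_temperature(tc)


class TestFoldChange:
    def test_kcat_decrease_f298a(self):
        # WT kcat 8.3e-1 vs F298A 2.3e-2: ≥36-fold decrease
        fold = fold_change(8.3e-1, 2.3e-2, mode="decrease")
        assert fold == pytest.approx(36.1, abs=0.1)
        assert fold >= 36.0

    def test_km_increase_y288q_rounds_to_26(self):
        assert fold_change(39.0, 1022.0, mode="increase", rounding="nearest-int") == 26

    def test_equal_values_unity(self):
        assert fold_change(3.0, 3.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestTimeToFraction:
    def test_closed_form(self):
        assert time_to_fraction(0.05, 0.95) == pytest.approx(np.log(20) / 0.05)

    def test_formation_rate_ranking(self):
        """Faster adduct formation reaches 95% amplitude sooner."""
        _, wt = synthetic.generate_cd_timecourse(rate=np.log(20) / 60.0)
        _, slow = synthetic.generate_cd_timecourse(rate=np.log(20) / 360.0)
        assert time_to_fraction(wt["rate"]) == pytest.approx(60.0)
        assert time_to_fraction(slow["rate"]) == pytest.approx(360.0)
        assert time_to_fraction(wt["rate"]) < time_to_fraction(slow["rate"])
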