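"""Enzyme-latency pipeline: rates, slopes, ratio, P_m, Arrhenius, transport fits."""

import math

import numpy as np
import pytest
from scipy import stats

from h2o2perm import (
    ArrheniusModel,
    Geometry,
    LatencyExperiment,
    NoLatencyError,
    NoLatencyWarning,
    SignalKind,
    TimeCourse,
    arrhenius_fit,
    fit_transport_trace,
    initial_rate,
    latency_ratio,
    pm_from_latency,
    r_from_pm,
    secondary_slope,
    to_concentration,
)
from h2o2perm import constants
from h2o2perm.exceptions import FitError, InsufficientDataError
from h2o2perm.synthetic import gen_stopped_flow, gen_timecourse_series


def make_trace(t, y, kind=SignalKind.concentration, **kw):
    return TimeCourse(t=np.asarray(t, float), y=np.asarray(y, float),
                      signal_kind=kind, **kw)


class TestToConcentration:
    def test_beer_lambert_at_240nm(self):
        tc = make_trace([0, 1, 2, 3], [0.394] * 4, SignalKind.absorbance240)
        conv = to_concentration(tc)
        assert conv.signal_kind == SignalKind.concentration
        assert conv.y == pytest.approx([0.01] * 4, rel=1e-12)

    def test_zero_absorbance_is_zero_concentration(self):
        tc = make_trace([0, 1, 2, 3], [0.0] * 4, SignalKind.absorbance240)
        assert np.all(to_concentration(tc).y == 0.0)

    def test_oxyhemoglobin_at_577nm(self):
        tc = make_trace([0, 1, 2, 3], [0.15] * 4, SignalKind.absorbance577)
        assert to_concentration(tc).y == pytest.approx([10e-6] * 4, rel=1e-12)

    def test_scattering_has_no_conversion(self):
        tc = make_trace([0, 1, 2, 3], [1.0] * 4, SignalKind.scattering)
        with pytest.raises(ValueError):
            to_concentration(tc)


class TestInitialRate:
    def test_noiseless_exponential_within_three_percent(self):
        """Early-window slope on <=5% consumption approximates k*C0."""
        k, C0 = 0.01, 10e-3
        t = np.linspace(0, 0.05 / k, 60)  # window spans ~5% consumption
        tc = make_trace(t, C0 * np.exp(-k * t))
        ir = initial_rate(tc, max_fraction=0.05, max_time=math.inf)
        assert ir.rate == pytest.approx(k * C0, rel=0.03)

    def test_constant_signal_has_zero_rate(self):
        tc = make_trace([0, 1, 2, 3, 4], [0.5] * 5)
        assert initial_rate(tc).rate == pytest.approx(0.0, abs=1e-15)

    def test_noisy_trace_within_three_standard_errors(self):
        k, C0 = 0.005, 10e-3
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 60.0, 1.0)
        y = C0 * np.exp(-k * t) * (1 + 0.01 * rng.standard_normal(len(t)))
        ir = initial_rate(make_trace(t, y))
        assert abs(ir.rate - k * C0) < 3 * ir.stderr + 0.05 * k * C0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            make_trace([0, 1, 2], [1, 2, 3])


class TestSecondarySlope:
    def test_line_through_origin(self):
        pts = [(a, 2.5 * a) for a in (5, 10, 15, 20, 25)]
        rs = secondary_slope(pts)
        assert rs.slope == pytest.approx(2.5, rel=1e-12)
        assert rs.intercept == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_point_order(self):
        pts = [(5, 1.1), (10, 2.3), (15, 3.2), (20, 4.1)]
        assert secondary_slope(pts).slope == pytest.approx(
            secondary_slope(pts[::-1]).slope, rel=1e-12
        )

    def test_rescaling_amounts_rescales_slope_inversely(self):
        pts = [(5, 1.1), (10, 2.3), (15, 3.2), (20, 4.1)]
        scaled = [(a * 10, r) for a, r in pts]
        assert secondary_slope(scaled).slope == pytest.approx(
            secondary_slope(pts).slope / 10, rel=1e-12
        )

    def test_identical_amounts_rejected(self):
        with pytest.raises(InsufficientDataError):
            secondary_slope([(5, 1.0), (5, 2.0)])


class TestLatencyRatio:
    def test_fourfold_latency(self):
        assert latency_ratio(1.0, 4.3) == pytest.approx(1 / 4.3, rel=1e-12)

    def test_intact_cells_at_23_percent_of_lysed_activity(self):
        assert latency_ratio(0.23, 1.0) == pytest.approx(0.23)

    def test_no_barrier_is_flagged_not_raised(self):
        with pytest.warns(NoLatencyWarning):
            R = latency_ratio(1.0, 1.0)
        assert R == 1.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(NoLatencyError):
            latency_ratio(0.0, 1.0)


class TestPmFromLatency:
    def test_rbc_headline_permeability(self):
        """R = 1/4.3 with RBC geometry and the frozen catalase constant gives 1.6e-3."""
        P_m = pm_from_latency(1 / 4.3, constants.K_CATALASE_RBC, Geometry.rbc())
        assert P_m == pytest.approx(1.6e-3, rel=0.01)

    def test_impermeable_limit(self):
        assert pm_from_latency(1e-9, 82.1, Geometry.rbc()) < 1e-10

    def test_sphere_scaling_halving_radius_doubles_pm(self):
        R, k = 0.3, 50.0
        p100 = pm_from_latency(R, k, Geometry.sphere(100.0))
        p50 = pm_from_latency(R, k, Geometry.sphere(50.0))
        assert Geometry.sphere(100.0).area_to_volume() == pytest.approx(3e5, rel=1e-12)
        assert p50 == pytest.approx(p100 / 2, rel=1e-12)

    def test_round_trip_with_inverse_over_grid(self):
        geom = Geometry.rbc()
        for R in np.linspace(0.05, 0.95, 10):
            for k in (10.0, 82.1, 500.0):
                P = pm_from_latency(R, k, geom)
                assert r_from_pm(P, k, geom) == pytest.approx(R, rel=1e-12)

    def test_r_outside_unit_interval_rejected(self):
        with pytest.raises(NoLatencyError):
            pm_from_latency(1.2, 82.1, Geometry.rbc())


class TestFullPipelineRecovery:
    @pytest.mark.parametrize("P_true, radius_nm", [(3.7e-5, 100.0), (1.3e-3, 500.0)])
    def test_median_recovery_within_ten_percent(self, P_true, radius_nm):
        """Liposome dose series at 1% noise: median recovered P_m within 10% (20 seeds)."""
        recovered = []
        for seed in range(20):
            sample = gen_timecourse_series(
                design="liposome", P_m=P_true, k_catalase=80.0,
                radius_nm=radius_nm, noise_sd=0.01, seed=seed,
            )
            res = LatencyExperiment(
                sample.intact, sample.disrupted, sample.geometry, k_catalase=80.0
            ).fit()
            recovered.append(res.P_m)
        assert np.median(recovered) == pytest.approx(P_true, rel=0.10)

    def test_results_summary_mentions_key_quantities(self):
        sample = gen_timecourse_series(design="liposome", P_m=3.7e-5, k_catalase=80.0,
                                       radius_nm=100.0, noise_sd=0.0, seed=0)
        res = LatencyExperiment(sample.intact, sample.disrupted, sample.geometry, 80.0).fit()
        text = res.summary()
        assert "P_m" in text and "gradient" in text


class TestArrhenius:
    def test_rbc_two_point_activation_energy(self):
        """25/37 C permeabilities give E_a ~ 30 kJ/mol, inside the 32 +- 4 band."""
        fit = arrhenius_fit([(298.15, 1.0e-3), (310.15, 1.6e-3)])
        assert 28.0 <= fit.E_a <= 36.0

    def test_temperature_independent_pm_has_zero_activation_energy(self):
        fit = arrhenius_fit([(293.15, 1e-3), (303.15, 1e-3), (313.15, 1e-3)])
        assert fit.E_a == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_forward_model_recovered_exactly(self):
        E_a, lnA = 57.0, 10.0
        temps = [constants.celsius_to_kelvin(c) for c in range(20, 41, 5)]
        pts = [(T, math.exp(lnA - E_a * 1000 / (constants.R_GAS * T))) for T in temps]
        fit = arrhenius_fit(pts)
        assert fit.E_a == pytest.approx(E_a, rel=1e-10)
        assert fit.lnA == pytest.approx(lnA, rel=1e-10)

    def test_prediction_round_trip(self):
        fit = arrhenius_fit([(298.15, 1.0e-3), (310.15, 1.6e-3)])
        assert fit.predict(298.15) == pytest.approx(1.0e-3, rel=1e-9)

    def test_single_temperature_rejected(self):
        with pytest.raises(InsufficientDataError):
            ArrheniusModel([(298.15, 1e-3), (298.15, 2e-3)])

    def test_activation_energy_recovery_unbiased_under_noise(self):
        """10% multiplicative noise on P_m leaves E_a unbiased over 200 seeds."""
        estimates = []
        for seed in range(200):
            from h2o2perm.synthetic import gen_arrhenius_series

            sample = gen_arrhenius_series(E_a=130.0, P_ref=3.7e-5, noise_sd=0.10, seed=seed)
            estimates.append(arrhenius_fit(sample.points()).E_a)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - 130.0) < 2 * se


class TestTransportFits:
    def test_noiseless_single_exponential_is_exact(self):
        sample = gen_stopped_flow("single_exp", k_water=5.0, noise_sd=0.0)
        fit = fit_transport_trace(sample.trace, "single_exp")
        assert fit.k_water == pytest.approx(5.0, rel=1e-6)

    def test_double_exponential_recovery_unbiased(self):
        """Seeded shrink-reswell traces: mean k_glycerol within 2 SE of 0.2 (100 seeds)."""
        ks = []
        for seed in range(100):
            sample = gen_stopped_flow("double_exp", k_rise=8.0, k_glycerol=0.2,
                                      noise_sd=0.02, seed=seed)
            ks.append(fit_transport_trace(sample.trace, "double_exp").k_glycerol)
        ks = np.asarray(ks)
        se = ks.std(ddof=1) / math.sqrt(len(ks))
        assert abs(ks.mean() - 0.2) < 2 * se

    def test_inhibited_glycerol_transport_separates(self):
        """Two trace sets with threefold different k_glycerol separate at p < 1e-4."""
        control, treated = [], []
        for seed in range(20):
            c = gen_stopped_flow("double_exp", k_glycerol=0.3, noise_sd=0.02, seed=seed)
            t = gen_stopped_flow("double_exp", k_glycerol=0.1, noise_sd=0.02, seed=1000 + seed)
            control.append(fit_transport_trace(c.trace, "double_exp").k_glycerol)
            treated.append(fit_transport_trace(t.trace, "double_exp").k_glycerol)
        res = stats.ttest_ind(control, treated)
        assert res.pvalue < 1e-4
        assert np.mean(control) > np.mean(treated)

    def test_sorted_constants_rise_faster_than_decay(self):
        sample = gen_stopped_flow("double_exp", k_rise=8.0, k_glycerol=0.2,
                                  noise_sd=0.02, seed=3)
        fit = fit_transport_trace(sample.trace, "double_exp")
        assert fit.k_rise > fit.k_glycerol

    def test_flat_trace_raises_fit_error(self):
        sample = gen_stopped_flow("single_exp", amplitude=0.0, noise_sd=0.0)
        assert sample.truth["flat"]
        with pytest.raises(FitError):
            fit_transport_trace(sample.trace, "single_exp")
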