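"""Two-compartment H2O2 clearance model: gradients, half-life, fractions, closure."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from h2o2perm import (
    KineticScenario,
    PrxMode,
    RBCKineticsModel,
    extracellular_rate_constant,
    forward_latency,
    half_life,
    physiological_scenario,
    simulate,
    steady_state_gradient,
)
from h2o2perm import constants
from h2o2perm.synthetic import RBC_AMOUNTS_M


def catalase_only(P_m=1.6e-3, hematocrit=1e-4, C0=10e-3, k_cat=constants.K_CATALASE_RBC):
    return KineticScenario(P_m=P_m, hematocrit=hematocrit, C0_out=C0, k_cat=k_cat)


class TestSimulate:
    def test_no_cells_no_consumption(self):
        sc = KineticScenario(P_m=1.6e-3, hematocrit=0.0, C0_out=1e-3,
                             k_cat=constants.K_CATALASE_RBC)
        res = simulate(sc, t_end=10.0)
        assert res.C_out == pytest.approx(np.full_like(res.C_out, 1e-3), rel=1e-9)

    def test_well_mixed_limit_matches_closed_form(self):
        """Huge P_m: the suspension behaves as one well-mixed compartment.

        With C_in = C_out = C, consumption happens in the cell fraction f,
        so total H2O2 decays as dC/dt = -f k_intra C (single-compartment
        closed form).
        """
        f, k_cat = 0.05, 82.1
        sc = KineticScenario(P_m=1e3, hematocrit=f, C0_out=1e-3, k_cat=k_cat)
        k_expected = k_cat * f
        res = simulate(sc, t_end=2 * math.log(2) / k_expected)
        mask = res.C_out > 0.1 * sc.C0_out
        slope = stats.linregress(res.t[mask], np.log(res.C_out[mask])).slope
        assert -slope == pytest.approx(k_expected, rel=1e-3)

    def test_mass_conservation_reported_small(self):
        res = simulate(catalase_only(), t_end=10.0)
        assert res.mass_error <= 1e-6

    def test_tolerance_invariance_to_four_significant_figures(self):
        sc = physiological_scenario()
        h1 = half_life(sc, rtol=1e-8)
        h2 = half_life(sc, rtol=1e-10, atol=1e-16)
        assert h1 == pytest.approx(h2, rel=1e-4)


class TestSteadyStateGradient:
    def test_prx2_dominated_gradient_is_sixteen_hundred_fold(self):
        sc = KineticScenario(
            P_m=1.6e-3, hematocrit=0.45, C0_out=1e-6,
            k_prx=1e8, prx_total=400e-6,
        )
        g = steady_state_gradient(sc)
        assert round(g, -2) == 1600

    def test_catalase_only_gradient_is_4_3_fold(self):
        g = steady_state_gradient(catalase_only())
        assert g == pytest.approx(4.3, abs=0.05)

    def test_no_consumption_means_no_gradient(self):
        sc = KineticScenario(P_m=1.6e-3, hematocrit=0.1, C0_out=1e-6)
        assert steady_state_gradient(sc) == pytest.approx(1.0)

    def test_closed_form_agrees_with_ode_on_parameter_grid(self):
        """Quasi-steady C_out/C_in from the ODE matches 1 + k_intra/(P_m A/V) to <0.1%."""
        P_grid = np.logspace(-4, -2, 10)
        k_grid = np.logspace(0.5, 4.5, 10)
        for P_m in P_grid:
            for k_intra in k_grid:
                sc = KineticScenario(P_m=P_m, hematocrit=1e-4, C0_out=1e-3, k_cat=k_intra)
                k_ext = extracellular_rate_constant(sc)
                res = simulate(sc, t_end=math.log(2) / k_ext, n_points=100)
                assert res.gradient == pytest.approx(
                    steady_state_gradient(sc), rel=1e-3
                )


class TestHalfLife:
    def test_physiological_half_life_about_35_ms(self):
        t_half = half_life(physiological_scenario())
        assert 31.8e-3 <= t_half <= 38.8e-3

    def test_doubling_pm_roughly_halves_half_life(self):
        sc = physiological_scenario()
        t1 = half_life(sc)
        t2 = half_life(replace(sc, P_m=2 * sc.P_m))
        assert t2 < t1
        assert t2 == pytest.approx(t1 / 2, rel=0.05)  # permeation-limited regime

    def test_closed_form_permeation_limited_estimate(self):
        sc = physiological_scenario()
        g = steady_state_gradient(sc)
        k = sc.P_m * sc.area_to_volume * sc.hematocrit / (1 - sc.hematocrit) * (1 - 1 / g)
        assert half_life(sc) == pytest.approx(math.log(2) / k, rel=0.02)

    @pytest.mark.parametrize("param", ["P_m", "hematocrit", "k_cat"])
    def test_monotone_decreasing(self, param):
        base = dict(P_m=1.6e-3, hematocrit=0.2, C0_out=1e-6, k_cat=82.1)
        values = {
            "P_m": [4e-4, 1.6e-3, 6.4e-3],
            "hematocrit": [0.1, 0.3, 0.45],
            "k_cat": [20.0, 82.1, 300.0],
        }[param]
        halves = []
        for v in values:
            sc = KineticScenario(**{**base, param: v})
            halves.append(half_life(sc))
        assert halves[0] > halves[1] > halves[2]


class TestPathwayFractions:
    def test_catalase_only_gets_full_share(self):
        res = simulate(catalase_only(), t_end=10.0)
        fc, fp = res.pathway_fractions()
        assert fc == pytest.approx(1.0)
        assert fc + fp == pytest.approx(1.0, abs=1e-9)

    def test_bolus_depletes_prx_pool_catalase_dominates(self):
        """10 mM bolus vs a finite 400 uM Prx2 pool: catalase share >= 0.95."""
        sc = KineticScenario(
            P_m=1.6e-3, hematocrit=1e-4, C0_out=10e-3,
            k_cat=82.1, k_prx=1e8, prx_total=400e-6,
            prx_mode=PrxMode.finite_pool_no_recycling,
        )
        res = simulate(sc, t_end=5 * math.log(2) / extracellular_rate_constant(
            replace(sc, k_prx=0.0, prx_total=0.0)))
        fc, fp = res.pathway_fractions()
        assert fc >= 0.95
        assert fc + fp == pytest.approx(1.0, abs=1e-9)

    def test_lower_dose_shifts_share_to_prx(self):
        shares = []
        for C0 in (10e-3, 5e-3, 2.5e-3):
            sc = KineticScenario(
                P_m=1.6e-3, hematocrit=1e-4, C0_out=C0,
                k_cat=82.1, k_prx=1e8, prx_total=400e-6,
                prx_mode=PrxMode.finite_pool_no_recycling,
            )
            k_ref = extracellular_rate_constant(replace(sc, k_prx=0.0, prx_total=0.0))
            res = simulate(sc, t_end=5 * math.log(2) / k_ref)
            shares.append(res.pathway_fractions()[1])
        assert shares[0] < shares[1] < shares[2]


class TestForwardLatency:
    def test_lysed_to_intact_ratio_is_4_3(self):
        res = forward_latency(catalase_only(), amounts=RBC_AMOUNTS_M)
        assert round(res.ratio, 1) == 4.3

    def test_pipeline_inversion_recovers_pm_across_grid(self):
        """Forward simulation then latency inversion is the identity on P_m to <2%."""
        for P_m in (1e-4, 3e-4, 1e-3, 3e-3, 1e-2):
            res = forward_latency(catalase_only(P_m=P_m), amounts=RBC_AMOUNTS_M)
            assert res.P_m_recovered == pytest.approx(P_m, rel=0.02)

    def test_huge_pm_shows_no_latency(self):
        res = forward_latency(catalase_only(P_m=1.0), amounts=RBC_AMOUNTS_M)
        assert res.R > 0.99

    def test_requires_catalase_only_scenario(self):
        with pytest.raises(ValueError):
            forward_latency(physiological_scenario(), amounts=RBC_AMOUNTS_M)


class TestModelFacade:
    def test_summary_and_reaction_table(self):
        model = RBCKineticsModel(physiological_scenario())
        res = model.simulate()
        text = res.summary()
        assert "gradient" in text and "half-life" in text
        table = model.reaction_table()
        assert set(table["reaction"]) >= {"permeation", "catalase", "prx2"}
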