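"""Scenario transforms, one-way DSA, PSA and CEAC behaviour."""

import numpy as np
import pandas as pd
import pytest

from htncea import cea
from htncea.params import UncertainParam
from htncea.sensitivity import (
    PSAResult,
    apply_scenario,
    ceac,
    one_way_dsa,
    run_psa,
    uncertainty_interval,
)


def _fast(params, cycles=10):
    params.cycles = cycles
    return params


class TestApplyScenario:
    def test_empty_scenario_is_identity(self, params):
        from htncea.params import dump_parameters

        out = apply_scenario(params, {})
        assert dump_parameters(out) == dump_parameters(params)

    def test_adherence_scales_risk_reduction(self, params):
        out = apply_scenario(params, {"adherence": 0.5})
        assert out.treatment.adherence == 0.5
        # effective rr with rr = 0.7 and 50% adherence: 1 - 0.5*(1-0.7)
        from htncea.markov import TreatmentScenario

        scen = TreatmentScenario(
            "treated", 0.7, rr_events={"event_MI": 0.7}, adherence=0.5
        )
        assert scen.effective_rr("event_MI") == pytest.approx(0.85)

    def test_pill_disutility_combines_multiplicatively(self, params):
        from htncea.burden import combine_dw

        out = apply_scenario(params, {"pill_disutility": True})
        assert out.treatment.pill_disutility_on
        w = combine_dw(
            out.disability_weights.treated_controlled,
            out.disability_weights.pill_disutility.mean,
        )
        assert w == pytest.approx(0.211621, abs=1e-6)

    def test_lag_and_risk_mode(self, params):
        out = apply_scenario(params, {"lag_years": 1, "risk_mode": "linear_increasing"})
        assert out.treatment.lag_years == 1
        assert out.transitions.risk_mode == "linear_increasing"

    def test_unknown_key_rejected(self, params):
        with pytest.raises(KeyError, match="unknown scenario"):
            apply_scenario(params, {"not_a_knob": 1})

    def test_original_book_untouched(self, params):
        before = params.treatment.adherence
        apply_scenario(params, {"adherence": 0.25})
        assert params.treatment.adherence == before


class TestOneWayDSA:
    def test_zero_width_range_reproduces_base(self, params):
        ps = _fast(params)
        base = ps.costs.discount_rate
        res = one_way_dsa(ps, "costs.discount_rate", base, base)
        assert res.icer_low == pytest.approx(res.icer_base, abs=1e-9)
        assert res.icer_high == pytest.approx(res.icer_base, abs=1e-9)

    def test_drug_price_moves_treated_cost_monotonically(self, params):
        ps = _fast(params)
        base = ps.costs.annual_drug_cost.mean
        res = one_way_dsa(ps, "costs.annual_drug_cost", 0.8 * base, 1.2 * base)
        # pricier drugs make the treated arm worse: NMB strictly ordered
        assert res.nmb_low > res.nmb_high

    def test_discount_rate_bounds(self, params):
        ps = _fast(params)
        res = one_way_dsa(ps, "costs.discount_rate", 0.03, 0.06)
        assert res.icer_low != res.icer_high  # discounting matters

    def test_swapped_bounds_rejected(self, params):
        with pytest.raises(ValueError):
            one_way_dsa(params, "costs.discount_rate", 0.06, 0.03)


class TestPSA:
    def test_point_mass_book_reproduces_deterministic_run(self, params):
        ps = _fast(params)
        include = ("treatment.rr_chd", "treatment.rr_stroke")
        for path in include:
            exec_val = {"treatment.rr_chd": 0.78, "treatment.rr_stroke": 0.62}[path]
            section, leaf = path.split(".")
            setattr(getattr(ps, section), leaf, UncertainParam(exec_val))
        base = cea.evaluate(ps)
        psa = run_psa(ps, n_draws=3, seed=1, include=include)
        for col, value in (
            ("delta_cost", base.overall.delta_cost),
            ("delta_dalys", base.overall.delta_dalys),
        ):
            assert (psa.draws[col] == value).all()  # bit-for-bit

    def test_same_seed_reproducible(self, params):
        ps = _fast(params, cycles=5)
        a = run_psa(ps, n_draws=5, seed=42)
        b = run_psa(ps, n_draws=5, seed=42)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_intervals_are_empirical_percentiles(self, params):
        ps = _fast(params, cycles=5)
        psa = run_psa(ps, n_draws=40, seed=7)
        lo, hi = psa.intervals["delta_dalys"]
        exp_lo, exp_hi = np.percentile(psa.draws["delta_dalys"], [2.5, 97.5])
        assert (lo, hi) == pytest.approx((exp_lo, exp_hi))

    def test_constructed_cost_saving_fraction_is_one(self):
        draws = pd.DataFrame(
            {
                "delta_cost": [10.0, 5.0, 1.0],
                "delta_dalys": [1.0, 2.0, 3.0],
                "icer": [10.0, 2.5, 1 / 3],
                "nmb": [1.0, 1.0, 1.0],
            }
        )
        psa = PSAResult(3, 0, draws)
        assert psa.fraction_cost_saving == 1.0
        quads = psa.quadrant_fractions()
        assert quads["more_effective_cost_saving"] == 1.0


class TestCEAC:
    def _psa_from(self, delta_cost, delta_dalys):
        n = len(delta_cost)
        return PSAResult(
            n, 0,
            pd.DataFrame(
                {
                    "delta_cost": delta_cost,
                    "delta_dalys": delta_dalys,
                    "icer": np.zeros(n),
                    "nmb": np.zeros(n),
                }
            ),
        )

    def test_all_dominant_draws_curve_is_one(self):
        psa = self._psa_from([5.0, 3.0], [1.0, 2.0])
        curve = ceac(psa, [0.0, 100.0, 1e6])
        assert np.all(curve.probability == 1.0)

    def test_wtp_zero_equals_cost_saving_fraction(self):
        psa = self._psa_from([5.0, -3.0, 1.0], [1.0, 1.0, 1.0])
        curve = ceac(psa, [0.0])
        assert curve.probability[0] == pytest.approx(psa.fraction_cost_saving)

    def test_two_draw_split_at_known_wtp(self):
        # draw 1: NMB(100) = 100*1 - 50 > 0; draw 2: 100*1 - 150 < 0
        psa = self._psa_from([-50.0, -150.0], [1.0, 1.0])
        curve = ceac(psa, [100.0])
        assert curve.probability[0] == 0.5

    def test_large_wtp_limit_is_positive_effect_fraction(self):
        psa = self._psa_from([0.0, 0.0, 0.0, 0.0], [1.0, -1.0, 2.0, -0.5])
        curve = ceac(psa, [1e12])
        assert curve.probability[0] == pytest.approx(0.5)

    def test_bernoulli_fraction_recovered_within_mc_error(self):
        rng = np.random.default_rng(0)
        p = 0.3
        n = 1000
        effect = np.where(rng.random(n) < p, 1.0, -1.0)
        psa = self._psa_from(np.zeros(n), effect)
        curve = ceac(psa, [1e9])
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(curve.probability[0] - p) < tol

    def test_empty_grid_rejected(self):
        psa = self._psa_from([1.0], [1.0])
        with pytest.raises(ValueError):
            ceac(psa, [])


class TestUncertaintyInterval:
    def test_constant_draws_degenerate(self):
        assert uncertainty_interval([2.0, 2.0, 2.0]) == (2.0, 2.0)

    def test_linear_interpolation_rule(self):
        lo, hi = uncertainty_interval(np.arange(1, 1001), 0.95)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_nested_as_level_grows(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(size=500)
        lo90, hi90 = uncertainty_interval(draws, 0.90)
        lo99, hi99 = uncertainty_interval(draws, 0.99)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_insufficient_draws(self):
        with pytest.raises(ValueError):
            uncertainty_interval([1.0])
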