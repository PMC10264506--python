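"""Base case, PSA, CEAC, tornado, horizon sweep and scenario analyses."""

import logging

import numpy as np
import pytest

import excea
from excea import CEResult, base_case, ceac, extended_supervision_scenario, horizon_sweep, run_psa, tornado
from excea.analyses import EXTENDED_SUPERVISION_COST
from excea.params import ParameterRegistry, ParameterSpec


@pytest.fixture(scope="module")
def fixed_registry(registry):
    """Same means, every distribution degenerate (no parameter uncertainty)."""
    reg = ParameterRegistry()
    for s in registry.specs:
        family = "table" if s.family == "table" else "fixed"
        reg.add(ParameterSpec(s.name, family, s.mean, units=s.units, group=s.group))
    return reg


@pytest.fixture(scope="module")
def psa_small(registry, life_table, utility_table):
    return run_psa(registry, life_table, utility_table, n_iter=500, seed=7)


class TestCEResult:
    def test_inmb_identity(self):
        r = CEResult(0.0, 358.0, 0.0, 0.0789, wtp=50_000)
        assert r.inmb == pytest.approx(50_000 * 0.0789 - 358, abs=1e-9)

    def test_icer_undefined_when_no_qaly_difference(self):
        r = CEResult(100.0, 100.0, 2.0, 2.0)
        assert not r.icer_defined and np.isnan(r.icer)
        assert r.delta_cost == 0 and r.delta_qaly == 0

    def test_dominance_flag(self):
        r = CEResult(100.0, 99.0, 2.0, 2.01)
        assert r.dominant and r.inmb > 0
        assert not CEResult(100.0, 101.0, 2.0, 2.01).dominant


class TestBaseCase:
    def test_null_intervention_gives_zero_increments(
        self, registry, life_table, utility_table
    ):
        res = base_case(
            registry, life_table, utility_table,
            overrides={"hr_cvd_exercise": 1.0, "hr_recurrence_exercise": 1.0,
                       "c_exercise": 0.0},
        )
        assert res.delta_cost == 0.0 and res.delta_qaly == 0.0
        assert not res.icer_defined

    def test_base_case_exercise_costs_more_gains_qalys(
        self, registry, life_table, utility_table
    ):
        res = base_case(registry, life_table, utility_table)
        assert res.delta_qaly > 0
        assert res.cost_intervention > res.cost_control
        assert res.inmb == pytest.approx(
            res.wtp * res.delta_qaly - res.delta_cost, abs=1e-9
        )


class TestPSA:
    def test_same_seed_identical_summaries(self, registry, life_table, utility_table):
        a = run_psa(registry, life_table, utility_table, n_iter=200, seed=11)
        b = run_psa(registry, life_table, utility_table, n_iter=200, seed=11)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        assert a.summary().to_dict() == b.summary().to_dict()

    def test_fixed_parameters_reproduce_base_case_exactly(
        self, fixed_registry, life_table, utility_table
    ):
        res_det = base_case(fixed_registry, life_table, utility_table)
        psa = run_psa(fixed_registry, life_table, utility_table, n_iter=1, seed=3)
        s = psa.summary()
        assert s.cost_control == res_det.cost_control
        assert s.cost_intervention == res_det.cost_intervention
        assert s.qaly_control == res_det.qaly_control
        assert s.qaly_intervention == res_det.qaly_intervention

    def test_summary_icer_is_ratio_of_mean_increments(self, psa_small):
        s = psa_small.summary()
        assert s.icer == pytest.approx(
            psa_small.delta_cost.mean() / psa_small.delta_qaly.mean(), rel=1e-12
        )

    def test_percentile_bounds_bracket_means(self, psa_small):
        s = psa_small.summary()
        lo, hi = s.ci["delta_qaly"]
        assert lo <= s.delta_qaly <= hi

    def test_psa_mean_converges_to_base_case_with_one_free_parameter(
        self, registry, fixed_registry, life_table, utility_table
    ):
        """With only the baseline-CVD beta free, PSA means agree with the
        deterministic base case within 3 Monte Carlo standard errors."""
        reg = ParameterRegistry()
        for s in fixed_registry.specs:
            if s.name == "p_cvd_baseline":
                reg.add(registry["p_cvd_baseline"])
            else:
                reg.add(ParameterSpec(s.name, s.family, s.mean, units=s.units, group=s.group))
        psa = run_psa(reg, life_table, utility_table, n_iter=10_000, seed=5)
        det = base_case(reg, life_table, utility_table)
        for arr, target in [(psa.delta_cost, det.delta_cost),
                            (psa.delta_qaly, det.delta_qaly)]:
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - target) < 3 * se + 1e-12

    def test_iteration_frame_schema(self, psa_small):
        f = psa_small.to_frame()
        assert set(f.columns) == {"iteration", "arm", "cost", "qaly"}
        assert len(f) == 2 * psa_small.n_iter


class TestCEAC:
    def test_limits_match_sign_fractions(self, psa_small):
        curve = ceac(psa_small, [0.0, 1e9])
        p0 = float(np.mean(psa_small.delta_cost < 0))
        p_inf = float(np.mean(psa_small.delta_qaly > 0))
        assert curve["probability"].iloc[0] == pytest.approx(p0)
        assert curve["probability"].iloc[1] == pytest.approx(p_inf)

    def test_monotone_when_all_gains_positive(self, psa_small):
        keep = psa_small.delta_qaly > 0
        sub = excea.PSAResult(
            psa_small.cost_control[keep], psa_small.cost_intervention[keep],
            psa_small.qaly_control[keep], psa_small.qaly_intervention[keep],
            seed=0,
        )
        curve = ceac(sub)
        assert np.all(np.diff(curve["probability"]) >= 0)

    def test_default_grid_and_empty_grid(self, psa_small):
        assert len(ceac(psa_small)) == 101
        with pytest.raises(ValueError):
            ceac(psa_small, [])

    def test_degenerate_psa_probability_one(self, fixed_registry, life_table, utility_table):
        psa = run_psa(fixed_registry, life_table, utility_table, n_iter=3, seed=0)
        assert psa.summary().inmb > 0
        assert psa.prob_cost_effective() == 1.0


@pytest.fixture(scope="module")
def entries(registry, life_table, utility_table):
    return tornado(registry, life_table, utility_table)


@pytest.fixture(scope="module")
def sweep(registry, life_table, utility_table):
    return horizon_sweep(registry, life_table, utility_table, years=range(1, 11))


class TestTornado:
    def test_sorted_by_decreasing_width(self, entries):
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_icer_increases_with_intervention_cost(self, entries):
        e = next(e for e in entries if e.parameter == "c_exercise")
        assert e.icer_high > e.icer_low

    def test_parameters_without_ci_skipped_with_notice(
        self, registry, life_table, utility_table, caplog
    ):
        with caplog.at_level(logging.INFO, logger="excea.analyses"):
            entries = tornado(registry, life_table, utility_table)
        varied = {e.parameter for e in entries}
        assert "share_stroke" not in varied
        assert any("share_stroke" in r.message for r in caplog.records)

    def test_degenerate_ci_gives_zero_width(self, life_table, utility_table, registry):
        reg = ParameterRegistry()
        for s in registry.specs:
            if s.name == "c_exercise":
                reg.add(ParameterSpec(s.name, "gamma", s.mean, s.mean, s.mean,
                                      units=s.units))
            else:
                reg.add(s)
        entries = tornado(reg, life_table, utility_table)
        e = next(e for e in entries if e.parameter == "c_exercise")
        assert e.width == pytest.approx(0.0, abs=1e-9)


class TestHorizonSweepAndScenario:
    def test_year_one_not_cost_effective(self, sweep):
        r = sweep.results[1]
        assert r.icer > sweep.wtp

    def test_icer_non_increasing_in_horizon(self, sweep):
        # once dominant the ICER goes negative; the trend must never reverse
        icers = [sweep.results[y].icer for y in range(1, 11)]
        assert np.all(np.diff(icers) < 0)

    def test_dominance_implies_positive_inmb(self, sweep):
        for r in sweep.results.values():
            if r.dominant:
                assert r.inmb > 0

    def test_break_even_flags_consistent(self, sweep):
        fce = sweep.first_cost_effective_year
        fd = sweep.first_dominant_year
        assert fce is not None and fd is not None and fce <= fd
        assert sweep.results[fd].dominant

    def test_invalid_horizon_rejected(self, registry, life_table, utility_table):
        with pytest.raises(ValueError):
            horizon_sweep(registry, life_table, utility_table, years=[0])

    def test_scenario_is_pure_first_cycle_cost_shift(
        self, registry, life_table, utility_table
    ):
        base = base_case(registry, life_table, utility_table)
        scen = extended_supervision_scenario(registry, life_table, utility_table)
        assert EXTENDED_SUPERVISION_COST == 36 * 75
        assert scen.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-12)
        # add-on lands in the first cycle: discounted once, half-cycle weighted
        draw = registry.point_estimates()
        _, tr = excea.run_arm(draw, excea.EXERCISE, 5, life_table, utility_table,
                              return_trace=True)
        w = 0.5 * (1.0 + tr.occupancy[1, excea.HealthState.NO_CVD])
        assert scen.delta_cost - base.delta_cost == pytest.approx(
            EXTENDED_SUPERVISION_COST * w / 1.05, abs=1e-6
        )
        assert scen.icer > base.icer
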