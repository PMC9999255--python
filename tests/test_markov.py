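import numpy as np
import pytest
from hypothesis import given, strategies as st

import drscreen as d
from drscreen.markov import HealthState, N_STATES
from drscreen.synthetic import generate_scenario

from conftest import make_config


class TestMortalityOddsAdjustment:
    def test_identity_odds_ratio(self):
        assert d.apply_mortality_or(0.02, 1.0) == pytest.approx(0.02, abs=1e-15)

    def test_odds_tripled(self):
        # p=0.5 has odds 1; OR 3 gives odds 3, i.e. probability 3/4
        assert d.apply_mortality_or(0.5, 3.0) == pytest.approx(0.75, abs=1e-15)

    def test_matches_direct_odds_arithmetic(self):
        o = 0.02 / 0.98 * 2.5
        assert d.apply_mortality_or(0.02, 2.5) == pytest.approx(
            o / (1 + o), abs=1e-15)

    def test_degenerate_certain_death(self):
        with pytest.warns(UserWarning):
            assert d.apply_mortality_or(1.0, 2.0) == 1.0

    @given(p=st.floats(0.0, 0.99), odds_ratio=st.floats(0.1, 10.0))
    def test_stays_in_unit_interval_and_monotone(self, p, odds_ratio):
        q = d.apply_mortality_or(p, odds_ratio)
        assert 0.0 <= q < 1.0
        if odds_ratio >= 1.0:
            assert q >= p - 1e-15
        else:
            assert q <= p + 1e-15


class TestTransitionMatrix:
    def test_identity_when_no_events(self, quiet_config):
        params, _ = d.load_parameters(quiet_config)
        M = d.build_transition_matrix(params, 70)
        assert np.allclose(M, np.eye(N_STATES))

    def test_row_stochastic_on_random_scenarios(self):
        for seed in range(100):
            sc = generate_scenario(seed)
            for age in (65, 80, 94, 120):
                M = d.build_transition_matrix(sc.params, age)
                assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
                assert M.min() >= 0.0

    def test_no_transition_to_less_severe_state(self, default_model):
        params, _ = default_model
        M = d.build_transition_matrix(params, 70)
        severity = [0, 1, 2, 2, 2, 2, 3, 4]  # treated == same severity tier
        for i in range(N_STATES):
            for j in range(N_STATES):
                if severity[j] < severity[i]:
                    assert M[i, j] == 0.0

    def test_treatment_multiplier_one_equalises_progression(self):
        cfg = make_config({"rx_progression_multiplier": 1.0})
        params, _ = d.load_parameters(cfg)
        M = d.build_transition_matrix(params, 70)
        assert M[HealthState.STDR_TREATED, HealthState.BLIND] == pytest.approx(
            M[HealthState.STDR_UNDETECTED, HealthState.BLIND])
        assert M[HealthState.DME_TREATED, HealthState.BLIND] == pytest.approx(
            M[HealthState.DME_UNDETECTED, HealthState.BLIND])

    def test_overfull_row_is_configuration_error(self):
        cfg = make_config({"p_non_stdr_to_stdr": 0.6, "p_non_stdr_to_dme": 0.45})
        with pytest.raises(d.ValidationError):
            d.load_parameters(cfg)


class TestScreeningUpdate:
    def _vec(self, **mass):
        v = np.zeros(N_STATES)
        for name, m in mass.items():
            v[HealthState[name.upper()]] = m
        return v

    def test_perfect_program_detects_everything(self, default_model):
        _, strategies = default_model
        perfect = d.StrategyConfig("perfect", 1.0, 1.0, 1.0, 1.0, 10.0)
        occ = self._vec(no_dr=0.5, stdr_undetected=0.3, dme_undetected=0.2)
        out, tallies = d.screening_update(occ, perfect)
        assert out[HealthState.STDR_UNDETECTED] == 0.0
        assert out[HealthState.STDR_TREATED] == pytest.approx(0.3)
        assert out[HealthState.DME_TREATED] == pytest.approx(0.2)
        assert tallies.false_positives == 0.0

    def test_zero_sensitivity_changes_nothing_but_fp_remain(self):
        blunt = d.StrategyConfig("blunt", 0.0, 0.9, 1.0, 1.0, 10.0)
        occ = self._vec(no_dr=0.6, non_stdr=0.2, stdr_undetected=0.2)
        out, tallies = d.screening_update(occ, blunt)
        assert np.allclose(out, occ)
        assert tallies.false_positives == pytest.approx(0.8 * 0.1)

    def test_ai_arm_hand_arithmetic(self, default_model):
        _, strategies = default_model
        occ = self._vec(no_dr=0.9, stdr_undetected=0.10)
        out, tallies = d.screening_update(occ, strategies["ai"])
        moved = 0.10 * 0.8047 * 0.504
        assert tallies.treatments_started_stdr == pytest.approx(moved)
        assert out[HealthState.STDR_TREATED] == pytest.approx(moved)
        assert out[HealthState.STDR_UNDETECTED] == pytest.approx(0.10 - moved)

    def test_mass_is_conserved(self, default_model):
        _, strategies = default_model
        occ = self._vec(no_dr=0.3, non_stdr=0.3, stdr_undetected=0.2,
                        dme_undetected=0.1, blind=0.05, dead=0.05)
        out, _ = d.screening_update(occ, strategies["ai"])
        assert out.sum() == pytest.approx(occ.sum(), abs=1e-15)


class TestDiscount:
    @pytest.mark.parametrize("value,rate,cycle,expected", [
        (100.0, 0.035, 0, 100.0),
        (100.0, 0.0, 30, 100.0),
        (100.0, 0.035, 2, 100.0 / 1.035 ** 2),
    ])
    def test_values(self, value, rate, cycle, expected):
        assert d.discount(value, rate, cycle) == pytest.approx(expected, rel=1e-12)


class TestRunCohort:
    def test_occupancy_rows_sum_to_one(self, base_result):
        _, traces = base_result
        for trace in traces.values():
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)

    def test_dead_occupancy_nondecreasing(self, base_result):
        _, traces = base_result
        for trace in traces.values():
            dead = trace.occupancy[:, HealthState.DEAD]
            assert np.all(np.diff(dead) >= -1e-12)
            assert dead[-1] > dead[1]

    def test_annuity_limit(self, quiet_config):
        params, strategies = d.load_parameters(quiet_config)
        trace = d.run_cohort(params, strategies["manual"])
        annuity = 0.8 * sum(1.035 ** -k for k in range(30))
        assert trace.discounted_qaly == pytest.approx(annuity, abs=1e-10)

    def test_years_without_blindness_when_nobody_dies(self, quiet_config):
        quiet_config["settings"]["discount_rate"] = 0.0
        params, strategies = d.load_parameters(quiet_config)
        trace = d.run_cohort(params, strategies["ai"])
        assert trace.years_without_blindness == pytest.approx(30.0, abs=1e-10)

    def test_deterministic_for_fixed_inputs(self, default_model):
        params, strategies = default_model
        a = d.run_cohort(params, strategies["ai"])
        b = d.run_cohort(params, strategies["ai"])
        assert a.discounted_cost == b.discounted_cost
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_raising_progression_does_not_raise_qalys(self):
        base, _ = d.base_case()
        for knob in ("p_non_stdr_to_stdr", "p_stdr_to_blind",
                     "p_no_dr_to_non_stdr"):
            res, _ = d.base_case(overrides={knob: min(
                1.0, d.load_parameters()[0].values[knob] * 1.5)})
            assert res.baseline.qaly <= base.baseline.qaly + 1e-12
            assert res.comparator.qaly <= base.comparator.qaly + 1e-12

    def test_raising_any_cost_does_not_lower_total_cost(self):
        base, _ = d.base_case()
        values = d.load_parameters()[0].values
        for knob in ("cost_screening_ai", "cost_blind_followup_indirect",
                     "cost_tx_followup_dme", "cost_referral_exam"):
            res, _ = d.base_case(overrides={knob: values[knob] * 1.5})
            assert res.comparator.cost >= base.comparator.cost - 1e-9
            assert res.baseline.cost >= base.baseline.cost - 1e-9

    def test_half_cycle_correction_averages_accruals(self, quiet_config):
        quiet_config["settings"]["half_cycle"] = True
        params, strategies = d.load_parameters(quiet_config)
        trace = d.run_cohort(params, strategies["manual"])
        # no events: start and end occupancy identical, so accruals match
        annuity = 0.8 * sum(1.035 ** -k for k in range(30))
        assert trace.discounted_qaly == pytest.approx(annuity, abs=1e-10)

    def test_trace_exports_are_tidy(self, base_result):
        _, traces = base_result
        occ = traces["ai"].occupancy_frame()
        assert set(occ.columns) == {"cycle", "state", "occupancy"}
        assert len(occ) == 31 * N_STATES
        tal = traces["ai"].tally_frame()
        assert len(tal) == 30
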