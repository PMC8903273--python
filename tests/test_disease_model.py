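"""Unit and property tests of the EDSS progression engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spmscea import (
    ArmSpec,
    InvalidMatrixError,
    InvalidParameterError,
    MortalityModel,
    TransitionMatrix,
    adjust_progression,
    build_cycle_operator,
    combined_death_probability,
    expected_relapses,
    run_cohort,
)
from spmscea.disease_model import DEAD, N_EDSS, N_STATES, OFF, ON, CohortState
from spmscea.exceptions import ConfigError

from conftest import mass_is_conserved


def simple_matrix(progress=0.2, improve=0.0):
    """Tridiagonal test matrix with uniform move probabilities."""
    p = np.zeros((N_EDSS, N_EDSS))
    for i in range(N_EDSS):
        up = progress if i + 1 < N_EDSS else 0.0
        down = improve if i - 1 >= 0 else 0.0
        p[i, i] = 1.0 - up - down
        if up:
            p[i, i + 1] = up
        if down:
            p[i, i - 1] = down
    return TransitionMatrix(p)


def flat_mortality(q=0.0, multipliers=None):
    if multipliers is None:
        multipliers = np.ones(N_EDSS)
    ages = np.arange(0, 121, dtype=float)
    return MortalityModel(
        ages=ages,
        q_male=np.full_like(ages, q),
        q_female=np.full_like(ages, q),
        edss_multipliers=multipliers,
    )


def neutral_arm(stop_edss=10, disc=0.0):
    return ArmSpec(
        name="neutral",
        hr_cdp6=1.0,
        rr_arr=1.0,
        baseline_discontinuation=disc,
        stop_edss=stop_edss,
    )


@st.composite
def random_matrices(draw):
    """Band-dominant matrices from the synthetic generator's family."""
    from spmscea import SyntheticConfig, gen_transition_matrix

    progression = draw(st.floats(0.05, 0.4))
    cfg = SyntheticConfig(
        seed=draw(st.integers(0, 2**31 - 1)),
        progression_intensity=progression,
        improvement_intensity=progression * draw(st.floats(0.0, 0.4)),
        progression_gradient=draw(st.floats(0.85, 1.0)),
    )
    return gen_transition_matrix(cfg)


class TestAdjustProgression:
    def test_unit_hazard_ratio_is_identity(self):
        m = simple_matrix(0.25, 0.05)
        adjusted = adjust_progression(m, 1.0)
        assert np.array_equal(adjusted.probs, m.probs)

    def test_rate_scale_closed_form(self):
        m = simple_matrix(progress=0.2)
        adjusted = adjust_progression(m, 0.5)
        expected = 1.0 - 0.8**0.5  # 0.10557...
        assert adjusted.probs[0, 1] == pytest.approx(expected, rel=1e-12)
        assert adjusted.probs[0, 0] == pytest.approx(1.0 - expected, rel=1e-12)

    def test_vanishing_hazard_removes_progression(self):
        m = simple_matrix(progress=0.3, improve=0.05)
        adjusted = adjust_progression(m, 1e-14)
        upper = np.triu(adjusted.probs, k=1)
        assert np.all(upper < 1e-12)
        # improvement untouched
        assert np.array_equal(np.tril(adjusted.probs, -1), np.tril(m.probs, -1))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            adjust_progression(simple_matrix(), 0.0)
        with pytest.raises(InvalidMatrixError):
            TransitionMatrix(np.full((N_EDSS, N_EDSS), 0.2))

    @settings(max_examples=50, derandomize=True)
    @given(random_matrices(), st.floats(0.05, 3.0))
    def test_row_stochastic_and_monotone(self, matrix, hr):
        adjusted = adjust_progression(matrix, hr)
        assert np.allclose(adjusted.probs.sum(axis=1), 1.0, atol=1e-12)
        for i in range(N_EDSS):
            before = matrix.probs[i, i + 1 :].sum()
            after = adjusted.probs[i, i + 1 :].sum()
            if hr < 1.0:
                assert after <= before + 1e-12
            else:
                assert after >= before - 1e-12
        # improvement probabilities never touched
        assert np.array_equal(
            np.tril(adjusted.probs, -1), np.tril(matrix.probs, -1)
        )


class TestMortality:
    def test_multiplier_one_returns_background(self):
        mm = flat_mortality(q=0.013)
        got = combined_death_probability(50.0, 0.4, 0, mm)
        assert got == pytest.approx(0.013, rel=1e-12)

    def test_rate_scale_multiplier(self):
        mult = np.ones(N_EDSS)
        mult[6:] = 2.27
        mm = flat_mortality(q=0.01, multipliers=mult)
        got = combined_death_probability(50.0, 0.0, 6, mm)
        assert got == pytest.approx(1.0 - 0.99**2.27, rel=1e-12)  # 0.022556

    def test_certain_death_capped_at_one(self):
        mult = np.ones(N_EDSS)
        mult[9] = 6.45
        mm = flat_mortality(q=1.0, multipliers=mult)
        assert combined_death_probability(50.0, 0.5, 9, mm) == 1.0

    def test_age_outside_table_raises(self, params):
        from spmscea.exceptions import OutOfRangeError

        with pytest.raises(OutOfRangeError):
            combined_death_probability(140.0, 0.4, 3, params.mortality)

    def test_sex_mix_weighting(self):
        ages = np.arange(0, 121, dtype=float)
        mm = MortalityModel(
            ages=ages,
            q_male=np.full_like(ages, 0.02),
            q_female=np.full_like(ages, 0.01),
            edss_multipliers=np.ones(N_EDSS),
        )
        assert mm.background_probability(50.0, 0.399) == pytest.approx(
            0.399 * 0.02 + 0.601 * 0.01, rel=1e-12
        )


class TestCycleOperator:
    def test_neutral_arm_is_natural_history_bordered_by_mortality(self, params):
        natural = params.natural_matrix
        mm = flat_mortality(q=0.01)
        op = build_cycle_operator(neutral_arm(), natural, mm, 50.0, 0.4)
        surv = 1.0 - mm.death_probabilities(50.0, 0.4)
        # hr = 1, rr = 1, no stopping: both branches reproduce natural history
        assert np.array_equal(op[ON, ON], surv[:, None] * natural.probs)
        assert np.array_equal(op[OFF, OFF], surv[:, None] * natural.probs)
        assert np.all(op[ON, OFF] == 0.0)
        assert np.allclose(op[:DEAD, DEAD], 0.01, atol=1e-15)

    def test_certain_discontinuation_empties_on_branch(self, params):
        arm = ArmSpec(
            name="x", hr_cdp6=0.5, rr_arr=0.5,
            baseline_discontinuation=0.999999999, stop_edss=7,
        )
        # effectively certain stopping: on-branch destinations carry ~0 mass
        op = build_cycle_operator(arm, params.natural_matrix, flat_mortality(), 50.0, 0.4)
        assert np.all(op[ON, ON] < 1e-8)

    def test_stop_rule_moves_high_edss_off_treatment(self, params):
        arm = ArmSpec(name="x", hr_cdp6=0.5, rr_arr=0.5,
                      baseline_discontinuation=0.0, stop_edss=7)
        op = build_cycle_operator(arm, params.natural_matrix, flat_mortality(), 50.0, 0.4)
        # no on-treatment destination at or above the stop level
        assert np.all(op[ON, ON][:, 7:] == 0.0)
        # on-treatment rows at/above stop discontinue with certainty
        assert np.all(op[7:10, 0:N_EDSS] == 0.0)

    @pytest.mark.parametrize("age", [48.0, 60.0, 85.0])
    def test_rows_sum_to_one(self, params, age):
        arm = params.intervention.arm
        op = build_cycle_operator(arm, params.natural_matrix, params.mortality,
                                  age, params.male_fraction)
        assert np.allclose(op.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(op >= 0.0)


class TestRunCohort:
    def test_one_cycle_trace_has_two_states(self, params):
        trace = run_cohort(params.intervention.arm, params, horizon=1)
        assert len(trace) == 2
        assert trace.state(0).cycle == 0 and trace.state(1).cycle == 1

    def test_zero_horizon_rejected(self, params):
        with pytest.raises(ConfigError):
            run_cohort(params.intervention.arm, params, horizon=0)

    def test_identity_dynamics_are_a_fixed_point(self, params):
        import dataclasses

        frozen = dataclasses.replace(
            params,
            natural_matrix=TransitionMatrix(np.eye(N_EDSS)),
            mortality=flat_mortality(q=0.0),
        )
        arm = neutral_arm()
        trace = run_cohort(arm, frozen, horizon=5)
        for t in range(len(trace)):
            assert np.allclose(trace.occupancy[t], trace.occupancy[0], atol=1e-15)

    def test_baseline_on_treatment_and_mass_conserved(self, params):
        trace = run_cohort(params.intervention.arm, params, horizon=30)
        assert np.allclose(trace.occupancy[0][ON], params.baseline_distribution)
        assert trace.occupancy[0][OFF].sum() == 0.0
        assert mass_is_conserved(trace)
        dead = trace.occupancy[:, DEAD]
        assert np.all(np.diff(dead) >= -1e-15)

    def test_bad_baseline_rejected(self, params):
        import dataclasses

        bad = dataclasses.replace(
            params, baseline_distribution=params.baseline_distribution * 0.5
        )
        with pytest.raises(ConfigError):
            run_cohort(params.intervention.arm, bad, horizon=2)

    def test_stronger_efficacy_lowers_edss_and_extends_life(self, params):
        import dataclasses

        arms = {
            hr: dataclasses.replace(params.intervention.arm, hr_cdp6=hr)
            for hr in (0.5, 0.93)
        }
        traces = {hr: run_cohort(arm, params) for hr, arm in arms.items()}
        n = min(len(t) for t in traces.values())
        for t in range(1, n):
            strong = traces[0.5].state(t)
            weak = traces[0.93].state(t)
            if strong.live_mass > 1e-9 and weak.live_mass > 1e-9:
                assert strong.mean_edss() <= weak.mean_edss() + 1e-12
        ly = {hr: tr.occupancy[:, :DEAD].sum() for hr, tr in traces.items()}
        assert ly[0.5] >= ly[0.93]


class TestExpectedRelapses:
    def base_state(self, occupancy):
        return CohortState(occupancy=occupancy, age=48.0, cycle=0)

    def test_single_state_matches_input_probability(self, params):
        occ = np.zeros(N_STATES)
        occ[3] = 1.0  # EDSS 3 on treatment
        got = expected_relapses(self.base_state(occ), params.relapse_probs, 1.0)
        assert got == pytest.approx(0.161, rel=1e-12)

    def test_zero_relative_risk_suppresses_treated_relapses(self, params):
        occ = np.zeros(N_STATES)
        occ[3] = 1.0
        assert expected_relapses(self.base_state(occ), params.relapse_probs, 0.0) == 0.0

    def test_mixed_occupancy_hand_value(self, params):
        occ = np.zeros(N_STATES)
        occ[3] = 0.5  # EDSS 3 on treatment
        occ[N_EDSS + 6] = 0.5  # EDSS 6 off treatment
        got = expected_relapses(self.base_state(occ), params.relapse_probs, 0.59)
        assert got == pytest.approx(0.5 * 0.161 * 0.59 + 0.5 * 0.126, rel=1e-12)
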