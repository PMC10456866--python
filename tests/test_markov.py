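import numpy as np
import pytest

from pahcea import (ArmTransitions, CohortSpec, EconSettings, LifeTable,
                    build_transition_matrix, estimate_transition_probs,
                    run_cohort)
from pahcea.states import HealthState


def oracle_matrix(arm, first_cycle, d):
    """Independent assembly: enumerate each state's allowed destinations and
    let 'stay' absorb the remainder of the row."""
    p21 = arm.p_improve_2to1 if first_cycle else 0.0
    p32 = arm.p_improve_3to2 if first_cycle else 0.0
    moves = {
        0: {1: arm.p_worsen},
        1: {0: p21, 2: arm.p_worsen},
        2: {1: p32, 3: arm.p_worsen},
        3: {},
    }
    m = np.zeros((5, 5))
    m[4, 4] = 1.0
    for i, dests in moves.items():
        m[i, 4] = d[i]
        row_rest = 0.0
        for j, p in dests.items():
            m[i, j] = (1.0 - d[i]) * p
            row_rest += m[i, j]
        m[i, i] = 1.0 - d[i] - row_rest
    return m


class TestEstimation:
    @pytest.mark.parametrize("k,n,expected", [
        (3, 23, 0.130),    # dual FC II -> I
        (55, 95, 0.579),   # dual FC III -> II
        (51, 98, 0.520),   # triple FC III -> II
        (3, 124, 0.024),   # dual pooled worsening
        (1, 123, 0.008),   # triple pooled worsening
    ])
    def test_trial_counts_reproduce_published_probabilities(self, k, n,
                                                            expected):
        arm = estimate_transition_probs(k, n, 0, 1, 0, 1)
        assert round(arm.p_improve_2to1, 3) == expected

    def test_zero_count_gives_zero_probability(self):
        arm = estimate_transition_probs(0, 100, 0, 100, 0, 200)
        assert arm.p_improve_2to1 == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition_probs(1, 0, 0, 1, 0, 1)
        with pytest.raises(ValueError):
            estimate_transition_probs(5, 3, 0, 1, 0, 1)

    def test_arm_transitions_rejects_excess_mass(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            ArmTransitions(0.9, 0.1, 0.2)


class TestMatrixAssembly:
    def test_matches_enumeration_oracle_on_randomized_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pw = rng.uniform(0, 0.3)
            arm = ArmTransitions(rng.uniform(0, 1 - pw),
                                 rng.uniform(0, 1 - pw), pw)
            d = rng.uniform(0, 1, size=4)
            first = bool(rng.integers(0, 2))
            m = build_transition_matrix(arm, first, d)
            np.testing.assert_allclose(m, oracle_matrix(arm, first, d),
                                       atol=1e-12)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_subsequent_cycles_have_no_improvement(self):
        arm = ArmTransitions(0.26, 0.52, 0.008)
        m = build_transition_matrix(arm, first_cycle=False,
                                    death_probs=[0.01] * 4)
        assert m[1, 0] == 0.0  # FC2 -> FC1
        assert m[2, 1] == 0.0  # FC3 -> FC2

    def test_certain_death_is_absorbing_limit(self):
        arm = ArmTransitions(0.1, 0.2, 0.02)
        m = build_transition_matrix(arm, True, [1.0] * 4)
        for i in range(4):
            np.testing.assert_array_equal(m[i], [0, 0, 0, 0, 1])

    def test_first_cycle_fc3_row_hand_assembly(self):
        arm = ArmTransitions(0.0, 0.579, 0.024)
        m = build_transition_matrix(arm, True, [0.0, 0.0, 0.02, 0.0])
        expected = [0.0, 0.98 * 0.579, 0.98 * (1 - 0.579 - 0.024),
                    0.98 * 0.024, 0.02]
        np.testing.assert_allclose(m[2], expected, atol=1e-12)

    def test_invalid_death_probs_rejected(self):
        arm = ArmTransitions(0.1, 0.1, 0.01)
        with pytest.raises(ValueError):
            build_transition_matrix(arm, True, [0.5, 0.5, 1.5, 0.5])


@pytest.fixture(scope="module")
def zero_mortality_table():
    ages = np.arange(0, 106)
    return LifeTable(ages, np.zeros(106), np.zeros(106))


class TestCohortTrace:
    def test_identity_dynamics_keep_occupancy_constant(self,
                                                       zero_mortality_table):
        arm = ArmTransitions(0.0, 0.0, 0.0)
        trace = run_cohort(CohortSpec(), arm, zero_mortality_table,
                           (1, 1, 1, 1), EconSettings())
        for row in trace.occupancy:
            np.testing.assert_allclose(row, [0, 0.5, 0.5, 0, 0], atol=1e-14)

    def test_mass_conserved_on_randomized_inputs(self, life_table):
        rng = np.random.default_rng(3)
        settings = EconSettings()
        for _ in range(20):
            pw = rng.uniform(0, 0.2)
            arm = ArmTransitions(rng.uniform(0, 0.5), rng.uniform(0, 0.5), pw)
            hrs = tuple(np.sort(rng.uniform(1, 100, size=4)))
            trace = run_cohort(CohortSpec(), arm, life_table, hrs, settings)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-10)
            death = trace.occupancy[:, HealthState.DEATH]
            assert np.all(np.diff(death) >= -1e-12)

    def test_everyone_dies_eventually(self, life_table, params):
        """With strictly positive death probabilities the death state
        absorbs the whole cohort (checked at 600 cycles)."""
        arm = ArmTransitions(0.130, 0.579, 0.024)
        hrs = (params.hr_fc1.base, params.hr_fc2.base, params.hr_fc3.base,
               params.hr_fc4.base)
        long_run = EconSettings(horizon_years=300.0)
        trace = run_cohort(CohortSpec(), arm, life_table, hrs, long_run)
        assert trace.n_cycles == 600
        assert trace.occupancy[-1, HealthState.DEATH] > 0.9999

    def test_worsening_only_dynamics_deplete_mild_states(self, life_table):
        arm = ArmTransitions(0.0, 0.0, 0.05)
        trace = run_cohort(CohortSpec(), arm, life_table, (5, 22, 39, 57),
                           EconSettings())
        mild = trace.occupancy[1:, 0] + trace.occupancy[1:, 1]
        assert np.all(np.diff(mild) <= 1e-14)

    def test_trace_frame_layout(self, fitted):
        df = fitted.traces["dual"].to_frame()
        assert list(df.columns) == ["cycle", "age", "FC1", "FC2", "FC3",
                                    "FC4", "DEATH"]
        assert df["age"].iloc[0] == 36.0
        assert df["age"].iloc[2] == 37.0
        assert len(df) == 61
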