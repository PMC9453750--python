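"""Behavioral statistics and on-/off-policy simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fediowa.behavior_analysis import (
    block_learning_scores,
    deck_proportions,
    group_mean_diff,
    mixed_anova,
    simulate_off_policy,
    simulate_on_policy,
    switch_probability,
)
from fediowa.gru_choice_model import init_params
from fediowa.igt_task import build_scheme
from conftest import make_record


@pytest.fixture(scope="module")
def scheme():
    return build_scheme("traditional")


class TestDeckProportions:
    def test_alternating_subject(self):
        props, _, _ = deck_proportions([make_record(choices=[1, 2] * 5)])
        np.testing.assert_allclose(props[0], [0.5, 0.5, 0, 0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = [make_record(f"s{i}", 1, rng.integers(1, 5, 30)) for i in range(8)]
        props, mean, se = deck_proportions(seqs)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)
        np.testing.assert_allclose(mean.sum(), 1.0)

    def test_group_mean_arithmetic(self):
        seqs = [
            make_record("a", 1, [1] * 4),
            make_record("b", 1, [2] * 4),
            make_record("c", 1, [3] * 4),
        ]
        _, mean, _ = deck_proportions(seqs)
        np.testing.assert_allclose(mean, [1 / 3, 1 / 3, 1 / 3, 0])


class TestLearningScores:
    def test_all_good_deck_saturates(self):
        scores = block_learning_scores([make_record(choices=[3] * 95)])
        np.testing.assert_array_equal(scores[0], [10] * 9 + [5])

    def test_all_bad_deck_saturates_negative(self):
        scores = block_learning_scores([make_record(choices=[1] * 95)])
        np.testing.assert_array_equal(scores[0], [-10] * 9 + [-5])

    def test_mixed_block_counting(self):
        choices = [3] * 6 + [1] * 4 + [3] * 85  # block 1: 6 good, 4 bad
        scores = block_learning_scores([make_record(choices=choices)])
        assert scores[0, 0] == 2

    def test_blocking_of_95_trials_is_ten_blocks(self):
        scores = block_learning_scores([make_record(choices=[1] * 95)])
        assert scores.shape == (1, 10)

    def test_nonstandard_length_warns(self):
        with pytest.warns(UserWarning):
            scores = block_learning_scores([make_record(choices=[1] * 47)])
        assert scores.shape == (1, 5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=95, max_size=95))
    def test_sum_identity(self, choices):
        # sum of block scores = 95 - 2 * (# bad-deck choices)
        scores = block_learning_scores([make_record(choices=choices)])
        n_bad = sum(c in (1, 2) for c in choices)
        assert scores.sum() == 95 - 2 * n_bad


class TestSwitchProbability:
    def test_always_switcher(self):
        sw = switch_probability([make_record(choices=[1, 2, 3, 4], losses=[0, 250, 0, 0])])
        np.testing.assert_allclose(sw[0], [1.0, 1.0])

    def test_never_switcher(self):
        sw = switch_probability([make_record(choices=[2] * 5, losses=[0, 250, 0, 250, 0])])
        np.testing.assert_allclose(sw[0], [0.0, 0.0])

    def test_hand_counted_case(self):
        sw = switch_probability([make_record(choices=(1, 1, 2), losses=(0, 250, 0))])
        np.testing.assert_allclose(sw[0], [1.0, 0.0])

    def test_empty_condition_is_nan(self):
        sw = switch_probability([make_record(choices=(1, 2, 1), losses=(0, 0, 0))])
        assert np.isnan(sw[0, 0]) and sw[0, 1] == 1.0


class TestGroupMeanDiff:
    def test_identical_groups(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        r = group_mean_diff(a, a)
        assert r.eta == 0.0 and r.p == pytest.approx(1.0)

    def test_paired_shift_is_exact(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        r = group_mean_diff(a, a + 0.5, paired=True)
        assert r.eta == pytest.approx(-0.5)
        assert r.se == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_shift_recovery(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        r = group_mean_diff(a, b)
        assert abs(r.eta - 1.0) < 3 * r.se
        assert r.p < 0.001


class TestMixedAnova:
    def test_two_level_within_has_unit_epsilon(self):
        rng = np.random.default_rng(0)
        r = mixed_anova(rng.normal(0, 1, (12, 2)), rng.normal(0, 1, (12, 2)))
        assert r.epsilon == 1.0

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(1)
        r = mixed_anova(rng.normal(0, 1, (20, 10)), rng.normal(0, 1, (20, 10)))
        assert 1 / 9 <= r.epsilon <= 1.0

    def test_null_population_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, (15, 10))
            b = rng.normal(0, 1, (15, 10))
            if mixed_anova(a, b).p_interaction > 0.05:
                hits += 1
        assert hits >= 90

    def test_constructed_interaction_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (50, 10))
        b = rng.normal(0, 1, (50, 10))
        b[:, 5:] += 2.0
        r = mixed_anova(a, b)
        assert r.p_interaction < 0.01

    def test_group_f_matches_t_squared_on_subject_means(self):
        # independent cross-check: with a 2-group between factor, the
        # between-subjects F(1, N-2) equals the squared pooled-variance t
        # statistic computed on per-subject mean scores
        from scipy import stats

        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (10, 4))
        b = rng.normal(0.8, 1, (12, 4))
        r = mixed_anova(a, b)
        t, p = stats.ttest_ind(a.mean(axis=1), b.mean(axis=1), equal_var=True)
        assert r.F_group == pytest.approx(t**2, rel=1e-6)
        assert r.p_group == pytest.approx(p, rel=1e-6)
        assert r.df_group == (1.0, 20.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova(np.zeros((1, 10)), np.zeros((5, 10)))


class TestOnPolicy:
    def test_uniform_model_plays_uniformly(self, scheme):
        p = init_params(4, seed=0)
        p.V[...] = 0.0
        agents = simulate_on_policy(p, scheme, n_agents=50, T=95, seed=0)
        props, mean, _ = deck_proportions(agents)
        se3 = 3 * np.sqrt(0.25 * 0.75 / (50 * 95))
        assert np.all(np.abs(mean - 0.25) < se3)

    def test_fixed_seed_reproduces_agent_pool(self, scheme):
        p = init_params(4, seed=1)
        a = simulate_on_policy(p, scheme, n_agents=5, T=20, seed=3)
        b = simulate_on_policy(p, scheme, n_agents=5, T=20, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.choices, y.choices)

    def test_payoffs_follow_scheme(self, scheme):
        p = init_params(4, seed=2)
        (agent,) = simulate_on_policy(p, scheme, n_agents=1, T=30, seed=5)
        # replay: per-deck draw counters must reproduce the recorded payoffs
        draws = [0] * 4
        for t in range(30):
            d = agent.choices[t]
            from fediowa.igt_task import payoff

            r, l = payoff(scheme, d, draws[d - 1])
            draws[d - 1] += 1
            assert agent.rewards[t] == r and agent.losses[t] == l


class TestOffPolicy:
    def test_uniform_model_traces_constant_quarter(self, scheme):
        p = init_params(4, seed=0)
        p.V[...] = 0.0
        trace = simulate_off_policy(p, 2, T=30, scheme=scheme)
        np.testing.assert_allclose(trace["p_stay"], 0.25, atol=1e-12)

    def test_loss_markers_match_schedule(self, scheme):
        p = init_params(4, seed=1)
        trace = simulate_off_policy(p, 4, T=30, scheme=scheme)
        assert len(trace) == 30
        expected = [scheme.loss_schedule[3][t % 10] > 0 for t in range(30)]
        assert list(trace["loss_trial"]) == expected

    def test_deterministic(self, scheme):
        p = init_params(4, seed=2)
        a = simulate_off_policy(p, 1, T=30, scheme=scheme)
        b = simulate_off_policy(p, 1, T=30, scheme=scheme)
        assert (a["p_stay"] == b["p_stay"]).all()
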