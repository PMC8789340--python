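import numpy as np
import pytest
from scipy import stats

import hothand as hh
from hothand.shotlog import ConfigurationError, UndefinedStatisticError


def seq(outcomes, game_id="g"):
    return hh.GameSequence(outcomes=np.array(outcomes), game_id=game_id)


class TestEnumerationOracle:
    @pytest.mark.parametrize("n,M,expected", [(4, 2, 1 / 3), (3, 2, 1 / 2), (5, 2, 1 / 4)])
    def test_known_small_cases(self, n, M, expected):
        assert hh.exhaustive_conditional_mean(n, M, k=1) == pytest.approx(expected)

    def test_closed_form_matches_enumeration_everywhere(self):
        for n in range(2, 11):
            for M in range(1, n + 1):
                assert hh.exhaustive_conditional_mean(n, M, 1) == pytest.approx(
                    hh.perm_mean_closed_form_k1(n, M), abs=1e-12
                )

    @pytest.mark.parametrize("k", [1, 2])
    def test_streak_selection_bias_is_non_positive(self, k):
        # the mean conditional statistic never exceeds the success rate M/n
        for n in range(k + 1, 9):
            for M in range(1, n):
                try:
                    mean = hh.exhaustive_conditional_mean(n, M, k)
                except UndefinedStatisticError:
                    continue
                assert mean <= M / n + 1e-12

    def test_all_success_composition(self):
        assert hh.perm_mean_closed_form_k1(2, 2) == 1.0

    def test_zero_successes_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hh.perm_mean_closed_form_k1(5, 0)


class TestPermutationNull:
    def test_degenerate_all_makes(self):
        null = hh.permutation_conditional_distribution([seq([1] * 6)], k=2,
                                                       n_perm=20, seed=1)
        assert null.mean == 1.0
        assert null.empirical_p == 1.0
        assert null.n_undefined == 0

    def test_sampling_converges_to_enumeration_mean(self):
        # single 8-trial game with 4 makes: closed form 3/7
        null = hh.permutation_conditional_distribution(
            [seq([1, 1, 1, 1, 0, 0, 0, 0])], k=1, n_perm=500, seed=7
        )
        se = null.replicate_values.std(ddof=1) / np.sqrt(null.replicate_values.size)
        assert abs(null.mean - 3 / 7) < 3 * se

    def test_within_game_stratification_preserves_composition(self):
        # a game of all makes contributes followers at rate 1 in every replicate
        null = hh.permutation_conditional_distribution(
            [seq([1, 1, 1], "a"), seq([0, 0, 0], "b")], k=1, n_perm=50, seed=3
        )
        assert null.mean == 1.0

    def test_undefined_replicates_are_excluded_and_counted(self):
        # one make in a 3-trial game: permutations placing it last have no follower
        null = hh.permutation_conditional_distribution(
            [seq([1, 0, 0])], k=1, n_perm=200, seed=5
        )
        assert null.n_undefined > 0
        assert null.replicate_values.size == null.n_replicates - null.n_undefined
        assert null.mean == 0.0  # the follower is never a make with a single make

    def test_empirical_p_tail_conventions(self):
        null_ge = hh.permutation_conditional_distribution(
            [seq([1, 1, 0, 1, 1])], k=1, n_perm=100, seed=11, tail="ge"
        )
        null_gt = hh.permutation_conditional_distribution(
            [seq([1, 1, 0, 1, 1])], k=1, n_perm=100, seed=11, tail="gt"
        )
        assert null_ge.empirical_p >= null_gt.empirical_p

    def test_no_followers_in_observed_data_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            hh.permutation_conditional_distribution([seq([0, 0, 0])], k=1)

    def test_empirical_p_uniform_under_the_null(self):
        # iid Bernoulli(0.5) games: the permutation p-value should be ~uniform
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(80):
            games = [seq(rng.integers(0, 2, size=10), game_id=i) for i in range(12)]
            try:
                null = hh.permutation_conditional_distribution(games, 1, n_perm=99,
                                                              seed=int(rng.integers(2**31)))
            except UndefinedStatisticError:
                continue
            pvals.append(null.empirical_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestSelectionBias:
    def test_ten_makes_in_twenty_trials(self):
        assert hh.selection_bias_probability(20, 10) == pytest.approx(9 / 19)

    def test_lone_make_followed_by_miss(self):
        assert hh.selection_bias_probability(2, 1) == 0.0

    def test_enumeration_agrees_with_closed_form(self):
        for n, M in [(6, 3), (5, 2), (7, 7)]:
            assert hh.selection_bias_probability(n, M, "enumerate") == pytest.approx(
                (M - 1) / (n - 1)
            )

    def test_monte_carlo_within_three_standard_errors(self):
        n_mc = 20_000
        est = hh.selection_bias_probability(6, 3, "monte_carlo", n_mc=n_mc, seed=13)
        p = 2 / 5
        n_valid = n_mc * (1 - 1 / 6)  # picks at the last position are discarded
        se = np.sqrt(p * (1 - p) / n_valid)
        assert abs(est - p) < 3 * se

    def test_zero_makes_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hh.selection_bias_probability(5, 0)


class TestSimulationNull:
    def test_mean_matches_poisson_binomial_mean(self):
        probs = np.array([0.2, 0.4, 0.6, 0.8])
        null = hh.simulate_conditional_null(np.tile(probs, 50), n_sim=2000, seed=21)
        se = null.replicate_values.std(ddof=1) / np.sqrt(2000)
        assert abs(null.mean - 0.5) < 3 * se

    def test_constant_probability_reduces_to_binomial(self):
        null = hh.simulate_conditional_null(np.full(100, 0.5), n_sim=4000, seed=22)
        var = null.replicate_values.var(ddof=1)
        assert null.mean == pytest.approx(0.5, abs=0.01)
        assert var == pytest.approx(0.25 / 100, rel=0.15)

    def test_degenerate_high_probabilities(self):
        null = hh.simulate_conditional_null(np.full(50, 0.999), n_sim=200, seed=23)
        assert null.mean > 0.99

    def test_empirical_p_against_observed(self):
        null = hh.simulate_conditional_null(np.full(20, 0.5), n_sim=500, seed=24,
                                            observed=1.0)
        assert null.empirical_p <= 0.01

    def test_rejects_bad_inputs(self):
        with pytest.raises(UndefinedStatisticError):
            hh.simulate_conditional_null(np.array([]))
        with pytest.raises(ValueError):
            hh.simulate_conditional_null(np.array([0.0, 0.5]))


class TestWaldWolfowitz:
    def test_expected_runs_for_balanced_ten_trials(self):
        # E[R] = 2*5*5/10 + 1 = 6: a 5/5 sequence with exactly 6 runs gives z = 0
        z, p = hh.wald_wolfowitz_test(seq([1, 1, 0, 0, 1, 1, 0, 0, 1, 0]))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_alternating_sequence_is_anti_streaky(self):
        z, p = hh.wald_wolfowitz_test(seq([1, 0, 1, 0, 1, 0]))
        assert z > 0 and p > 0.5

    def test_blocked_sequence_is_streaky(self):
        z, p = hh.wald_wolfowitz_test(seq([1, 1, 1, 0, 0, 0]))
        assert z < 0 and p < 0.05

    def test_two_sided_doubles_the_smaller_tail(self):
        z1, p1 = hh.wald_wolfowitz_test(seq([1, 1, 1, 0, 0, 0]))
        z2, p2 = hh.wald_wolfowitz_test(seq([1, 1, 1, 0, 0, 0]), alternative="two-sided")
        assert z2 == z1
        assert p2 == pytest.approx(2 * p1)

    def test_continuity_correction_shrinks_z(self):
        z, _ = hh.wald_wolfowitz_test(seq([1, 1, 1, 0, 0, 0]))
        zc, _ = hh.wald_wolfowitz_test(seq([1, 1, 1, 0, 0, 0]),
                                       continuity_correction=True)
        assert abs(zc) < abs(z)

    def test_single_valued_sequence_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hh.wald_wolfowitz_test(seq([1, 1, 1, 1]))
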