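"""Closed-form decision theory: posteriors, log odds, learning functions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from similearn import bayes_core as bc

# ---------------------------------------------------------------------------
# independent enumeration oracle


def enumerate_social_log_odds(a, i, n, rep):
    """Brute-force log[P(z=1|a,i)/P(z=0|a,i)] by summing the joint
    P(y, z, a, i) over all states, with a flat prior on y."""
    probs = {0: 0.0, 1: 0.0}
    for y, z in itertools.product((0, 1), (0, 1)):
        p_y = 0.5
        p_z = rep.gamma_hat if z != y else 1.0 - rep.gamma_hat
        correct = (a == bc.SAME) == (z == y)
        p_a = rep.phi_hat if correct else 1.0 - rep.phi_hat
        p_demo1 = rep.q_hat if y == 1 else 1.0 - rep.q_hat
        p_i = stats.binom.pmf(i, n, p_demo1)
        probs[z] += p_y * p_z * p_a * p_i
    return float(np.log(probs[1]) - np.log(probs[0]))


rep_strategy = st.builds(
    bc.CognitiveRep,
    q_hat=st.floats(0.51, 0.99),
    gamma_hat=st.floats(0.01, 0.99),
    phi_hat=st.floats(0.01, 0.99),
    sigma_hat=st.floats(0.2, 5.0),
)


class TestDemoCountLikelihood:
    @pytest.mark.parametrize(
        "i, n, q, y, expected",
        [
            (5, 5, 0.75, 1, 0.2373046875),
            (4, 5, 0.75, 1, 0.3955078125),
            (0, 5, 1.0, 1, 0.0),
            (0, 5, 0.75, 0, 0.2373046875),  # relabeled mirror of the first
        ],
    )
    def test_known_values(self, i, n, q, y, expected):
        assert bc.demo_count_likelihood(i, n, q, y) == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one_over_counts(self):
        total = sum(bc.demo_count_likelihood(i, 7, 0.62, 1) for i in range(8))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(i=-1), dict(i=6), dict(q=1.5), dict(y=2)])
    def test_domain_errors(self, bad):
        kwargs = dict(i=2, n_demo=5, q=0.75, y=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            bc.demo_count_likelihood(kwargs["i"], kwargs["n_demo"], kwargs["q"], kwargs["y"])


class TestSimilarityPosterior:
    def test_discordant_signal_exactly_offsets_biased_prior(self):
        # gamma*phi == (1-gamma)*(1-phi): the signal neutralizes the prior
        assert bc.similarity_posterior(0.1, 0.9, bc.DIFFERENT) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "gamma, phi, a, expected",
        [
            (0.1, 0.9, bc.SAME, 0.81 / 0.82),
            (0.3, 0.5, bc.SAME, 0.7),      # uninformative signal returns prior
            (0.3, 0.5, bc.DIFFERENT, 0.7),
            (0.5, 0.7, bc.SAME, 0.7),      # flat prior cancels
            (0.5, 0.7, bc.DIFFERENT, 0.3),
        ],
    )
    def test_closed_forms(self, gamma, phi, a, expected):
        assert bc.similarity_posterior(gamma, phi, a) == pytest.approx(expected)

    def test_degenerate_raises_not_nan(self):
        with pytest.raises(ValueError):
            bc.similarity_posterior(0.0, 1.0, bc.DIFFERENT)

    def test_bad_signal_label(self):
        with pytest.raises(ValueError):
            bc.similarity_posterior(0.1, 0.9, "sideways")


class TestSocialLogOdds:
    def test_concordant_unanimous_example(self, default_rep):
        assert bc.social_log_odds(bc.SAME, 5, 5, default_rep) == pytest.approx(
            4.107, abs=1e-3
        )

    @pytest.mark.parametrize("i", range(6))
    def test_offset_representation_ignores_demonstrators(self, i, default_rep):
        # gamma_hat*phi_hat == (1-gamma_hat)(1-phi_hat): "different" signal
        # makes the demonstrator count uninformative
        assert bc.social_log_odds(bc.DIFFERENT, i, 5, default_rep) == pytest.approx(
            0.0, abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(rep=rep_strategy, i=st.integers(0, 8), a=st.sampled_from([bc.SAME, bc.DIFFERENT]))
    def test_antisymmetry(self, rep, i, a):
        n = 8
        assert bc.social_log_odds(a, n - i, n, rep) == pytest.approx(
            -bc.social_log_odds(a, i, n, rep), abs=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(rep=rep_strategy, i=st.integers(0, 5), a=st.sampled_from([bc.SAME, bc.DIFFERENT]))
    def test_matches_enumeration_oracle(self, rep, i, a):
        expected = enumerate_social_log_odds(a, i, 5, rep)
        assert bc.social_log_odds(a, i, 5, rep) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rep=rep_strategy, i=st.integers(0, 5), a=st.sampled_from([bc.SAME, bc.DIFFERENT]))
    def test_posterior_normalization(self, rep, i, a):
        L = bc.social_log_odds(a, i, 5, rep)
        p1 = 1.0 / (1.0 + np.exp(-L))
        assert p1 + (1.0 - p1) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p1 <= 1.0

    @pytest.mark.parametrize("i", range(6))
    def test_uninformative_signal_collapses_conditions(self, i):
        rep = bc.CognitiveRep(q_hat=0.8, gamma_hat=0.2, phi_hat=0.5, sigma_hat=1.0)
        same = bc.social_log_odds(bc.SAME, i, 5, rep)
        diff = bc.social_log_odds(bc.DIFFERENT, i, 5, rep)
        assert same == pytest.approx(diff, abs=1e-12)


class TestChoose:
    def test_private_signal_decides_when_social_is_neutral(self, default_rep, rng):
        obs = bc.Observation(s=3.0, i=2, n_demo=5, a=bc.DIFFERENT)
        assert bc.choose(obs, default_rep, rng) == 1

    def test_small_private_signal_overridden_by_social(self, default_rep, rng):
        # L(same, 5) ~ +4.107 dominates 2s = -0.2
        obs = bc.Observation(s=-0.1, i=5, n_demo=5, a=bc.SAME)
        assert bc.choose(obs, default_rep, rng) == 1

    def test_exact_tie_is_fair_coin(self, default_rep):
        obs = bc.Observation(s=0.0, i=2, n_demo=5, a=bc.DIFFERENT)  # L = 0
        rng = np.random.default_rng(0)
        draws = [bc.choose(obs, default_rep, rng) for _ in range(400)]
        assert 140 < sum(draws) < 260  # ~Binomial(400, 1/2), +-6 SD


class TestChoiceProbability:
    def test_neutral_social_equals_alpha(self, default_world, default_rep):
        # L = 0 under the offset "different" signal: only the private signal acts
        p = bc.choice_probability(1, bc.DIFFERENT, 3, default_world, default_rep)
        assert p == pytest.approx(default_world.alpha)
        assert p == pytest.approx(stats.norm.cdf(1.0), abs=1e-12)

    def test_strong_social_saturates(self, default_world):
        rep = bc.CognitiveRep(q_hat=1 - 1e-9, gamma_hat=1e-9, phi_hat=1 - 1e-9,
                              sigma_hat=1.0)
        p = bc.choice_probability(1, bc.SAME, 5, default_world, rep)
        assert p > 0.9999

    def test_agrees_with_monte_carlo_choose(self, default_world, default_rep, rng):
        n_draws = 100_000
        for z, a, i in [(1, bc.SAME, 4), (0, bc.SAME, 1), (1, bc.DIFFERENT, 5)]:
            p = bc.choice_probability(z, a, i, default_world, default_rep)
            s = rng.normal(2 * z - 1, default_world.sigma, size=n_draws)
            L = bc.social_log_odds(a, i, 5, default_rep)
            sim = np.mean(2.0 * s / default_rep.sigma_hat**2 + L > 0)
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(sim - p) < 3 * se + 1e-12


class TestLearningFunction:
    def test_offset_rep_gives_flat_line_at_alpha(self, default_world, default_rep):
        lf = bc.learning_function(default_world, default_rep, bc.DIFFERENT)
        assert lf.probs == pytest.approx(
            np.full(6, default_world.alpha), abs=1e-12
        )

    def test_facultative_collapse_at_uninformative_phi_hat(self, default_world):
        rep = bc.CognitiveRep(q_hat=0.8, gamma_hat=0.15, phi_hat=0.5, sigma_hat=1.0)
        same = bc.learning_function(default_world, rep, bc.SAME)
        diff = bc.learning_function(default_world, rep, bc.DIFFERENT)
        assert same.probs == pytest.approx(diff.probs, abs=1e-12)

    def test_relabeling_symmetry_holds_by_construction(self, default_world, default_rep):
        # P(own optimum | k) must not depend on which behavior is labelled 1:
        # compare the two labelings directly
        n = default_world.n_demo
        for a in (bc.SAME, bc.DIFFERENT):
            lf = bc.learning_function(default_world, default_rep, a)
            for k in range(n + 1):
                p1 = bc.choice_probability(1, a, k, default_world, default_rep)
                p0 = 1 - bc.choice_probability(0, a, n - k, default_world, default_rep)
                assert lf[k] == pytest.approx(0.5 * (p1 + p0), abs=1e-15)
                assert p1 == pytest.approx(p0, abs=1e-12)

    def test_conformist_rep_lies_above_diagonal_for_majorities(self, default_world):
        rep = bc.CognitiveRep(q_hat=0.9, gamma_hat=0.05, phi_hat=0.6, sigma_hat=3.0)
        world = bc.WorldParams(gamma=0.05, phi=0.6, n_demo=5, sigma=3.0)
        lf = bc.learning_function(world, rep, bc.SAME)
        n = world.n_demo
        for k in range(n // 2 + 1, n):
            assert lf[k] > k / n
        assert lf[n] > 0.99


class TestAsymmetryIndex:
    def test_uninformative_signal_is_symmetric(self, default_world):
        rep = bc.CognitiveRep(q_hat=0.75, gamma_hat=0.25, phi_hat=0.5, sigma_hat=1.0)
        assert bc.asymmetry_index(default_world, rep) == 0.0

    def test_flat_prior_is_symmetric(self, default_world):
        rep = bc.CognitiveRep(q_hat=0.75, gamma_hat=0.5, phi_hat=0.7, sigma_hat=1.0)
        assert bc.asymmetry_index(default_world, rep) == pytest.approx(0.0, abs=1e-12)

    def test_biased_prior_with_informative_signal_is_asymmetric(self, default_world):
        rep = bc.CognitiveRep(q_hat=0.75, gamma_hat=0.25, phi_hat=0.7, sigma_hat=1.0)
        assert bc.asymmetry_index(default_world, rep) > 0.0

    @pytest.mark.parametrize("phi_hat", [0.6, 0.75, 0.9])
    def test_vanishes_as_prior_flattens(self, default_world, phi_hat):
        values = [
            abs(bc.asymmetry_index(
                default_world,
                bc.CognitiveRep(0.75, gamma_hat, phi_hat, 1.0),
            ))
            for gamma_hat in (0.3, 0.4, 0.45, 0.499)
        ]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 1e-3

    @pytest.mark.parametrize("gamma_hat", [0.1, 0.25, 0.4])
    def test_vanishes_as_signal_becomes_perfect(self, default_world, gamma_hat):
        values = [
            abs(bc.asymmetry_index(
                default_world,
                bc.CognitiveRep(0.75, gamma_hat, phi_hat, 1.0),
            ))
            for phi_hat in (0.9, 0.99, 0.999, 0.9999)
        ]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 1e-3


class TestValidation:
    def test_world_params_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bc.WorldParams(gamma=1.2, phi=0.9)
        with pytest.raises(ValueError):
            bc.WorldParams(gamma=0.1, phi=0.4)
        with pytest.raises(ValueError):
            bc.WorldParams(gamma=0.1, phi=0.9, sigma=0.0)

    def test_alpha_increases_as_noise_falls(self):
        alphas = [bc.WorldParams(0.1, 0.9, sigma=s).alpha for s in (3.0, 1.0, 0.5)]
        assert alphas == sorted(alphas)
        assert all(0.5 < a < 1.0 for a in alphas)

    def test_cognitive_rep_open_intervals(self):
        with pytest.raises(ValueError):
            bc.CognitiveRep(q_hat=0.5, gamma_hat=0.1, phi_hat=0.9)
        with pytest.raises(ValueError):
            bc.CognitiveRep(q_hat=0.75, gamma_hat=0.0, phi_hat=0.9)

    def test_observation_count_bounds(self):
        with pytest.raises(ValueError):
            bc.Observation(s=0.0, i=6, n_demo=5, a=bc.SAME)
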