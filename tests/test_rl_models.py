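"""RL model likelihoods, fitting, labels, and the exploration grid."""

import math

import numpy as np
import pandas as pd
import pytest

from explorebandit import rl_models as rm
from explorebandit.bandit_env import generate_reward_walk, simulate_session
from explorebandit.behavior_metrics import tetrachoric_corr, wsls_rates
from explorebandit.explore_hmm import fit_hmm, viterbi_decode

from conftest import constant_schedule, make_session


class TestLikelihood:
    def test_delta_rule_softmax_hand_recursion(self):
        # trial 1: p = 1/2; after L rewarded Q_L = 0.75, trial 2 choose L:
        # p = logistic(beta * (0.75 - 0.5))
        sess = make_session([0, 0], [1, 0])
        nll = rm.rl_nll("rl", {"alpha": 0.5, "beta": 1.0}, sess)
        expected = -math.log(0.5) - math.log(1 / (1 + math.exp(-0.25)))
        assert nll == pytest.approx(expected, abs=1e-9)

    def test_noisy_wsls_win_stay_term(self):
        sess = make_session([0, 0], [1, 0])
        nll = rm.rl_nll("wsls", {"eps": 0.2}, sess)
        assert nll == pytest.approx(-math.log(0.5) - math.log(0.9), abs=1e-12)

    def test_random_model_is_coin_flip(self):
        sess = make_session([0, 1, 1, 0, 1], [0, 0, 0, 0, 0])
        assert rm.rl_nll("random", {"b": 0.5}, sess) == pytest.approx(5 * math.log(2))

    def test_out_of_bounds_params_raise(self):
        sess = make_session([0, 1])
        with pytest.raises(ValueError):
            rm.rl_nll("rl", {"alpha": 1.5, "beta": 1.0}, sess)
        with pytest.raises(ValueError):
            rm.rl_nll("rlck_gamma",
                      {"alpha": 0.9, "beta": 1, "alpha_c": 0.1, "beta_c": 1, "gamma": 2.0},
                      sess)

    @pytest.mark.parametrize(
        "model_id,params",
        [
            ("rl", {"alpha": 0.3, "beta": 4.0}),
            ("rl_eps", {"alpha": 0.3, "beta": 4.0, "eps": 0.1}),
            ("rlck", {"alpha": 0.3, "beta": 4.0, "alpha_c": 0.5, "beta_c": 2.0}),
            ("rlck_gamma", {"alpha": 0.3, "beta": 4.0, "alpha_c": 0.5, "beta_c": 2.0, "gamma": 0.5}),
            ("rlck_eta", {"alpha": 0.3, "beta": 4.0, "alpha_c": 0.5, "beta_c": 2.0, "eta": 0.6}),
        ],
    )
    def test_trace_probabilities_multiply_to_nll(self, model_id, params, rng):
        sessions = [
            make_session(rng.integers(0, 2, 80), rng.integers(0, 2, 80), session_index=i + 1)
            for i in range(2)
        ]
        nll, trace = rm.rl_nll(model_id, params, sessions, return_trace=True)
        choices = np.concatenate([s.choices for s in sessions])
        assert nll == pytest.approx(
            float(-np.log(trace.choice_probabilities(choices)).sum()), abs=1e-9
        )
        p = trace.p_right
        assert np.all((p >= 0) & (p <= 1))
        assert np.all((trace.q >= 0) & (trace.q <= 1))
        assert np.all((trace.ck >= 0) & (trace.ck <= 1))

    def test_lapse_free_model_nests_plain_rl(self, rng):
        sess = make_session(rng.integers(0, 2, 100), rng.integers(0, 2, 100))
        base = {"alpha": 0.4, "beta": 3.0}
        assert rm.rl_nll("rl_eps", {**base, "eps": 0.0}, sess) == pytest.approx(
            rm.rl_nll("rl", base, sess), abs=1e-10
        )

    def test_eta_model_is_reparameterized_rlck(self, rng):
        sess = make_session(rng.integers(0, 2, 100), rng.integers(0, 2, 100))
        eta = rm.rl_nll(
            "rlck_eta",
            {"alpha": 0.4, "beta": 6.0, "alpha_c": 0.3, "beta_c": 4.0, "eta": 0.5},
            sess,
        )
        ck = rm.rl_nll(
            "rlck", {"alpha": 0.4, "beta": 3.0, "alpha_c": 0.3, "beta_c": 2.0}, sess
        )
        assert eta == pytest.approx(ck, abs=1e-10)


class TestFitting:
    def test_bias_recovery_binomial_mle(self, rng):
        c = (rng.random(10_000) > 0.7).astype(int)  # P(left) = 0.7
        fit = rm.fit_rl("random", make_session(c), seed=0)
        se = math.sqrt(0.7 * 0.3 / 10_000)
        assert fit.params["b"] == pytest.approx(0.7, abs=3 * se)

    def test_fit_deterministic_given_seed(self, rng):
        sess = make_session(rng.integers(0, 2, 200), rng.integers(0, 2, 200))
        f1 = rm.fit_rl("rl", sess, seed=5)
        f2 = rm.fit_rl("rl", sess, seed=5)
        assert f1.params == f2.params and f1.nll == f2.nll

    def test_learning_rate_recovery_across_replicates(self):
        """Fitting rlck to its own simulations recovers alpha within 0.1
        in at least 90% of replicates (8 sessions x 300 trials each)."""
        truth = {"alpha": 0.4, "beta": 3.0, "alpha_c": 0.3, "beta_c": 1.0}
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            sessions = []
            for j in range(8):
                sched = generate_reward_walk(300, seed=int(rng.integers(2**31)))
                sessions.append(
                    simulate_session(rm.make_policy("rlck", truth), sched,
                                     seed=int(rng.integers(2**31)), session_index=j + 1)
                )
            fit = rm.fit_rl("rlck", sessions, n_restarts=5,
                            seed=int(rng.integers(2**31)))
            hits += abs(fit.params["alpha"] - truth["alpha"]) <= 0.1
        assert hits >= 0.9 * n_rep

    def test_nesting_model_never_fits_worse(self, rng):
        sched = generate_reward_walk(300, seed=3)
        sess = simulate_session(
            rm.make_policy("rl", {"alpha": 0.4, "beta": 4.0}), sched, seed=9
        )
        f_rl = rm.fit_rl("rl", sess, n_restarts=6, seed=1)
        f_eps = rm.fit_rl("rl_eps", sess, n_restarts=6, seed=1)
        f_ck = rm.fit_rl("rlck", sess, n_restarts=6, seed=1)
        assert f_eps.nll <= f_rl.nll + 1e-3
        assert f_ck.nll <= f_rl.nll + 1e-3

    def test_session_fit_unit_returns_per_session_fits(self, rng):
        sessions = [
            make_session(rng.integers(0, 2, 60), rng.integers(0, 2, 60), session_index=i + 1)
            for i in range(3)
        ]
        fits = rm.fit_rl("random", sessions, fit_unit="session", seed=0)
        assert len(fits) == 3
        for fit, sess in zip(fits, sessions):
            assert fit.params["b"] == pytest.approx(float((sess.choices == 0).mean()), abs=0.02)

    def test_maximal_learning_rate_behaves_like_wsls(self):
        sched = generate_reward_walk(2000, seed=4)
        sess = simulate_session(
            rm.make_policy("rl", {"alpha": 1.0, "beta": 10.0}), sched, seed=2
        )
        rates = wsls_rates(sess)
        lose_stay = 1.0 - rates["lose_shift"]
        assert rates["win_stay"] > lose_stay + 0.2


class TestAgreementAndLabels:
    def test_constant_prediction_agreement_is_majority_rate(self):
        sess = make_session([0] * 7 + [1] * 3)
        fit = rm.RlFit("random", {"b": 0.7}, 0, 0, 0, 1, None)
        assert rm.model_agreement(fit, sess) == pytest.approx(0.7)

    def test_perfect_predictor_agreement_is_one(self):
        # wsls with eps=0 deterministically reproduces a WSLS-generated
        # sequence from trial 2 on; trial 1 ties at p=0.5 (half credit)
        c = [0, 0, 1, 1, 1]
        r = [1, 0, 1, 1, 0]
        sess = make_session(c, r)
        fit = rm.RlFit("wsls", {"eps": 0.0}, 0, 0, 0, 1, None)
        assert rm.model_agreement(fit, sess) == pytest.approx((4 + 0.5) / 5)

    def test_explore_labels_definition_and_greedy_limit(self):
        sched = constant_schedule(0.8, 0.2, 500)
        fit_params = {"alpha": 0.7, "beta": 20.0}
        sess = simulate_session(rm.make_policy("rl", fit_params), sched, seed=11)
        fit = rm.RlFit("rl", fit_params, 0, 0, 0, 1, None)
        labels = rm.rl_explore_labels(fit, sess)
        assert labels.mean() < 0.1  # near-greedy agent rarely deviates
        nll, trace = rm.rl_nll("rl", fit_params, sess, return_trace=True)
        q_chosen = trace.q[np.arange(sess.n_trials), sess.choices]
        q_other = trace.q[np.arange(sess.n_trials), 1 - sess.choices]
        assert np.all(labels[q_chosen > q_other] == 0)

    def test_labels_require_value_based_model(self):
        fit = rm.RlFit("random", {"b": 0.5}, 0, 0, 0, 1, None)
        with pytest.raises(ValueError):
            rm.rl_explore_labels(fit, make_session([0, 1]))

    def test_rl_and_hmm_labels_positively_correlated(self):
        truth = {"alpha": 0.4, "beta": 3.0, "alpha_c": 0.3, "beta_c": 1.0}
        rng = np.random.default_rng(14)
        sessions = []
        for j in range(4):
            sched = generate_reward_walk(300, seed=int(rng.integers(2**31)))
            sessions.append(
                simulate_session(rm.make_policy("rlck", truth), sched,
                                 seed=int(rng.integers(2**31)), session_index=j + 1)
            )
        rl_fit = rm.fit_rl("rlck", sessions, n_restarts=5, seed=2)
        rl_labels = rm.rl_explore_labels(rl_fit, sessions)
        hmm_fit = fit_hmm(sessions, "tied2", n_restarts=10, seed=3)
        hmm_labels = np.concatenate(
            [viterbi_decode(hmm_fit.spec, s).binary_explore for s in sessions]
        )
        assert tetrachoric_corr(rl_labels, hmm_labels) > 0.1


class TestGrid:
    def test_grid_api_and_no_learning_limit(self):
        grid = rm.exploration_grid_experiment(
            n_agents=30, alpha_range=(0.01, 0.02), beta_range=(1.0, 10.0),
            trials=150, seed=2, hmm_restarts=3,
        )
        assert set(grid.columns) == {"agent", "alpha", "beta", "p_explore", "reward_rate"}
        moderate = rm.exploration_grid_experiment(
            n_agents=30, alpha_range=(0.4, 0.5), beta_range=(1.0, 10.0),
            trials=150, seed=2, hmm_restarts=3,
        )
        # values never move for near-zero learning rates, so choices stay
        # near coin-flipping and are labeled exploratory far more often
        assert grid.p_explore.mean() > moderate.p_explore.mean() + 0.2

    def test_glm_recovers_planted_coefficient(self, rng):
        n = 4000
        alpha = rng.uniform(0.05, 1.0, n)
        beta = rng.uniform(0.1, 10.0, n)
        zb = (beta - beta.mean()) / beta.std()
        explore = 0.5 - 0.1 * zb + rng.normal(0, 0.05, n)
        table = pd.DataFrame(
            {"alpha": alpha, "beta": beta, "p_explore": explore, "reward_rate": 0.5}
        )
        res = rm.exploration_glm(table)
        assert res.loc["beta", "coef"] == pytest.approx(-0.1, abs=3 * res.loc["beta", "se"])

    def test_glm_rejects_constant_predictor(self):
        table = pd.DataFrame(
            {"alpha": [0.5] * 10, "beta": np.linspace(1, 5, 10), "p_explore": 0.5}
        )
        with pytest.raises(ValueError):
            rm.exploration_glm(table)

    def test_reward_rate_peaks_at_interior_learning_rate(self):
        """At strong value sensitivity (beta = 10), a moderate learning
        rate out-earns the maximal one, which degenerates toward
        win-stay/lose-shift."""
        rng = np.random.default_rng(8)
        scheds = [generate_reward_walk(300, seed=i) for i in range(60)]
        def mean_reward(alpha):
            pol = rm.make_policy("rl", {"alpha": alpha, "beta": 10.0})
            return np.mean([
                simulate_session(pol, s, seed=int(rng.integers(2**31))).rewards.mean()
                for s in scheds
            ])
        assert mean_reward(0.35) > mean_reward(1.0) + 0.005
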