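"""Behavioral statistics against simulated oracle agents and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdlc.agent import AgentConfig, MDLCAgent
from mdlc.analysis import (
    conflict_profile,
    degradation_decay,
    fit_choice_weights,
    fit_lagged_regression,
    fit_stay_regression,
    gini,
    masked_divergence,
    reaction_time,
    ridge_logistic,
)


# ---------------------------------------------------------------------------
# synthetic oracle agents for the two-step task
# ---------------------------------------------------------------------------

def simulate_two_step(stay_rule, n=10_000, seed=0):
    """Generate two-step trial records from a rule
    stay_rule(prev_transition, prev_reward) -> probability of staying."""
    rng = np.random.default_rng(seed)
    trials = []
    action = int(rng.integers(2))
    prev = None
    for _ in range(n):
        if prev is not None:
            p_stay = stay_rule(prev["transition"], prev["reward"])
            if rng.random() >= p_stay:
                action = 1 - action
        transition = "common" if rng.random() < 0.8 else "uncommon"
        reward = float(rng.random() < 0.5)
        rec = {"stage1_action": action, "transition": transition,
               "reward": reward, "session": 0}
        trials.append(rec)
        prev = rec
    return trials


class TestStayRegression:
    def test_reward_stay_agent_shows_model_free_pattern(self):
        trials = simulate_two_step(
            lambda tr, rw: 0.9 if rw else 0.1, seed=1)
        res = fit_stay_regression(trials)
        assert res.coefficients["common_rewarded"] > 0
        assert res.coefficients["uncommon_rewarded"] > 0
        assert res.coefficients["common_unrewarded"] < 0
        assert res.coefficients["uncommon_unrewarded"] < 0
        # near-equal within reward condition (transition played no role)
        assert res.coefficients["common_rewarded"] == pytest.approx(
            res.coefficients["uncommon_rewarded"], abs=0.2)
        assert res.pattern == "model_free"

    def test_transition_aware_agent_shows_model_based_pattern(self):
        trials = simulate_two_step(
            lambda tr, rw: 0.9 if ((rw and tr == "common")
                                   or (not rw and tr == "uncommon")) else 0.1,
            seed=2)
        res = fit_stay_regression(trials)
        assert res.coefficients["common_rewarded"] > 0
        assert res.coefficients["uncommon_unrewarded"] > 0
        assert res.pattern == "model_based"

    @pytest.mark.parametrize("seed", range(10))
    def test_random_agent_has_null_coefficients(self, seed):
        trials = simulate_two_step(lambda tr, rw: 0.5, n=4000, seed=seed)
        res = fit_stay_regression(trials)
        n_sig = sum(res.z[k] >= 2 for k in res.z)
        assert n_sig <= 1  # at most one false positive per fit

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            fit_stay_regression(simulate_two_step(lambda t, r: 0.5, n=50))


class TestLaggedRegression:
    @staticmethod
    def simulate_bandit(rule, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        choices, rewards = [], []
        c = int(rng.integers(2))
        for t in range(n):
            if t > 0:
                c = rule(choices[-1], rewards[-1], rng)
            choices.append(c)
            rewards.append(float(rng.random() < 0.5))
        return [(np.array(choices), np.array(rewards))]

    def test_win_stay_lose_shift_loads_on_lag1_reward_seeking(self):
        def rule(c, r, rng):
            return c if r else 1 - c
        res = fit_lagged_regression(self.simulate_bandit(rule, seed=3))
        rs = res.family("reward_seeking")
        assert rs[0] > 1.0
        assert np.all(np.abs(rs[1:]) < 0.3)
        assert abs(res.family("perseveration")[0]) < 0.3 or rs[0] > \
            res.family("perseveration")[0]

    def test_repeat_agent_loads_on_lag1_perseveration(self):
        def rule(c, r, rng):
            return c if rng.random() < 0.9 else 1 - c
        res = fit_lagged_regression(self.simulate_bandit(rule, seed=4))
        pv = res.family("perseveration")
        assert pv[0] > 1.0
        assert abs(res.family("reward_seeking")[0]) < 0.3

    def test_side_symmetric_agent_null_outcome_main_effect(self):
        def rule(c, r, rng):
            return int(rng.integers(2))
        res = fit_lagged_regression(self.simulate_bandit(rule, seed=5))
        assert np.all(np.abs(res.family("outcome_main")) < 0.2)


class TestReactionTime:
    @pytest.mark.parametrize("pmax,threshold,expected", [
        (1.0, 3.0, 3), (0.5, 1.0, 2), (0.6, 1.5, 3)])
    def test_closed_form_examples(self, pmax, threshold, expected):
        dist = np.array([pmax, 1.0 - pmax]) if pmax < 1 else np.array([1.0, 0.0])
        assert reaction_time(dist, threshold) == expected

    @given(st.floats(0.05, 0.95), st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_equals_ceiling_rule(self, p, thr):
        dist = np.array([p, 1.0 - p])
        assert reaction_time(dist, thr) == int(np.ceil(thr / max(p, 1 - p)))

    def test_nonincreasing_in_pmax(self):
        thr = 1.5
        rts = [reaction_time(np.array([p, 1 - p]), thr)
               for p in np.linspace(0.5, 0.99, 30)]
        assert np.all(np.diff(rts) <= 0)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            reaction_time(np.array([0.5, 0.5]), 0.0)


class TestGini:
    def test_equal_weights_zero(self):
        assert gini([1, 1, 1, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_single_cue_reference(self):
        # direct evaluation of the pairwise-difference formula for n = 4
        assert gini([1, 0, 0, 0]) == pytest.approx(0.75, abs=1e-12)

    def test_two_of_four(self):
        assert gini([2, 2, 0, 0]) == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
           st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_and_permutation_invariance(self, w, c):
        rng = np.random.default_rng(0)
        w = np.asarray(w)
        assert gini(w * c) == pytest.approx(gini(w), rel=1e-9)
        assert gini(rng.permutation(w)) == pytest.approx(gini(w), rel=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            gini([0.0, 0.0])


class TestChoiceWeights:
    @staticmethod
    def simulate_choices(decision, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n):
            a, b = rng.integers(0, 2, 4).astype(float), \
                rng.integers(0, 2, 4).astype(float)
            trials.append({"option_a": a, "option_b": b,
                           "choice": decision(a, b, rng)})
        return trials

    def test_top_feature_agent_concentrates_weights(self):
        def top_only(a, b, rng):
            if a[0] != b[0]:
                return 0 if a[0] > b[0] else 1
            return int(rng.integers(2))
        w, _ = fit_choice_weights(self.simulate_choices(top_only, seed=6))
        assert np.argmax(np.abs(w)) == 0
        assert gini(w) > 0.55  # near the single-cue reference (0.75)

    def test_equal_weighting_agent_low_gini(self):
        def equal(a, b, rng):
            da = float(np.sum(a) - np.sum(b))
            p = 1.0 / (1.0 + np.exp(-3.0 * da))
            return 0 if rng.random() < p else 1
        w, _ = fit_choice_weights(self.simulate_choices(equal, seed=7))
        assert gini(w) < 0.2

    def test_shuffled_labels_yield_null_weights(self):
        def coin(a, b, rng):
            return int(rng.integers(2))
        w, _ = fit_choice_weights(self.simulate_choices(coin, seed=8))
        assert np.all(np.abs(w) < 0.1)
        if np.all(np.abs(w) < 1e-12):
            with pytest.raises(ValueError):
                gini(w)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            fit_choice_weights(self.simulate_choices(
                lambda a, b, rng: 0, n=100))


class TestConflictAndMasking:
    @pytest.fixture()
    def agent(self):
        return MDLCAgent(AgentConfig(
            feature_groups=[("w", 3), ("c", 3)], n_actions=2, hidden_size=8,
            seed=0))

    def test_identical_pathways_zero_kl_profile(self, agent):
        probes = [{"obs": np.eye(6)[i], "condition": "x"} for i in range(3)]
        prof = conflict_profile(agent, probes)
        assert prof.mean_kl["x"] == pytest.approx(0.0, abs=1e-9)
        assert prof.n["x"] == 3

    def test_unlabeled_probe_raises(self, agent):
        with pytest.raises(ValueError):
            conflict_profile(agent, [{"obs": np.zeros(6)}])

    def test_masking_inactive_group_no_divergence(self, agent):
        rng = np.random.default_rng(1)
        agent.params["c_Wout"].data = rng.normal(size=(8, 2))
        stim = np.zeros((4, 6))
        stim[:, :3] = rng.random((4, 3))  # group "c" inactive
        assert masked_divergence(agent, stim, "c") == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_zeroed_readout_no_divergence(self, agent):
        stim = np.random.default_rng(2).random((4, 6))
        assert masked_divergence(agent, stim, "w") == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_unknown_group_raises(self, agent):
        with pytest.raises(KeyError):
            masked_divergence(agent, np.zeros((1, 6)), "nope")


class TestDegradationDecay:
    def test_step_drop_detected_at_window_length(self):
        presses = np.concatenate([np.ones(500), np.zeros(500)])
        assert degradation_decay(presses, onset=500, window=50) == 50

    def test_constant_rate_never_decays(self):
        assert degradation_decay(np.ones(1000), onset=500) == np.inf

    def test_exponential_decay_recovers_half_life(self):
        # closed-form oracle: the log carries the press probability itself,
        # so the only distortion is the trailing-window smoothing lag
        tau = 1000.0
        onset = 600
        t = np.arange(8000)
        p = np.where(t < onset, 0.9, 0.9 * np.exp(-(t - onset) / tau))
        est = degradation_decay(p, onset=onset, window=50)
        assert est == pytest.approx(tau * np.log(2), rel=0.10)

    def test_zero_pre_onset_rate_raises(self):
        with pytest.raises(ValueError):
            degradation_decay(np.zeros(400), onset=200)


class TestRidgeLogistic:
    def test_matches_statsmodels_on_well_conditioned_fit(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(10)
        X = rng.normal(size=(4000, 3))
        beta_true = np.array([0.8, -0.5, 0.2])
        y = (rng.random(4000) <
             1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta, bse, _ = ridge_logistic(X, y, penalty=1e-8)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-4)
        np.testing.assert_allclose(bse, ref.bse, atol=1e-4)

    def test_separation_flagged_and_finite(self):
        X = np.linspace(-1, 1, 100)[:, None]
        y = (X[:, 0] > 0).astype(float)
        beta, bse, flags = ridge_logistic(X, y, penalty=1e-4)
        assert np.isfinite(beta).all() and np.isfinite(bse).all()
        assert flags["separation"]
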