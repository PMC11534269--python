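"""Task-environment contracts and trial statistics."""

import numpy as np
import pytest

from mdlc.envs import (
    ContingencyEnv,
    DemandChoiceEnv,
    DriftingBanditEnv,
    GoalNavEnv,
    MultiAttributeEnv,
    ShapeNamingEnv,
    StroopEnv,
    TwoStepEnv,
    is_noncompensatory,
)


def collect_episode(env, policy, rng):
    obs = env.reset(rng)
    infos, rewards = [], []
    done = False
    while not done:
        res = env.step(policy(obs, rng))
        infos.append(res.info)
        rewards.append(res.reward)
        obs, done = res.observation, res.done
    return infos, rewards


def random_policy(n):
    return lambda obs, rng: int(rng.integers(n))


class TestGoalNav:
    def test_wall_bump_keeps_position(self):
        env = GoalNavEnv()
        rng = np.random.default_rng(0)
        env.reset(rng)
        env.pos = (0, 3)
        res = env.step(0)  # up, into the wall
        assert res.info["position"] == (0, 3)
        assert not res.done

    def test_adjacent_goal_step_rewards_and_ends(self):
        env = GoalNavEnv(fixed_goal=0)
        env.reset(np.random.default_rng(0))
        env.pos = (0, 1)
        res = env.step(2)  # left onto (0, 0)
        assert res.reward == 1.0 and res.done and res.info["reached"]

    def test_goal_cue_frequencies(self):
        env = GoalNavEnv(goal_freqs=[0.8, 0.2])
        rng = np.random.default_rng(1)
        cues = [env.reset(rng) is not None and env.goal_idx
                for _ in range(10_000)]
        assert np.mean(np.array(cues) == 0) == pytest.approx(0.8, abs=0.01)

    def test_goal_outside_grid_raises(self):
        with pytest.raises(ValueError):
            GoalNavEnv(grid_size=4, goals=[(0, 0), (5, 5)])

    def test_reproducible_under_seed(self):
        def run(seed):
            env = GoalNavEnv()
            rng = np.random.default_rng(seed)
            env.reset(rng)
            return collect_episode(env, random_policy(4),
                                   np.random.default_rng(seed + 1))
        assert run(3) == run(3)


class TestStroop:
    def test_word_reading_rule(self):
        env = StroopEnv()
        env.reset(np.random.default_rng(0))
        env.trial = {"task": "WR", "word": "RED", "color": "blue",
                     "congruence": "incongruent", "correct": 0}
        assert env.step(0).reward == 1.0

    def test_color_naming_rule_rejects_word_response(self):
        env = StroopEnv()
        env.reset(np.random.default_rng(0))
        env.trial = {"task": "CN", "word": "RED", "color": "blue",
                     "congruence": "incongruent", "correct": 1}
        assert env.step(0).reward == 0.0

    def test_neutral_mode_never_shows_both_dimensions(self):
        env = StroopEnv(neutral_only=True)
        rng = np.random.default_rng(2)
        for _ in range(500):
            env.reset(rng)
            assert (env.trial["word"] == "none") or (env.trial["color"] == "none")
            assert env.trial["congruence"] == "neutral"

    def test_trial_mix_proportions(self):
        env = StroopEnv(p_word_reading=0.75, p_incongruent=0.5)
        rng = np.random.default_rng(3)
        tasks = []
        for _ in range(10_000):
            env.reset(rng)
            tasks.append(env.trial["task"])
        assert np.mean(np.array(tasks) == "WR") == pytest.approx(0.75, abs=0.015)


class TestDemandChoice:
    def test_block_incongruence_converges_to_low(self):
        env = DemandChoiceEnv(block_length=20, p_incongruent_high=0.9,
                              p_incongruent_low=0.1)
        rng = np.random.default_rng(4)
        incong = []
        for _ in range(300):
            env.reset(rng)
            env.step(env.low_action)  # always pick the low block
            for _ in range(20):
                res = env.step(0)
                incong.append(res.info["congruence"] == "incongruent")
        assert np.mean(incong) == pytest.approx(0.1, abs=0.02)

    def test_block_length_one_is_choice_plus_single_trial(self):
        env = DemandChoiceEnv(block_length=1)
        env.reset(np.random.default_rng(0))
        res1 = env.step(0)
        assert not res1.done and res1.info["stage"] == "choice"
        res2 = env.step(0)
        assert res2.done

    def test_invalid_proportions_raise(self):
        with pytest.raises(ValueError):
            DemandChoiceEnv(p_incongruent_high=0.2, p_incongruent_low=0.5)


class TestShapeNaming:
    def test_congruent_trial_same_answer_under_both_cues(self):
        env = ShapeNamingEnv()
        for probe in ShapeNamingEnv.probe_set(env.spec):
            if probe["congruence"] == "congruent":
                cn = probe["color"]
                sn = probe["shape"]
                assert cn == sn

    def test_probe_set_composition_fixed(self):
        env = ShapeNamingEnv()
        p1 = ShapeNamingEnv.probe_set(env.spec)
        p2 = ShapeNamingEnv.probe_set(env.spec)
        assert len(p1) == 8
        for a, b in zip(p1, p2):
            assert a["task"] == b["task"] and a["congruence"] == b["congruence"]

    def test_zero_shape_trials_matches_pretraining_mix(self):
        env = ShapeNamingEnv(p_shape_naming=0.0)
        rng = np.random.default_rng(5)
        for _ in range(200):
            env.reset(rng)
            assert env.trial["task"] == "CN"


class TestTwoStep:
    def test_common_transition_rate(self):
        env = TwoStepEnv(common_prob=0.8, n_trials=10_000)
        rng = np.random.default_rng(6)
        env.reset(rng)
        common = []
        for _ in range(10_000):
            env.step(int(rng.integers(2)))     # stage 1
            res = env.step(0)                   # stage 2
            common.append(res.info["transition"] == "common")
        assert np.mean(common) == pytest.approx(0.8, abs=0.01)

    def test_reward_probs_stay_in_bounds(self):
        env = TwoStepEnv(n_trials=2000)
        rng = np.random.default_rng(7)
        env.reset(rng)
        for _ in range(2000):
            env.step(0)
            res = env.step(0)
            lo, hi = env.bounds
            assert all(lo <= p <= hi for p in res.info["p_reward"])

    def test_cued_reversal_swaps_common_destination(self):
        env = TwoStepEnv(common_prob=0.99, reversal_hazard=0.0, n_trials=400)
        rng = np.random.default_rng(8)
        env.reset(rng)
        env.mapping = 0
        env.step(0)
        assert env.s2 == 0  # common under mapping 0
        env.step(0)
        env.mapping = 1     # cued reversal
        env.step(0)
        assert env.s2 == 1  # same action now commonly reaches the other state


class TestDriftingBandit:
    def test_probs_bounded_over_long_run(self):
        env = DriftingBanditEnv(n_trials=100_000)
        rng = np.random.default_rng(9)
        env.reset(rng)
        for _ in range(100_000):
            env.step(0)
            assert 0.05 <= env.p[0] <= 0.95 and 0.05 <= env.p[1] <= 0.95

    def test_zero_drift_keeps_probs_constant(self):
        env = DriftingBanditEnv(drift_sd=1e-300, n_trials=100)
        rng = np.random.default_rng(10)
        env.reset(rng)
        p0 = tuple(env.p)
        for _ in range(100):
            env.step(1)
        assert env.p == pytest.approx(p0, abs=1e-6)

    def test_fixed_arm_reward_rate_tracks_time_average(self):
        env = DriftingBanditEnv(n_trials=20_000)
        rng = np.random.default_rng(11)
        env.reset(rng)
        rewards, probs = [], []
        for _ in range(20_000):
            probs.append(env.p[0])
            rewards.append(env.step(0).reward)
        assert np.mean(rewards) == pytest.approx(np.mean(probs), abs=0.01)


class TestContingency:
    def test_training_phase_abstain_never_rewarded(self):
        env = ContingencyEnv(p=0.5, degradation_onset=1000)
        rng = np.random.default_rng(12)
        env.reset(rng)
        for _ in range(500):
            assert env.step(1).reward == 0.0

    def test_training_press_reward_frequency(self):
        env = ContingencyEnv(p=0.5, degradation_onset=20_000,
                             session_length=10_000)
        rng = np.random.default_rng(13)
        env.reset(rng)
        rewards = [env.step(0).info["reward"] for _ in range(10_000)]
        assert np.mean(rewards) == pytest.approx(0.5, abs=0.01)

    def test_degradation_rate_independent_of_action(self):
        env = ContingencyEnv(p=0.4, degradation_onset=1, session_length=4000)
        rng = np.random.default_rng(14)
        env.reset(rng)
        env.global_step = 10  # past onset
        r_press = [env.step(0).info["reward"] for _ in range(2000)]
        r_abst = [env.step(1).info["reward"] for _ in range(1999)]
        assert np.mean(r_press) == pytest.approx(np.mean(r_abst), abs=0.04)
        assert env.phase == "degradation"


class TestMultiAttribute:
    def test_weights_are_noncompensatory(self):
        assert is_noncompensatory((8, 4, 2, 1))
        assert not is_noncompensatory((4, 3, 2, 1))

    def test_top_feature_only_difference_decides(self):
        env = MultiAttributeEnv()
        env.reset(np.random.default_rng(0))
        env.trial = {"option_a": np.array([1., 1, 0, 1]),
                     "option_b": np.array([0., 1, 0, 1]),
                     "value_a": 13.0, "value_b": 5.0, "correct": 0,
                     "top_feature_differs": True, "top_feature_choice": 0}
        assert env.step(0).reward == 1.0

    def test_noncompensatory_arithmetic(self):
        # (0,1,1,1) vs (1,0,0,0): 7 < 8, second option correct
        w = np.array([8.0, 4, 2, 1])
        assert np.dot([0, 1, 1, 1], w) < np.dot([1, 0, 0, 0], w)

    def test_top_feature_validity_matches_enumeration_oracle(self):
        env = MultiAttributeEnv()
        pairs = MultiAttributeEnv.enumerate_pairs((8, 4, 2, 1))
        w = env.weights
        decided = [(a, b) for a, b in pairs if a[0] != b[0]]
        oracle_frac = sum(
            1 for a, b in decided
            if (a[0] > b[0]) == (float(a @ w) > float(b @ w))) / len(decided)
        assert oracle_frac == 1.0  # non-compensatory: top feature never wrong
        # empirical fraction of presented trials decided by the top feature
        rng = np.random.default_rng(15)
        hits = 0
        n = 10_000
        for _ in range(n):
            env.reset(rng)
            if env.trial["top_feature_differs"]:
                hits += env.trial["top_feature_choice"] == env.trial["correct"]
        assert hits / n == pytest.approx(len(decided) / len(pairs), abs=0.02)

    def test_ties_never_presented(self):
        env = MultiAttributeEnv()
        rng = np.random.default_rng(16)
        for _ in range(2000):
            env.reset(rng)
            assert env.trial["value_a"] != env.trial["value_b"]

    def test_payoff_scale_shrinks_reward_gap(self):
        env = MultiAttributeEnv(payoff_scale=0.3)
        env.reset(np.random.default_rng(0))
        wrong = 1 - env.trial["correct"]
        assert env.step(wrong).reward == pytest.approx(0.7)
        env.reset(np.random.default_rng(1))
        assert env.step(env.trial["correct"]).reward == 1.0


def test_observation_matches_spec_everywhere():
    envs = [GoalNavEnv(), StroopEnv(), DemandChoiceEnv(), ShapeNamingEnv(),
            TwoStepEnv(n_trials=5), DriftingBanditEnv(n_trials=5),
            ContingencyEnv(degradation_onset=10, session_length=5),
            MultiAttributeEnv()]
    rng = np.random.default_rng(17)
    for env in envs:
        obs = env.reset(rng)
        assert obs.shape == (env.spec.obs_dim,)
        res = env.step(0)
        assert res.observation.shape == (env.spec.obs_dim,)
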