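"""Control environment: observation, reward, supervisor gating, episodes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from softboil.env import (
    ACTION_TABLE,
    EggCookerEnv,
    EnvConfig,
    EpisodeFinishedError,
    InvalidActionError,
    StepRecord,
    build_observation,
    compute_reward,
    slope,
    supervisor_action,
)
from softboil.plant import PlantParams
from softboil.profiles import build_serving_profile


def reward_oracle(tm, tr, tm_p, tr_p, h, c, h_p, c_p):
    """Independent piecewise evaluation of the shaped reward."""
    e, ep = tm - tr, tm_p - tr_p
    r = -1.0 - abs(e) + (abs(ep) - abs(e))
    if abs(e) < 1.0:
        r += 10.0
    if abs(e) < 0.5:
        r += 100.0
    if abs(e) < 0.1:
        r += 150.0
    if abs(e) < 0.05:
        r += 200.0
    if abs(e) < 0.5 and abs(tm - tm_p) < 0.05:
        r += 100.0
    if h != h_p or c != c_p:
        r -= 10.0
    if ep < 0.0 and c == 1:
        r -= 100.0
    if ep > 0.1 and h == 1:
        r -= 100.0
    if h == 0 and c == 0:
        r += 10.0
    return r


class TestSlope:
    def test_constant_history_is_flat(self):
        assert slope([60.0] * 10) == 0.0
        assert slope([60.0]) == 0.0

    def test_linear_history(self):
        hist = [60.0 + 0.1 * k for k in range(10)]
        assert slope(hist) == pytest.approx(0.1)

    def test_respects_dt(self):
        hist = [60.0 + 0.1 * k for k in range(10)]
        assert slope(hist, dt=2.0) == pytest.approx(0.05)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_matches_endpoint_difference(self, hist):
        assert slope(hist) == pytest.approx((hist[-1] - hist[0]) / 9.0)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            slope([])


class TestReward:
    def test_tight_tracking_collects_all_bonuses(self):
        r = compute_reward(StepRecord(60.03, 60.0, 0, 0), StepRecord(60.04, 60.0, 0, 0))
        assert r.total == pytest.approx(568.98)
        assert (r.b1, r.b2, r.b3, r.b4, r.b5, r.s3) == (10, 100, 150, 200, 100, 10)

    def test_cooling_below_reference_is_sanctioned(self):
        r = compute_reward(StepRecord(59.4, 60.0, 0, 1), StepRecord(59.5, 60.0, 0, 0))
        assert r.total == pytest.approx(-101.7)
        assert r.s1 == -100 and r.p1 == -10 and r.b1 == 10

    def test_heating_above_reference_is_sanctioned(self):
        r = compute_reward(StepRecord(62.5, 60.0, 1, 0), StepRecord(62.6, 60.0, 1, 0))
        assert r.total == pytest.approx(-103.4)
        assert r.s2 == -100 and r.p1 == 0 and r.b1 == 0

    def test_matches_independent_oracle_on_random_tuples(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            # mixture: wide errors plus values clustered at the bonus thresholds
            if rng.random() < 0.5:
                e, ep = rng.uniform(-3, 3, size=2)
            else:
                e, ep = rng.uniform(-0.12, 0.12, size=2)
            tr = 60.0
            h, c, hp, cp = rng.integers(0, 2, size=4)
            got = compute_reward(
                StepRecord(tr + e, tr, int(h), int(c)),
                StepRecord(tr + ep, tr, int(hp), int(cp)),
            )
            want = reward_oracle(tr + e, tr, tr + ep, tr, h, c, hp, cp)
            assert got.total == want

    def test_total_equals_sum_of_components(self):
        r = compute_reward(StepRecord(60.4, 60.0, 1, 1), StepRecord(59.9, 60.0, 0, 0))
        parts = [r.step_penalty, r.abs_error, r.improvement, r.b1, r.b2, r.b3,
                 r.b4, r.b5, r.p1, r.s1, r.s2, r.s3]
        assert r.total == pytest.approx(sum(parts))

    def test_bonus_sum_takes_only_nested_values(self):
        sums = set()
        for e in np.linspace(-2, 2, 2001):
            for dT in (0.0, 0.2):
                r = compute_reward(StepRecord(60 + e, 60.0, 0, 0), StepRecord(60 + e + dT, 60.0, 0, 0))
                b = r.b1 + r.b2 + r.b3 + r.b4 + r.b5
                sums.add(b)
                if r.b4 > 0:
                    assert b >= 460
        assert sums <= {0, 10, 110, 210, 260, 360, 460, 560}


class TestSupervisor:
    CFG = EnvConfig()

    def test_full_heating_before_activation(self):
        cmd = supervisor_action(50.0, 90.0, False, None, self.CFG)
        assert (cmd.heating, cmd.cooling, cmd.valve_fraction) == (1, 0, 1.0)

    def test_bang_bang_above_band(self):
        cmd = supervisor_action(64.0, 60.0, True, None, self.CFG)
        assert (cmd.heating, cmd.cooling) == (0, 1)

    def test_bang_bang_below_band(self):
        cmd = supervisor_action(55.0, 60.0, True, None, self.CFG)
        assert (cmd.heating, cmd.cooling) == (1, 0)

    @pytest.mark.parametrize("action,expect", [(0, (0, 0)), (1, (1, 0)), (2, (0, 1)), (3, (1, 1))])
    def test_agent_action_mapping_inside_band(self, action, expect):
        cmd = supervisor_action(60.5, 60.0, True, action, self.CFG)
        assert (cmd.heating, cmd.cooling) == expect
        assert cmd.valve_fraction == 1.0

    def test_deployment_valve_restriction(self):
        cfg = EnvConfig(deployment_mode=True)
        cmd = supervisor_action(58.5, 60.0, True, 2, cfg)
        assert cmd.cooling == 1 and cmd.valve_fraction == 0.2
        # above the fine-control threshold the valve opens fully
        cmd = supervisor_action(62.5, 60.0, True, 2, cfg)
        assert cmd.cooling == 1 and cmd.valve_fraction == 1.0

    def test_invalid_action_rejected(self):
        with pytest.raises(InvalidActionError):
            supervisor_action(60.5, 60.0, True, 7, self.CFG)
        with pytest.raises(InvalidActionError):
            supervisor_action(60.5, 60.0, True, None, self.CFG)


class TestObservation:
    CFG = EnvConfig()

    def _rec(self, i):
        return (60.0 + i, 60.0, float(i), 0.1 * i, i % 2, 0)

    def test_length_and_lag0_first(self):
        records = [self._rec(i) for i in range(15)]
        obs = build_observation(records, self.CFG)
        assert obs.shape == (60,)
        assert tuple(obs[:6]) == self._rec(14)
        assert tuple(obs[6:12]) == self._rec(13)

    def test_start_padding_replicates_first_record(self):
        obs = build_observation([self._rec(0)], self.CFG)
        assert np.array_equal(obs.reshape(10, 6), np.tile(self._rec(0), (10, 1)))

    def test_shift_property(self):
        records = [self._rec(i) for i in range(12)]
        before = build_observation(records, self.CFG)
        after = build_observation(records + [self._rec(12)], self.CFG)
        assert np.array_equal(after[6:12], before[:6])

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            build_observation([], self.CFG)

    def test_normalization_flag(self):
        cfg = EnvConfig(normalize_obs=True)
        obs = build_observation([self._rec(2)], cfg)
        assert obs[0] == pytest.approx(0.62)
        assert obs[2] == pytest.approx(2.0)


class TestEpisode:
    def test_reset_is_seed_deterministic(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        obs1, info1 = env.reset(seed=11)
        obs2, info2 = env.reset(seed=11)
        assert np.array_equal(obs1, obs2)
        assert info1["params"] == info2["params"]

    def test_reset_samples_within_limits(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        from softboil.plant import PARAM_FIELDS, TABLE_LIMITS

        for seed in range(5):
            _, info = env.reset(seed=seed)
            for f in PARAM_FIELDS:
                lo, _, hi = TABLE_LIMITS[f]
                assert lo <= getattr(info["params"], f) <= hi

    def test_reset_hands_over_inside_gate(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        obs, info = env.reset(seed=3)
        assert info["supervisor_steps"] > 0
        assert abs(obs[2]) < env.config.rl_gate  # error of the lag-0 tuple

    def test_step_reward_matches_compute_reward(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        env.reset(seed=5)
        _, r, *_ = env.step(0)
        curr, prev = env._records[-1], env._records[-2]
        expect = compute_reward(
            StepRecord(curr[0], curr[1], curr[4], curr[5]),
            StepRecord(prev[0], prev[1], prev[4], prev[5]),
        ).total
        # the agent's step may be followed by supervisor steps; its own
        # reward refers to the transition it commanded
        agent_rows = [i for i, s in enumerate(env.log.source) if s == "agent"]
        assert r == env.log.reward[agent_rows[0]]

    def test_gate_exclusivity_under_random_actions(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        rng = np.random.default_rng(0)
        env.reset(seed=21)
        done = False
        while not done:
            _, _, term, trunc, _ = env.step(int(rng.integers(4)))
            done = term or trunc
        log = env.log
        assert set(log.source) <= {"supervisor", "agent"}
        for i, src in enumerate(log.source):
            if src == "agent":
                # gating is decided on the pre-step record
                assert abs(log.t_meas[i - 1] - log.t_ref[i - 1]) < env.config.rl_gate

    def test_idle_forever_truncates_at_max_steps(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        obs, _ = env.reset(seed=2)
        done = False
        while not done:
            obs, _, term, trunc, _ = env.step(0)
            done = term or trunc
        assert env.log.truncated and not env.log.terminated
        assert len(env.log) - 1 == env.config.max_steps

    def test_competent_policy_completes_profile(self, serving_profile, threshold_policy):
        env = EggCookerEnv(serving_profile)
        obs, _ = env.reset(seed=4)
        done = False
        while not done:
            obs, _, term, trunc, _ = env.step(threshold_policy.predict(obs))
            done = term or trunc
        log = env.log
        assert log.terminated and not log.truncated
        assert log.heatup_end_step is not None
        assert len(log) - 1 == log.heatup_end_step + 1295

    def test_returned_observation_matches_record_layout(self, serving_profile):
        # the environment's rolling buffer must agree with the canonical
        # observation constructed from the record history
        env = EggCookerEnv(serving_profile)
        obs, _ = env.reset(seed=8)
        assert np.array_equal(obs, build_observation(env._records, env.config))
        for action in (0, 1, 0, 2, 1):
            obs, *_ = env.step(action)
            assert np.array_equal(obs, build_observation(env._records, env.config))

    def test_step_after_done_raises(self, serving_profile):
        env = EggCookerEnv(serving_profile)
        obs, _ = env.reset(seed=2)
        done = False
        while not done:
            obs, _, term, trunc, _ = env.step(0)
            done = term or trunc
        with pytest.raises(EpisodeFinishedError):
            env.step(0)

    def test_fixed_params_override(self, serving_profile, nominal_params):
        env = EggCookerEnv(serving_profile, fixed_params=nominal_params)
        _, info = env.reset(seed=9)
        assert info["params"] == nominal_params

    def test_log_csv_roundtrip(self, tmp_path, serving_profile, threshold_policy):
        env = EggCookerEnv(serving_profile)
        obs, _ = env.reset(seed=4)
        for _ in range(50):
            obs, *_ = env.step(threshold_policy.predict(obs))
        path = tmp_path / "episode.csv"
        env.log.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["step", "t_true", "t_meas", "t_ref", "heating",
                                    "cooling", "valve_fraction", "reward", "source"]
        assert len(df) == len(env.log)
        assert df["t_true"].iloc[-1] == pytest.approx(env.log.t_true[-1], abs=1e-5)
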