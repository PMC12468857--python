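"""Episodic control environment for the egg-cooker plant.

The learned policy never controls the whole process.  A hand-coded
supervisor owns the regions where the correct action is obvious:

* from cold start until the measured temperature first reaches the
  activation temperature (87 degC), the heater runs at full power with the
  valve closed;
* whenever the tracking error leaves the +-3 degC gate, a bang-bang rule
  heats below the reference and cools above it.

Only inside the gate does the agent choose among four discrete actions
(heater x valve, both on/off).  Supervisor-controlled steps are advanced
internally and do not consume agent decisions, so the learning signal
contains only states the policy is responsible for; supervisor steps are
still recorded in the episode log.

The observation is a 60-vector: for each of the last 10 steps (most recent
first) the tuple (measured T, reference T, error, 10-step slope, heating
command, cooling command).  The reward combines a per-step penalty, the
absolute error, the error improvement, nested proximity bonuses (thresholds
1 / 0.5 / 0.1 / 0.05 degC), a steadiness bonus, an action-switching penalty
and sanctions for cooling below / heating above the reference, plus a bonus
for idling (see :func:`compute_reward`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .plant import (
    ActuatorCommand,
    PlantParams,
    PlantState,
    SimulationDivergedError,
    TABLE_LIMITS,
    sample_params,
)
from .profiles import ReferenceProfile, reference_at

__all__ = [
    "EnvConfig",
    "StepRecord",
    "RewardBreakdown",
    "EpisodeLog",
    "EggCookerEnv",
    "EpisodeFinishedError",
    "InvalidActionError",
    "slope",
    "build_observation",
    "compute_reward",
    "supervisor_action",
    "ACTION_TABLE",
]

#: Discrete action -> (heating, cooling) commands.
ACTION_TABLE = {0: (0, 0), 1: (1, 0), 2: (0, 1), 3: (1, 1)}


class EpisodeFinishedError(RuntimeError):
    """step() was called after the episode ended."""


class InvalidActionError(ValueError):
    """Agent action outside the discrete action set {0, 1, 2, 3}."""


@dataclass(frozen=True)
class EnvConfig:
    """Environment constants.

    All defaults are the operating values of the target process: 1 s control
    period, 5000-step episode cap, +-3 degC supervisor gate, 87 degC policy
    activation, and the deployment-only 20%-valve rule below 2 degC error.
    """

    dt: float = 1.0
    max_steps: int = 5000
    rl_gate: float = 3.0
    dqn_activation_temp: float = 87.0
    #: Measured temperature that starts the post-heat-up profile clock.
    #: None means the lower edge of the first hold's tolerance band
    #: (heat-up target minus the hold tolerance, 88 degC by default).
    #: Triggering at the band edge rather than at an exact 90 degC crossing
    #: keeps the profile clock reachable for a policy still learning to
    #: close the last degrees of heat-up.
    heatup_trigger_temp: float | None = None
    deployment_mode: bool = False
    deployment_valve_threshold: float = 2.0
    deployment_valve_fraction: float = 0.2
    history_len: int = 10
    normalize_obs: bool = False
    init_temp_range: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.rl_gate <= 0 or self.history_len < 1:
            raise ValueError("dt and rl_gate must be positive, history_len >= 1")


class StepRecord(NamedTuple):
    """Minimal per-step record needed for reward evaluation."""

    t_meas: float
    t_ref: float
    heating: int
    cooling: int


class RewardBreakdown(NamedTuple):
    """All reward terms of one step, itemized; ``total`` is their sum."""

    step_penalty: float
    abs_error: float
    improvement: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    p1: float
    s1: float
    s2: float
    s3: float
    total: float


def slope(history, dt: float = 1.0) -> float:
    """Temperature rate over the last 10 samples, degC/s.

    ``history`` holds up to 10 measured temperatures, oldest first.  The
    rate is (newest - oldest) / (9 * dt); at episode start the missing lags
    are implicitly padded with the earliest sample, so a constant (or
    single-sample) history gives 0.
    """
    if len(history) < 1:
        raise ValueError("history must hold at least one sample")
    return (history[-1] - history[0]) / (9.0 * dt)


def compute_reward(curr: StepRecord, prev: StepRecord, config: EnvConfig | None = None) -> RewardBreakdown:
    """Shaped tracking reward for the transition ``prev -> curr``.

    With e = measured - reference:

    * constant step penalty -1 and error penalty -|e_i|;
    * improvement term |e_{i-1}| - |e_i|;
    * nested proximity bonuses b1..b4 = 10/100/150/200 for
      |e_i| < 1 / 0.5 / 0.1 / 0.05 degC, and steadiness bonus b5 = 100 for
      |e_i| < 0.5 with the measured temperature moving < 0.05 degC;
    * switching penalty p1 = -10 when either actuator command changed;
    * sanctions s1 = -100 for cooling while previously below reference,
      s2 = -100 for heating while previously more than 0.1 degC above;
    * idle bonus s3 = +10 when both actuators are commanded off.
    """
    e = curr.t_meas - curr.t_ref
    e_prev = prev.t_meas - prev.t_ref
    abs_e = abs(e)
    improvement = abs(e_prev) - abs_e
    b1 = 10.0 if abs_e < 1.0 else 0.0
    b2 = 100.0 if abs_e < 0.5 else 0.0
    b3 = 150.0 if abs_e < 0.1 else 0.0
    b4 = 200.0 if abs_e < 0.05 else 0.0
    b5 = 100.0 if (abs_e < 0.5 and abs(curr.t_meas - prev.t_meas) < 0.05) else 0.0
    p1 = -10.0 if (curr.heating != prev.heating or curr.cooling != prev.cooling) else 0.0
    s1 = -100.0 if (e_prev < 0.0 and curr.cooling == 1) else 0.0
    s2 = -100.0 if (e_prev > 0.1 and curr.heating == 1) else 0.0
    s3 = 10.0 if (curr.heating == 0 and curr.cooling == 0) else 0.0
    total = -1.0 + -abs_e + improvement + b1 + b2 + b3 + b4 + b5 + p1 + s1 + s2 + s3
    return RewardBreakdown(-1.0, -abs_e, improvement, b1, b2, b3, b4, b5,
                           p1, s1, s2, s3, total)


def _resolve_command(
    t_meas: float,
    t_ref: float,
    activation_done: bool,
    agent_action: int | None,
    config: EnvConfig,
) -> tuple[int, int, float]:
    err = t_meas - t_ref
    if not activation_done:
        heating, cooling = 1, 0
    elif abs(err) >= config.rl_gate:
        heating, cooling = (0, 1) if err > 0 else (1, 0)
    else:
        if agent_action is None or agent_action not in ACTION_TABLE:
            raise InvalidActionError(f"agent action must be in 0..3, got {agent_action!r}")
        heating, cooling = ACTION_TABLE[agent_action]
    valve = 1.0
    if (
        config.deployment_mode
        and cooling == 1
        and abs(err) < config.deployment_valve_threshold
    ):
        valve = config.deployment_valve_fraction
    return heating, cooling, valve


def supervisor_action(
    t_meas: float,
    t_ref: float,
    activation_done: bool,
    agent_action: int | None,
    config: EnvConfig,
) -> ActuatorCommand:
    """Resolve the actuator command for one step.

    Priority: (a) full heating until the activation temperature has been
    reached once; (b) bang-bang outside the +-rl_gate band; (c) the agent's
    discrete action inside the band.  In deployment mode an open valve is
    throttled to the deployment fraction when the error magnitude is below
    the deployment threshold.
    """
    heating, cooling, valve = _resolve_command(t_meas, t_ref, activation_done, agent_action, config)
    return ActuatorCommand(heating=heating, cooling=cooling, valve_fraction=valve)


def build_observation(records: list[tuple], config: EnvConfig) -> np.ndarray:
    """Flatten the last ``history_len`` step records into the observation.

    ``records`` holds per-step tuples (t_meas, t_ref, err, slope, heating,
    cooling), oldest first.  The lag-0 tuple comes first; missing lags at
    episode start are back-filled with the earliest record.
    """
    if not records:
        raise ValueError("empty history buffer")
    n = len(records)
    h = config.history_len
    out = np.empty(6 * h, dtype=np.float64)
    for k in range(h):
        rec = records[n - 1 - k] if k < n else records[0]
        out[6 * k : 6 * k + 6] = rec
    if config.normalize_obs:
        out *= _obs_scale(h)
    return out


def _obs_scale(history_len: int) -> np.ndarray:
    scale = _OBS_SCALE_CACHE.get(history_len)
    if scale is None:
        scale = np.tile([0.01, 0.01, 1.0, 1.0, 1.0, 1.0], history_len)
        _OBS_SCALE_CACHE[history_len] = scale
    return scale


_OBS_SCALE_CACHE: dict[int, np.ndarray] = {}


@dataclass
class EpisodeLog:
    """Per-step trajectory of one episode.

    Row 0 is the initial condition (no actuation, zero reward).  The
    ``source`` tag records who commanded each step: ``supervisor`` or
    ``agent``.
    """

    t_true: list[float] = field(default_factory=list)
    t_meas: list[float] = field(default_factory=list)
    t_ref: list[float] = field(default_factory=list)
    heating: list[int] = field(default_factory=list)
    cooling: list[int] = field(default_factory=list)
    valve_fraction: list[float] = field(default_factory=list)
    reward: list[float] = field(default_factory=list)
    source: list[str] = field(default_factory=list)
    heatup_end_step: int | None = None
    hold90_end_step: int | None = None
    params: PlantParams | None = None
    terminated: bool = False
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.t_true)

    @property
    def agent_reward(self) -> float:
        """Cumulative reward over agent-controlled steps (the learning signal)."""
        return sum(r for r, s in zip(self.reward, self.source) if s == "agent")

    @property
    def total_reward(self) -> float:
        return sum(self.reward)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": range(len(self)),
                "t_true": self.t_true,
                "t_meas": self.t_meas,
                "t_ref": self.t_ref,
                "heating": self.heating,
                "cooling": self.cooling,
                "valve_fraction": self.valve_fraction,
                "reward": self.reward,
                "source": self.source,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["step", "t_true", "t_meas", "t_ref", "heating", "cooling",
                 "valve_fraction", "reward", "source"]
            )
            for i in range(len(self)):
                w.writerow(
                    [i, f"{self.t_true[i]:.6f}", f"{self.t_meas[i]:.6f}",
                     f"{self.t_ref[i]:.6f}", self.heating[i], self.cooling[i],
                     self.valve_fraction[i], f"{self.reward[i]:.4f}", self.source[i]]
                )


class EggCookerEnv:
    """Gymnasium-style episodic environment (reset / step API).

    Discrete action space of size 4 and a 60-dimensional observation.  Plant
    parameters are re-randomized at every reset.  ``step`` consumes one
    *agent* decision; any subsequent supervisor-governed plant steps are
    advanced internally before the next observation is returned.
    """

    action_space_n = 4

    def __init__(
        self,
        profile: ReferenceProfile,
        limits: dict | None = None,
        config: EnvConfig | None = None,
        seed: int | None = None,
        fixed_params: PlantParams | None = None,
    ):
        self.profile = profile
        self.limits = TABLE_LIMITS if limits is None else limits
        self.config = config or EnvConfig()
        self.fixed_params = fixed_params
        self.observation_size = 6 * self.config.history_len
        self._rng = np.random.default_rng(seed)
        self._post_steps = int(round(profile.total_duration / self.config.dt))
        self._trigger_temp = (
            self.config.heatup_trigger_temp
            if self.config.heatup_trigger_temp is not None
            else profile.heatup_target - profile.phases[0].tolerance
        )
        self._done = True
        self.log: EpisodeLog | None = None

    # -- internal mechanics -------------------------------------------------

    @property
    def state(self) -> PlantState:
        return PlantState(
            t_true=self._t_true,
            count_heat=self._count_heat,
            count_cool=self._count_cool,
            step_index=self._i,
        )

    def _noise(self) -> float:
        # block-drawn standard normals, scaled by the episode's sigma
        k = self._noise_pos
        if k == self._noise_buf.shape[0]:
            self._noise_buf = self._noise_rng.standard_normal(4096)
            k = 0
        self._noise_pos = k + 1
        return self._noise_buf[k]

    def _advance(self, heating: int, cooling: int, valve: float, source: str) -> float:
        """One plant step under the given command; returns the step reward."""
        cfg = self.config
        p = self.params
        ch = self._count_heat + 1.0 if heating else self._count_heat - 1.0
        ch = min(max(ch, 0.0), 2.0 * p.delay_heat)
        cc = self._count_cool + 1.0 if cooling else self._count_cool - 1.0
        cc = min(max(cc, 0.0), 2.0 * p.delay_cool)
        d_heat = min(ch / p.delay_heat, 1.0) * p.p_heater * cfg.dt / (p.m_water * p.cp_water)
        d_cool = (
            min(cc / p.delay_cool, 1.0)
            * valve * p.mdot * (p.t_cold - self._t_true) * cfg.dt / p.m_water
        )
        t_new = self._t_true + d_heat + d_cool
        if not math.isfinite(t_new):
            raise SimulationDivergedError(f"temperature diverged at step {self._i}")
        self._count_heat, self._count_cool, self._t_true = ch, cc, t_new
        self._i = i = self._i + 1

        t_meas = t_new + p.sigma_noise * self._noise() if p.sigma_noise else t_new
        self._meas_hist.append(t_meas)
        if self._heatup_end is None and t_meas >= self._trigger_temp:
            self._heatup_end = he = i
            self.log.heatup_end_step = i
            self.log.hold90_end_step = i + int(round(self.profile.phases[0].duration / cfg.dt))
            # freeze the post-heat-up reference trajectory into an array
            self._ref_cache = np.array(
                [reference_at(self.profile, he + k, he, cfg.dt)
                 for k in range(self._post_steps + 1)]
            )
        if not self._activated and t_meas >= cfg.dqn_activation_temp:
            self._activated = True
        if self._heatup_end is None:
            t_ref = self.profile.heatup_target
        else:
            k = i - self._heatup_end
            t_ref = self._ref_cache[k] if k <= self._post_steps else self._ref_cache[-1]
        prev = self._records[-1]
        hist = self._meas_hist[-cfg.history_len :]
        self._records.append(
            (t_meas, t_ref, t_meas - t_ref, slope(hist, cfg.dt), heating, cooling)
        )
        buf = self._obs_buf
        buf[1:] = buf[:-1]
        buf[0] = self._records[-1]
        r = compute_reward(
            StepRecord(t_meas, t_ref, heating, cooling),
            StepRecord(prev[0], prev[1], prev[4], prev[5]),
            cfg,
        ).total
        log = self.log
        log.t_true.append(t_new)
        log.t_meas.append(t_meas)
        log.t_ref.append(t_ref)
        log.heating.append(heating)
        log.cooling.append(cooling)
        log.valve_fraction.append(valve)
        log.reward.append(r)
        log.source.append(source)
        if self._heatup_end is not None and i >= self._heatup_end + self._post_steps:
            self._done = True
            log.terminated = True
        elif i >= cfg.max_steps:
            self._done = True
            log.truncated = True
        return r

    def _agent_in_control(self) -> bool:
        rec = self._records[-1]
        return self._activated and abs(rec[0] - rec[1]) < self.config.rl_gate

    def _run_supervisor(self) -> int:
        """Auto-advance supervisor-governed steps; returns how many ran."""
        n = 0
        cfg = self.config
        while not self._done and not self._agent_in_control():
            rec = self._records[-1]
            heating, cooling, valve = _resolve_command(rec[0], rec[1], self._activated, None, cfg)
            self._advance(heating, cooling, valve, "supervisor")
            n += 1
        return n

    # -- public API ---------------------------------------------------------

    def reset(self, seed: int | None = None) -> tuple[np.ndarray, dict]:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        ss = np.random.SeedSequence(self._rng.integers(2**31))
        param_rng, self._noise_rng, init_rng = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )
        self.params = (
            self.fixed_params
            if self.fixed_params is not None
            else sample_params(param_rng, self.limits)
        )
        lo, hi = self.config.init_temp_range
        t0 = float(init_rng.uniform(lo, hi))
        self._t_true = t0
        self._count_heat = self._count_cool = 0.0
        self._i = 0
        self._noise_buf = self._noise_rng.standard_normal(4096)
        self._noise_pos = 0
        t_meas0 = t0 + self.params.sigma_noise * self._noise() if self.params.sigma_noise else t0
        self._meas_hist = [t_meas0]
        self._heatup_end: int | None = None
        self._activated = self._meas_hist[0] >= self.config.dqn_activation_temp
        self._done = False
        self._records: list[tuple] = []
        self._ref_cache: np.ndarray | None = None
        self.log = EpisodeLog(params=self.params)
        t_ref = reference_at(self.profile, 0, None, self.config.dt)
        self._records.append((t_meas0, t_ref, t_meas0 - t_ref, 0.0, 0, 0))
        self._obs_buf = np.empty((self.config.history_len, 6), dtype=np.float64)
        self._obs_buf[:] = self._records[0]
        self.log.t_true.append(t0)
        self.log.t_meas.append(self._meas_hist[0])
        self.log.t_ref.append(t_ref)
        self.log.heating.append(0)
        self.log.cooling.append(0)
        self.log.valve_fraction.append(1.0)
        self.log.reward.append(0.0)
        self.log.source.append("supervisor")
        self._run_supervisor()
        info = {"params": self.params, "supervisor_steps": self._i}
        return self._observation(), info

    def _observation(self) -> np.ndarray:
        out = self._obs_buf.ravel().copy()
        if self.config.normalize_obs:
            out *= _obs_scale(self.config.history_len)
        return out

    def step(self, action: int) -> tuple[np.ndarray, float, bool, bool, dict]:
        if self._done:
            raise EpisodeFinishedError("episode is finished; call reset()")
        rec = self._records[-1]
        heating, cooling, valve = _resolve_command(
            rec[0], rec[1], self._activated, int(action), self.config
        )
        r = self._advance(heating, cooling, valve, "agent")
        sup = self._run_supervisor()
        obs = self._observation()
        info = {
            "t_true": self._t_true,
            "t_meas": self._records[-1][0],
            "t_ref": self._records[-1][1],
            "supervisor_steps": sup,
        }
        return obs, r, self.log.terminated, self.log.truncated, info
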