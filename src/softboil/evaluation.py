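"""Tracking and food-safety metrics, and batch policy evaluation.

Two metrics summarize a cooking episode:

* **tracking MSE** — mean squared measured-vs-reference error, in degC^2,
  over the part of the episode that follows cooling down from the 90 degC
  texture hold.  By default the window opens when the measured curve first
  reaches 60 degC after that hold (the pasteurization setpoint) and runs to
  episode end; an alternative anchor opens it directly at the end of the
  90 degC hold, which additionally scores the steep 90->60 ramp whose
  feasibility depends on the drawn cooling capacity rather than on the
  controller.
* **pasteurization time** — the longest contiguous interval with the water
  at or above 60 degC; compliance requires at least 10 minutes.  Simulation
  reports use the noise-free true temperature; imported sensor logs have
  only the measured channel.

Batch evaluation runs a trained policy greedily over freshly randomized
episodes and aggregates both metrics into a report that serializes to
JSON + CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .env import EggCookerEnv, EnvConfig, EpisodeLog
from .plant import PARAM_FIELDS, PlantParams
from .profiles import ReferenceProfile, build_serving_profile

__all__ = [
    "PASTEURIZATION_THRESHOLD",
    "PASTEURIZATION_MIN_S",
    "EvalReport",
    "mse_from_cooling",
    "pasteurization_time",
    "run_episode",
    "batch_evaluate",
    "write_report",
    "read_report",
    "load_temperature_log",
    "plot_episode",
]

PASTEURIZATION_THRESHOLD = 60.0  # degC
PASTEURIZATION_MIN_S = 600.0  # 10 min


def mse_from_cooling(log: EpisodeLog, anchor: str = "reach60") -> float:
    """Tracking MSE (degC^2) over the post-cooling window of an episode.

    ``anchor`` selects where the window opens: ``"reach60"`` (default) at
    the first step after the 90 degC hold where the measured temperature
    has come down to 60 degC; ``"hold90_end"`` directly at the first step
    after the hold.  The window always closes at episode end.
    """
    if log.hold90_end_step is None or len(log) <= log.hold90_end_step + 1:
        raise ValueError("episode log ends before cooling starts")
    t_meas = np.asarray(log.t_meas)
    t_ref = np.asarray(log.t_ref)
    if anchor == "hold90_end":
        start = log.hold90_end_step + 1
    elif anchor == "reach60":
        after = np.nonzero(t_meas[log.hold90_end_step + 1 :] <= PASTEURIZATION_THRESHOLD)[0]
        if after.size == 0:
            raise ValueError("temperature never cooled to 60 degC; metric undefined")
        start = log.hold90_end_step + 1 + int(after[0])
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    err = t_meas[start:] - t_ref[start:]
    return float(np.mean(err * err))


def pasteurization_time(
    temps,
    dt: float = 1.0,
    threshold: float = PASTEURIZATION_THRESHOLD,
) -> tuple[float, bool]:
    """Longest contiguous time at or above ``threshold``, and compliance.

    Compliance means the hold criterion T >= 60 degC for >= 10 min is met
    by a single uninterrupted run (pathogen inactivation does not survive a
    dip below the threshold in this criterion).
    """
    temps = np.asarray(temps)
    if temps.size == 0:
        raise ValueError("temperature series is empty")
    above = temps >= threshold
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    seconds = best * dt
    return seconds, seconds >= PASTEURIZATION_MIN_S


def _action_fn(policy):
    if hasattr(policy, "predict"):
        return policy.predict
    if callable(policy):
        return policy
    raise TypeError("policy must expose .predict(obs) or be callable")


def run_episode(
    policy,
    profile: ReferenceProfile,
    seed: int,
    limits: dict | None = None,
    config: EnvConfig | None = None,
    fixed_params: PlantParams | None = None,
) -> EpisodeLog:
    """Run one greedy episode and return its log."""
    env = EggCookerEnv(profile, limits=limits, config=config, fixed_params=fixed_params)
    act = _action_fn(policy)
    obs, _ = env.reset(seed=int(seed))
    done = False
    while not done:
        obs, _, term, trunc, _ = env.step(act(obs))
        done = term or trunc
    return env.log


@dataclass
class EvalReport:
    """Aggregate of a batch of randomized evaluation episodes."""

    n_runs: int
    seed: int
    mse: list[float]
    pasteurization_s: list[float]
    compliant: list[bool]
    episode_len: list[int]
    params: list[dict] = field(default_factory=list)
    mse_anchor: str = "reach60"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("report needs at least one run")
        for name in ("mse", "pasteurization_s", "compliant", "episode_len"):
            if len(getattr(self, name)) != self.n_runs:
                raise ValueError(f"{name} length != n_runs")

    @property
    def completion_rate(self) -> float:
        """Fraction of runs whose episode completed the profile (an
        incomplete run carries an undefined, NaN, tracking MSE)."""
        return float(np.mean(~np.isnan(self.mse)))

    @property
    def mse_min(self) -> float:
        return float(np.nanmin(self.mse))

    @property
    def mse_mean(self) -> float:
        return float(np.nanmean(self.mse))

    @property
    def mse_max(self) -> float:
        return float(np.nanmax(self.mse))

    def summary(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "seed": self.seed,
            "mse_anchor": self.mse_anchor,
            "completion_rate": self.completion_rate,
            "mse_min": self.mse_min,
            "mse_mean": self.mse_mean,
            "mse_max": self.mse_max,
            "pasteurization_mean_s": float(np.mean(self.pasteurization_s)),
            "pasteurization_min_s": float(np.min(self.pasteurization_s)),
            "compliance_rate": float(np.mean(self.compliant)),
            "episode_len_mean": float(np.mean(self.episode_len)),
        }


def batch_evaluate(
    policy,
    n_runs: int,
    seed: int,
    profile: ReferenceProfile | None = None,
    limits: dict | None = None,
    config: EnvConfig | None = None,
    mse_anchor: str = "reach60",
) -> EvalReport:
    """Greedy evaluation over ``n_runs`` freshly randomized episodes.

    Pasteurization is computed on the simulator's true (noise-free)
    temperature.  Deterministic for a given seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    profile = profile or build_serving_profile()
    run_seeds = np.random.default_rng(seed).integers(2**31, size=n_runs)
    mses, past, comp, lens, draws = [], [], [], [], []
    for s in run_seeds:
        log = run_episode(policy, profile, int(s), limits=limits, config=config)
        try:
            mses.append(mse_from_cooling(log, anchor=mse_anchor))
        except ValueError:
            # truncated before the cooling window: undefined tracking MSE
            mses.append(float("nan"))
        dt = (config or EnvConfig()).dt
        seconds, ok = pasteurization_time(log.t_true, dt=dt)
        past.append(seconds)
        comp.append(bool(ok))
        lens.append(len(log) - 1)
        draws.append(log.params.to_dict())
    return EvalReport(
        n_runs=n_runs,
        seed=seed,
        mse=mses,
        pasteurization_s=past,
        compliant=comp,
        episode_len=lens,
        params=draws,
        mse_anchor=mse_anchor,
    )


def write_report(report: EvalReport, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.json`` (summary + runs) and ``<path>.csv`` (per-run).

    The JSON carries full-precision per-run values, so read_report
    round-trips losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    json_path = path.with_suffix(".json")
    csv_path = path.with_suffix(".csv")
    payload = {
        "summary": report.summary(),
        "runs": {
            "mse": report.mse,
            "pasteurization_s": report.pasteurization_s,
            "compliant": report.compliant,
            "episode_len": report.episode_len,
            "params": report.params,
        },
    }
    json_path.write_text(json.dumps(payload, indent=2))
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run", "mse", "pasteurization_s", "compliant", "episode_len", *PARAM_FIELDS])
        for i in range(report.n_runs):
            p = report.params[i] if report.params else {}
            w.writerow(
                [i, repr(report.mse[i]), repr(report.pasteurization_s[i]),
                 int(report.compliant[i]), report.episode_len[i],
                 *(p.get(f, "") for f in PARAM_FIELDS)]
            )
    return json_path, csv_path


def read_report(path: str | Path) -> EvalReport:
    payload = json.loads(Path(path).with_suffix(".json").read_text())
    runs = payload["runs"]
    return EvalReport(
        n_runs=payload["summary"]["n_runs"],
        seed=payload["summary"]["seed"],
        mse=list(runs["mse"]),
        pasteurization_s=list(runs["pasteurization_s"]),
        compliant=[bool(c) for c in runs["compliant"]],
        episode_len=list(runs["episode_len"]),
        params=list(runs.get("params", [])),
        mse_anchor=payload["summary"].get("mse_anchor", "reach60"),
    )


def load_temperature_log(path: str | Path):
    """Import an external temperature log CSV.

    Accepts columns named (case-insensitively) step or time/timestamp, a
    temperature column (temperature, t_meas or temp), and optionally a
    reference column (reference, t_ref).  Returns a pandas DataFrame with
    columns step, t_meas and, when present, t_ref.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    out = pd.DataFrame()
    for want, names in (
        ("step", ("step", "time", "timestamp", "t")),
        ("t_meas", ("t_meas", "temperature", "temp", "t_measured")),
        ("t_ref", ("t_ref", "reference", "setpoint")),
    ):
        for n in names:
            if n in cols:
                out[want] = df[cols[n]]
                break
    if "t_meas" not in out:
        raise ValueError(f"no temperature column found in {path}")
    if "step" not in out:
        out.insert(0, "step", range(len(out)))
    return out


def plot_episode(log: EpisodeLog, path: str | Path, dt: float = 1.0) -> Path:
    """Save a PNG of measured temperature vs. reference over the episode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(len(log)) * dt
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.plot(t, log.t_meas, lw=0.8, label="measured")
    ax.plot(t, log.t_ref, lw=1.2, ls="--", label="reference")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("temperature [degC]")
    ax.legend(loc="best")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
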