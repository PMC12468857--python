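"""Reference temperature profiles for soft-boiled egg cooking.

The setpoint trajectory is staged: heat up to 90 degC (duration depends on
the thermal load, so this phase has no fixed length), hold 90 degC briefly
to set the egg-white texture, ramp down to 60 degC, hold 10 min for
pasteurization, ramp to 57 degC and hold to keep the eggs warm.

Two variants exist:

* the *serving* profile holds 90 degC for 1 min (the product trajectory);
* the *training* profile holds 90 degC for 10 min, so that a learning
  controller sees as much time near 90 degC as near the lower setpoints and
  does not under-weight performance there.

Time is indexed in control steps.  During heat-up the reference is the
90 degC target (the supervisor, not the learned policy, governs until the
activation temperature anyway); the post-heat-up clock starts at the step
the measured temperature first reaches the heat-up target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Phase",
    "ReferenceProfile",
    "InvalidProfileError",
    "build_serving_profile",
    "build_training_profile",
    "reference_at",
]

HEATUP_TARGET = 90.0


class InvalidProfileError(ValueError):
    """A phase has a non-positive duration or inconsistent endpoints."""


@dataclass(frozen=True)
class Phase:
    """One post-heat-up segment of the reference trajectory.

    ``kind`` is ``"hold"`` (constant at ``t_start == t_end``) or ``"ramp"``
    (linear from ``t_start`` to ``t_end`` over ``duration`` seconds).
    ``tolerance`` is the +- degC band the process is expected to stay in.
    """

    kind: str
    t_start: float
    t_end: float
    duration: float
    tolerance: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "ramp"):
            raise InvalidProfileError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise InvalidProfileError(f"{self.kind} phase duration must be positive")
        if self.kind == "hold" and self.t_start != self.t_end:
            raise InvalidProfileError("hold phase must have t_start == t_end")


@dataclass(frozen=True)
class ReferenceProfile:
    """Ordered post-heat-up phases plus the heat-up target."""

    phases: tuple[Phase, ...]
    heatup_target: float = HEATUP_TARGET

    def __post_init__(self) -> None:
        if not self.phases:
            raise InvalidProfileError("profile needs at least one phase")
        prev_end = self.heatup_target
        for ph in self.phases:
            if ph.t_start != prev_end:
                raise InvalidProfileError(
                    f"phase starting at {ph.t_start} degC breaks continuity "
                    f"(previous phase ended at {prev_end} degC)"
                )
            prev_end = ph.t_end

    @property
    def total_duration(self) -> float:
        """Post-heat-up length in seconds."""
        return sum(ph.duration for ph in self.phases)

    def to_dict(self) -> dict:
        return {
            "heatup_target": self.heatup_target,
            "phases": [
                {
                    "kind": p.kind,
                    "t_start": p.t_start,
                    "t_end": p.t_end,
                    "duration": p.duration,
                    "tolerance": p.tolerance,
                }
                for p in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ReferenceProfile":
        return cls(
            phases=tuple(Phase(**p) for p in raw["phases"]),
            heatup_target=raw.get("heatup_target", HEATUP_TARGET),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceProfile":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(path.read_text())
        else:
            raw = json.loads(path.read_text())
        return cls.from_dict(raw)

    def export_csv(self, path: str | Path, heatup_s: float = 0.0, dt: float = 1.0) -> None:
        """Write a two-column (step, t_ref) CSV, optionally with a heat-up
        prefix of ``heatup_s`` seconds at the heat-up target."""
        heatup_steps = int(round(heatup_s / dt))
        n = heatup_steps + int(round(self.total_duration / dt))
        with open(path, "w") as fh:
            fh.write("step,t_ref\n")
            for i in range(n + 1):
                fh.write(f"{i},{reference_at(self, i, heatup_steps, dt):.6f}\n")


def build_serving_profile(hold90_s: float = 60.0, hold57_s: float = 600.0) -> ReferenceProfile:
    """The product trajectory: 1 min at 90, 10 min at 60, then 57 degC.

    ``hold90_s`` tunes egg texture (longer -> firmer, adjusted in 10 s
    increments in practice); ``hold57_s`` is the keep-warm time, up to
    hours in deployment but 600 s by default for bounded episodes.
    """
    if hold90_s <= 0 or hold57_s <= 0:
        raise InvalidProfileError("hold durations must be positive")
    return ReferenceProfile(
        phases=(
            Phase("hold", 90.0, 90.0, hold90_s),
            Phase("ramp", 90.0, 60.0, 30.0),
            Phase("hold", 60.0, 60.0, 600.0),
            Phase("ramp", 60.0, 57.0, 5.0),
            Phase("hold", 57.0, 57.0, hold57_s),
        )
    )


def build_training_profile() -> ReferenceProfile:
    """The training trajectory: as serving, but 10 min at 90 degC."""
    return build_serving_profile(hold90_s=600.0, hold57_s=600.0)


def reference_at(
    profile: ReferenceProfile,
    step: int,
    heatup_end_step: int | None,
    dt: float = 1.0,
) -> float:
    """Reference temperature at a step index.

    ``heatup_end_step`` is the step at which the measured temperature first
    reached the heat-up target (None while still heating up).  Before that
    trigger the reference is the heat-up target; afterwards holds return
    their temperature and ramps interpolate linearly.  Beyond the last
    phase the final hold temperature persists.
    """
    if step < 0:
        raise ValueError("step must be non-negative")
    if heatup_end_step is None or step < heatup_end_step:
        return profile.heatup_target
    t = (step - heatup_end_step) * dt
    for ph in profile.phases:
        if t < ph.duration:
            if ph.kind == "hold":
                return ph.t_start
            return ph.t_start + (ph.t_end - ph.t_start) * t / ph.duration
        t -= ph.duration
    return profile.phases[-1].t_end
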