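"""Linearized thermal plant model of the egg cooker.

The cooker is a stirred water bath with a resistive heater and an on/off
cold-water exchange valve.  Per control step (``dt`` seconds) the medium
temperature changes by the sum of a heating and a cooling contribution,

    T_i = T_{i-1} + dT_heat + dT_cool
    dT_heat = heat_eff * P_heater * dt / (m_water * cp_water)
    dT_cool = cool_eff * valve * mdot * (T_cold - T_{i-1}) * dt / m_water

where ``heat_eff`` and ``cool_eff`` in [0, 1] model the lagged actuator
response: a counter is incremented while the actuator is commanded on and
decremented while it is off, clamped to [0, 2*delay]; the effective level is
``min(counter / delay, 1)``.  The clamp at twice the delay gives the
characteristic plateau memory — after long ON operation the effective level
stays saturated for about ``delay`` steps after switch-off.

There is no ambient heat-loss term: with both actuators off the temperature
holds exactly.  Measurement is the true temperature plus zero-mean Gaussian
noise.  Episode-to-episode variability of the real apparatus (load, supply
voltage, limescale, cold-water temperature) is captured by domain
randomization: each physical parameter is drawn uniformly from its
operational range at episode start.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CP_WATER",
    "PARAM_FIELDS",
    "TABLE_LIMITS",
    "NOMINAL_PARAMS",
    "PlantParams",
    "PlantState",
    "ActuatorCommand",
    "ActuationLevels",
    "InvalidLimitsError",
    "SimulationDivergedError",
    "load_limits",
    "sample_params",
    "effective_level",
    "update_counter",
    "step_plant",
    "measure",
    "actuation_levels",
    "effective_water_mass",
]

#: Specific heat of water, J/(kg K).  Fixed, not randomized.
CP_WATER = 4180.0

#: Randomized parameter names, in the canonical order of the limits table.
PARAM_FIELDS = (
    "m_water",
    "p_heater",
    "t_cold",
    "mdot",
    "delay_heat",
    "delay_cool",
    "sigma_noise",
)

#: Operational limits of the apparatus: {field: (min, nominal, max)}.
#: m_water kg, p_heater W, t_cold degC, mdot kg/s, delays in steps,
#: sigma_noise degC.
TABLE_LIMITS: dict[str, tuple[float, float, float]] = {
    "m_water": (5.00, 7.50, 12.00),
    "p_heater": (2300.0, 3600.0, 4800.0),
    "t_cold": (10.0, 20.0, 35.0),
    "mdot": (0.1, 0.2, 0.3),
    "delay_heat": (1.0, 2.5, 4.0),
    "delay_cool": (1.0, 2.0, 3.0),
    "sigma_noise": (0.01, 0.03, 0.05),
}


class InvalidLimitsError(ValueError):
    """A limits table entry has min > max or is missing a field."""


class SimulationDivergedError(FloatingPointError):
    """The simulated temperature became non-finite."""


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of one cooking episode.

    Attributes
    ----------
    m_water : float
        Mass of heated water (egg load folded in), kg.
    p_heater : float
        Heater power, W.
    t_cold : float
        Cooling-water temperature, degC (constant within an episode).
    mdot : float
        Cooling mass-flow rate at a fully open valve, kg/s.
    delay_heat, delay_cool : float
        Actuator response delays, in steps.  May be fractional.
    sigma_noise : float
        Measurement-noise standard deviation, degC.
    cp_water : float
        Specific heat of water, J/(kg K).
    """

    m_water: float
    p_heater: float
    t_cold: float
    mdot: float
    delay_heat: float
    delay_cool: float
    sigma_noise: float
    cp_water: float = CP_WATER

    def __post_init__(self) -> None:
        if self.m_water <= 0 or self.cp_water <= 0:
            raise ValueError("m_water and cp_water must be positive")
        if self.delay_heat < 1 or self.delay_cool < 1:
            raise ValueError("actuator delays must be >= 1 step")
        if self.mdot < 0 or self.sigma_noise < 0:
            raise ValueError("mdot and sigma_noise must be non-negative")

    @classmethod
    def from_fixture(cls, which: str) -> "PlantParams":
        """Return the min / nominal / max column of the limits table."""
        col = {"min": 0, "nominal": 1, "max": 2}
        if which not in col:
            raise ValueError(f"unknown fixture {which!r}; expected min|nominal|max")
        k = col[which]
        return cls(**{f: TABLE_LIMITS[f][k] for f in PARAM_FIELDS})

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class PlantState:
    """Evolving state of the simulator."""

    t_true: float
    count_heat: float = 0.0
    count_cool: float = 0.0
    step_index: int = 0


@dataclass(frozen=True)
class ActuatorCommand:
    """Commanded binary actuator states for one step.

    ``valve_fraction`` scales the cooling mass flow; it is 1.0 except in
    deployment mode, where fine cooling near the setpoint uses a 20%-open
    valve.
    """

    heating: int
    cooling: int
    valve_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.heating not in (0, 1) or self.cooling not in (0, 1):
            raise ValueError("heating and cooling must be binary")
        if not 0.0 < self.valve_fraction <= 1.0:
            raise ValueError("valve_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ActuationLevels:
    """Effective (lag-filtered) actuation fractions, both in [0, 1]."""

    heat_eff: float
    cool_eff: float


def load_limits(path: str | Path) -> dict[str, tuple[float, float, float]]:
    """Load a limits table from YAML or JSON.

    The file maps each parameter name to ``[min, nominal, max]`` (or
    ``[min, max]``, in which case the nominal is the midpoint).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    table: dict[str, tuple[float, float, float]] = {}
    for field in PARAM_FIELDS:
        if field not in raw:
            raise InvalidLimitsError(f"limits table missing field {field!r}")
        vals = [float(v) for v in raw[field]]
        if len(vals) == 2:
            vals = [vals[0], 0.5 * (vals[0] + vals[1]), vals[1]]
        if len(vals) != 3:
            raise InvalidLimitsError(f"{field}: expected [min, nominal, max]")
        table[field] = (vals[0], vals[1], vals[2])
    return table


def _validate_limits(limits: dict[str, tuple[float, float, float]]) -> None:
    for field in PARAM_FIELDS:
        if field not in limits:
            raise InvalidLimitsError(f"limits table missing field {field!r}")
        lo, *_, hi = limits[field]
        if lo > hi:
            raise InvalidLimitsError(f"{field}: min {lo} > max {hi}")


#: Nominal-column fixture, the mid column of the limits table.
NOMINAL_PARAMS = PlantParams.from_fixture("nominal")


def sample_params(
    rng: np.random.Generator | int,
    limits: dict[str, tuple[float, float, float]] | None = None,
) -> PlantParams:
    """Draw one episode's plant parameters by domain randomization.

    Each field is drawn independently and uniformly from its [min, max]
    range.  ``rng`` may be a Generator or an integer seed; the same seed
    yields identical parameters.
    """
    if limits is None:
        limits = TABLE_LIMITS
    _validate_limits(limits)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = {f: float(rng.uniform(limits[f][0], limits[f][-1])) for f in PARAM_FIELDS}
    return PlantParams(**draws)


def effective_level(count: float, delay: float) -> float:
    """Effective actuation fraction ``min(count / delay, 1)``."""
    if delay <= 0:
        raise ValueError(f"delay must be positive, got {delay}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return min(count / delay, 1.0)


def update_counter(count: float, commanded_on: bool, delay: float) -> float:
    """Advance an actuator's ON-counter one step, clamped to [0, 2*delay]."""
    count = count + 1.0 if commanded_on else count - 1.0
    return min(max(count, 0.0), 2.0 * delay)


def step_plant(
    state: PlantState,
    params: PlantParams,
    command: ActuatorCommand,
    dt: float = 1.0,
) -> PlantState:
    """Advance the plant one step under the given actuator command.

    Counters are updated from the command first, then the effective levels
    drive the temperature update.  Returns a new state; the input state is
    not mutated.
    """
    count_heat = update_counter(state.count_heat, bool(command.heating), params.delay_heat)
    count_cool = update_counter(state.count_cool, bool(command.cooling), params.delay_cool)
    heat_eff = effective_level(count_heat, params.delay_heat)
    cool_eff = effective_level(count_cool, params.delay_cool)

    d_heat = heat_eff * params.p_heater * dt / (params.m_water * params.cp_water)
    # cp cancels between the flow enthalpy and the bath heat capacity.
    d_cool = (
        cool_eff
        * command.valve_fraction
        * params.mdot
        * (params.t_cold - state.t_true)
        * dt
        / params.m_water
    )
    t_new = state.t_true + d_heat + d_cool
    if not math.isfinite(t_new):
        raise SimulationDivergedError(f"temperature diverged at step {state.step_index}")
    return PlantState(
        t_true=t_new,
        count_heat=count_heat,
        count_cool=count_cool,
        step_index=state.step_index + 1,
    )


def measure(state: PlantState, params: PlantParams, rng: np.random.Generator) -> float:
    """Measured temperature: true value plus Gaussian sensor noise."""
    if params.sigma_noise == 0.0:
        return state.t_true
    return state.t_true + params.sigma_noise * float(rng.standard_normal())


def actuation_levels(state: PlantState, params: PlantParams) -> ActuationLevels:
    """Current effective (lag-filtered) actuation fractions of a state."""
    return ActuationLevels(
        heat_eff=effective_level(state.count_heat, params.delay_heat),
        cool_eff=effective_level(state.count_cool, params.delay_cool),
    )


def effective_water_mass(
    m_water: float,
    n_eggs: int = 0,
    m_egg: float = 0.058,
    cp_egg: float = 3500.0,
) -> float:
    """Water-equivalent thermal mass of water plus an egg load.

    Eggs are folded into the water mass through the ratio of specific heats
    (hen's egg cp roughly 3300-3700 J/(kg K); default mid-range, 58 g egg).
    The randomization range of ``m_water`` already spans realistic loads, so
    this helper is for explicit what-if studies only.
    """
    if n_eggs < 0:
        raise ValueError("n_eggs must be non-negative")
    return m_water + n_eggs * m_egg * cp_egg / CP_WATER
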