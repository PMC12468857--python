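# Methods

This note documents the models, design choices and limitations behind
`softboil`: a simulation-trained reinforcement-learning temperature
controller for cooking pasteurized soft-boiled eggs.

## The control problem

Eggs are cooked in a stirred water bath with two on/off actuators: a
resistive heater (kW scale) and a valve admitting cold water from a
surrounding reservoir. The product requires a staged temperature
trajectory: heat to 90 °C, hold briefly to set the white's texture, cool to
60 °C and hold 10 min (pasteurization — *Salmonella* inactivation requires
T ≥ 60 °C for ≥ 10 min), then cool to 57 °C and keep warm. The actuators
are strongly asymmetric — full cooling moves the bath roughly ten times
faster than full heating near the working point — and both respond with a
dead time of a few seconds, which rules out a conventional PID loop. The
controller must also be robust to load (water mass and egg count), supply
voltage, cold-water temperature and heater fouling, none of which are known
exactly at run time.

## Plant model (`softboil.plant`)

A linearized lumped model advances the bath temperature once per control
step (Δt = 1 s):

    T_i = T_{i−1} + heat'·P·Δt/(m·c_p) + cool'·v·ṁ·(T_cold − T_{i−1})·Δt/m

with `m` the water mass [kg], `P` the heater power [W], `c_p` = 4180
J/(kg·K), `ṁ` the cooling mass flow at a fully open valve [kg/s], `T_cold`
the reservoir temperature [°C] and `v ∈ (0,1]` the valve fraction. The
specific heat cancels in the cooling term (flow enthalpy vs. bath
capacity). Actuator lag is modelled by a counter per actuator,
incremented while commanded on and decremented while off, clamped to
[0, 2·delay]; the effective actuation is `min(counter/delay, 1)`. The
clamp gives the observed switch-off memory: after long ON operation the
effective level remains saturated for about `delay` steps. Delays may be
fractional (the nominal heating delay is 2.5 steps); counters stay integer
and the ratio handles the fraction.

Deliberate simplifications:

* **No ambient heat-loss term.** With both actuators off the temperature
  holds exactly. This matches the linearized model of the well-insulated
  apparatus; it also means idling is free, which shapes what the learned
  policy converges to.
* **Infinite cold reservoir** at a constant per-episode `T_cold`, so
  cooling decays exponentially toward `T_cold` and can never cross it
  (ṁ·Δt/m < 1 over the whole parameter space).
* **Egg load folded into the water mass** via the specific-heat ratio
  (`effective_water_mass`); the randomized mass range is treated as
  already inclusive of realistic loads.
* **Measurement noise** is zero-mean Gaussian added per step to the true
  temperature; its standard deviation σ is an episode constant, drawn with
  the other parameters (sensor quality does not drift within one cook).

### Domain randomization

At each episode start every physical parameter is drawn independently and
uniformly from its operational range (uniform = the maximum-entropy choice
when only limits are known):

| parameter | min | nominal | max | unit |
|---|---|---|---|---|
| water mass | 5.0 | 7.5 | 12.0 | kg |
| heater power | 2300 | 3600 | 4800 | W |
| cold-water temperature | 10 | 20 | 35 | °C |
| cooling mass flow | 0.1 | 0.2 | 0.3 | kg/s |
| heating delay | 1 | 2.5 | 4 | steps |
| cooling delay | 1 | 2 | 3 | steps |
| noise σ | 0.01 | 0.03 | 0.05 | °C |

The ranges absorb real-world variability that is not modelled explicitly:
supply-voltage variation (heater power), limescale fouling (delays),
ambient and casing temperatures (cold-water range). The initial water
temperature is drawn uniformly from 15–30 °C; it only shifts the length of
the supervised heat-up phase.

## Reference profiles (`softboil.profiles`)

The serving profile is: heat-up → hold 90 °C (60 s, the texture knob,
adjustable in 10 s steps) → ramp 90→60 °C (30 s) → hold 60 °C (600 s,
pasteurization) → ramp 60→57 °C (5 s) → hold 57 °C (600 s by default;
keep-warm can last hours in deployment). The training variant extends the
90 °C hold to 600 s so the learner sees as much time near 90 °C as near
the lower setpoints. Post-heat-up lengths are 1295 s (serving) and 1835 s
(training). Ramps are linear; any smooth alternative is unobservable at
Δt = 1 s. During heat-up the reference is the 90 °C target, so the error
signal is defined everywhere (the supervisor, not the agent, governs most
of heat-up anyway).

**Profile clock trigger.** The post-heat-up clock starts at the first step
whose *measured* temperature crosses the lower edge of the first hold's
tolerance band, 90 − 2 = 88 °C (configurable via
`EnvConfig.heatup_trigger_temp`). Band-edge triggering, rather than an
exact 90 °C crossing, is a deliberate choice with a learnability argument
behind it: the hand-coded supervisor hands control to the agent at 87 °C,
the reward's idle bonus makes heating locally unattractive inside the
band, and the plant has no heat loss — so with an exact-90 trigger an
untrained policy freezes just above 87 °C, the profile clock never starts,
and no amount of value-based training can discover the holds (reaching
them would need ~26 consecutive exploratory heat actions). With the
88 °C trigger the profile always runs, every episode exposes the learner
to all phases, and a trained agent closes the remaining 2 °C within
seconds of the hold starting.

## Control environment (`softboil.env`)

The environment exposes the standard episodic RL interface (reset/step,
4 discrete actions = heater × valve, 60-dimensional observation) without
depending on an external RL framework.

* **Supervisor gating.** Full-power heating until the measured temperature
  first reaches 87 °C; bang-bang control (heat below / cool above the
  reference) whenever |error| ≥ 3 °C; the agent acts only inside the band.
  Supervisor steps advance internally without consuming agent decisions,
  and their rewards are logged but excluded from the learning signal, so
  the policy is trained only on states it is responsible for. The
  bang-bang rule carries no hysteresis; the gate itself separates regimes.
* **Observation** (per step, 10-lag history, most recent first): measured
  temperature, reference, error, 10-step slope, and the two commanded
  actuator states — the *commanded* states, because a real controller
  cannot observe the lag-filtered effective levels. Missing lags at
  episode start replicate the earliest record. Values are raw °C and °C/s
  by default, matching standard MLP-on-raw-inputs practice for this kind
  of controller; `EnvConfig.normalize_obs` optionally rescales the two
  temperature channels by 0.01, which speeds up early learning but is not
  needed at the shipped training scale.
* **Reward** (on measured temperature): −1 per step, −|e|, the error
  improvement |e₋₁| − |e|, nested proximity bonuses +10/+100/+150/+200
  below 1/0.5/0.1/0.05 °C, +100 for being within 0.5 °C while the measured
  temperature moved less than 0.05 °C, −10 per actuator-command change,
  −100 for cooling while below reference, −100 for heating while more than
  0.1 °C above, and +10 for idling. The idle bonus applies at any error
  magnitude, as designed.
* **Episode end**: when the final hold completes (terminated) or at 5000
  steps (truncated — e.g. when an untrained policy stalls heat-up).
* The deployment-only rule (valve restricted to 20 % when |e| < 2 °C) is
  off during training and simulation evaluation; it reflects a
  real-apparatus adjustment where full cooling proved too coarse.

## DQN training (`softboil.dqn`)

Standard deep Q-learning, written on NumPy: MLP 60→64→64→4 with ReLU,
uniform ±1/√fan_in initialization, ε-greedy behaviour, uniform replay,
hard target-network updates, smooth-L1 (Huber) TD loss, Adam, global
gradient-norm clipping. Hyperparameters are the widely used library
defaults for low-dimensional DQN: lr 1e-4, buffer 1e6, learning starts
100, batch 32, τ 1.0, γ 0.99, train frequency 4, 1 gradient step, target
update every 10 000 steps, ε 1.0→0.05 over the first 10 % of training,
max gradient norm 10. Checkpoints are snapshotted every 50 000 steps by
default, each evaluated greedily on a fixed seed set; the best checkpoint
by mean episode reward (the quantity the training curve reports) is
selected, ties going to the later step.

### Problem sizes and what they show

The full study protocol trains for 10 M agent steps with checkpoints
every 50 k. The package's acceptance run and test suite use a reduced
6 M-step budget (checkpoints every 250 k, 3 evaluation episodes per
checkpoint, replay capped at 500 k), chosen once from the learning-curve
shape: greedy performance takes off once the value estimates reach the
scale of the hold bonuses (~1–2.5 M steps) and checkpoint quality
plateaus around 5–6 M; a full 10 M run improves the best checkpoint no
further (3-episode eval mean MSE 0.023 at 5.75 M vs 0.029 for the 10 M
best). The compute-heavy kernels (network forward/backward, Adam) are
numba-compiled, so a 6 M-step run takes roughly ten minutes on one CPU
core. Batch evaluation uses 50 randomized episodes (the full protocol
uses 300); with all parameters drawn uniformly, 50 draws already probe
the load corners well.

A note on value scale: tight tracking earns ~570 per step, so true Q
values reach ~5·10⁴ while the Huber loss clips every TD gradient — Q
estimates therefore grow roughly linearly in update count, which is what
makes the takeoff late, and absolute calibration is never reached.
Action *ranking*, which is what the greedy policy uses, converges once
the staircase shape of the value function (steps at the bonus
thresholds) is in place.

### Known behaviour at the randomization corners

A converged policy holds every constant-temperature phase to within
±0.05 °C of the reference. The residual tracking error is concentrated
at the hold *entries* and is structural rather than a training artifact:
in draws whose cooling capacity ṁ·(T − T_cold)/m falls below the ramp's
1 °C/s, the supervisor (not the agent) rides the ramp with a saturated
cooling counter, and the counter's drain after handover delivers
rate × ~1.5·delay ≈ 3–5 °C of undershoot that nothing can cancel — the
heater is an order of magnitude weaker, and the reward sanctions heating
while above reference during the coast. Recovery at the weakest heating
rates (0.046 °C/s) takes ~1 min. Per-run MSE over the post-cooling
window therefore spans ~0.003 (favourable draws) to ~0.4 °C² (weak
cooling and weak heating together), even for a fully converged policy.
Similarly, episode rewards during training keep a wide spread at any
step count: ε stays at 0.05, and each residual random action can destroy
several steps of ~570/step bonus streaks, so per-episode totals vary by
tens of percent around their ceiling.

## Evaluation (`softboil.evaluation`)

* **Tracking MSE** — mean of (measured − reference)² from the point the
  cooled curve first reaches 60 °C to episode end. This window covers the
  pasteurization hold, the 60→57 ramp and the keep-warm hold. The
  alternative anchor (window opening directly at the end of the 90 °C
  hold) is available but not the default, because it additionally scores
  the 90→60 ramp, whose feasibility is set by the drawn cooling capacity
  rather than by the controller: near 60 °C the maximum cooling rate
  ṁ·(60 − T_cold)/m ranges from 0.21 to 3 °C/s across the parameter
  space, so roughly half of all draws physically cannot follow the
  −1 °C/s ramp tail and would accumulate multi-°C errors that no policy
  can avoid, inflating the metric by two orders of magnitude.
* **Pasteurization time** — the longest *contiguous* run at or above
  60 °C ("maintained" is read strictly: a dip below the threshold restarts
  the clock), computed on the simulator's true temperature in simulation
  reports and on the measured channel for imported CSV logs. Compliance
  requires ≥ 600 s. Note a structural caveat: the pasteurization setpoint
  *equals* the threshold, so a controller that holds 60.00 °C with
  symmetric fluctuations breaks the contiguous run at every downward
  crossing; observed compliance in simulation therefore depends on which
  side of 60 °C the policy happens to settle, and on the heat-up leg
  (which contributes its above-60 portion to the same contiguous run).
* Batch evaluation re-randomizes the plant each run, is deterministic
  given its seed, and serializes to JSON + CSV losslessly.

## What the simulation does not show

Passing these checks demonstrates control of the idealized lumped model:
a single well-mixed water temperature, linear actuation with delay ramps,
Gaussian sensor noise. It does not demonstrate spatial temperature
gradients, convective mixing artifacts, mid-yolk conduction (the quantity
pasteurization ultimately cares about), sensor placement effects, or any
real-hardware behaviour — physical apparatus, microcontroller interfaces
and hardware redesign are out of scope, and no real-system measurement is
reproduced or claimed here.

## Numerical and degenerate-input conventions

* Same seed ⇒ bitwise-identical parameter draws, episodes, training logs
  and reports; a single top-level seed is expanded via `SeedSequence`.
* `argmax` over Q ties resolves to the lowest action index (NumPy
  convention); checkpoint-selection ties resolve to the later step.
* Counter clamping makes the delay-ramp well-defined at the boundaries;
  a non-finite simulated temperature raises immediately.
* Zero-length holds, empty histories, empty checkpoint lists, invalid
  limits (min > max) and out-of-range actions raise typed errors rather
  than propagating silently.
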