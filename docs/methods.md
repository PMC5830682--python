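# Methods

`cyberslug` is a headless, fully seeded re-implementation of the
Cyberslug agent: a neuroeconomic model of approach-avoidance foraging
decision in the predatory sea-slug *Pleurobranchaea californica*,
originally published as an interactive NetLogo model.  The package
reproduces the model's decision equations and its batch
learning x satiation prey-selectivity experiments as a library plus CLI.
This note records the model, the parameterization, and the design
decisions taken where the published description leaves the
implementation open.

## The model

A single predator forages on a 2D toroidal grid among random-walking
prey of two species: Hermi (benign, rewarding; after *Hermissenda
crassicornis*) and Flab (noxious; after *Flabellina iodinea*), plus an
optional Batesian mimic, Faux-Flab (Flab's odor, Hermi's reward).  Every
prey deposits two odors into its grid cell each step — betaine, an
innate resource signal, and a species signature odor — and the fields
diffuse (8-neighbor exchange of a fraction `diffusion_rate`, NetLogo
`diffuse` style) and decay multiplicatively each step.

The agent carries two anterior sensors (±40° off the midline, 0.45 body
lengths ahead).  Each reports `log10(1 + c/floor)` of the local
concentration per odor channel; per-odor readings are averaged across
sensors.  From these:

* **Somatic map** — a signed place code of stimulus laterality:
  `SM = (flabL − flabR)·σ(k0·F) + (hermiL − hermiR)·σ(k0·H)` with
  `F = flab − hermi = −H` and σ the logistic.  The gates implement
  surround suppression: only the locally dominant signature odor steers.
* **Incentive** — `I = R⁺ − R⁻`, with
  `R⁺ = betaine/(1 + k1·Vh·hermi) + k3·Vh·hermi` and
  `R⁻ = k3·Vf·flab`, where Vh and Vf are Rescorla-Wagner associative
  strengths (`ΔV = α·β·(λ − V)`, α = 0.5, β = 1, λ = 1) updated once per
  prey consumed.  A naive agent tracks betaine alone.
* **Satiation** — `S = 1/(1 + k4·e^(−4N+2))²` of nutrition `N`, which
  decays by 0.0005·N per step, gains 0.3 per meal, and starts at 0.8.
* **Appetitive state** —
  `A = 0.01 + logistic(k5·I − k6·S) + k7·(switch_prev − 1)`, using the
  previous step's switch (the turn-network feedback is time-lagged).
* **Switch** — `sw = −2·logistic(k8·(A − 0.245)) + 1`: ≈ +1 (avoid)
  when appetitive state is below the 0.245 threshold, ≈ −1 (approach)
  above it.
* **Turn** — when any averaged reading exceeds the engagement threshold
  the agent turns by `k9·sw/(1 + e^(3·SM − sw))` degrees, mirrored onto
  the side indicated by the somatic map (see below); otherwise it
  wanders with uniform ±1° heading jitter.  It then advances at constant
  speed; prey within the consumption radius of its mouth are eaten and
  replaced at random positions.

Per-step update order: prey move → odors deposit/diffuse/decay →
sense → incentive → satiation → appetitive state (previous switch) →
switch → turn → advance → consume/learn.

## Motor-side resolution

The published turn equation carries the approach/avoid polarity in its
sign and modulates magnitude by the somatic map, but a scalar cannot
also encode which *side* to turn.  Applied literally one-sided, the
agent can only spiral clockwise toward (or away from) a stimulus:
avoidance fails head-on and approach is inefficient.  Since the model
describes the somatic map as the somatotopic *template* of the turn, the
step loop uses its sign to select the motor side: the heading change is
negated when the stimulus lies to the left.  In approach mode the agent
then turns toward the stimulus on either side, and in avoidance away
from it, with the published magnitude law; the turn-angle function
itself is unchanged.

## Parameterization

The learning parameters, nutrition dynamics, switch threshold, wander
amplitude, and the interface anchor points of the switch (A = 0.545 →
sw ≈ −1; A = 0.029 → sw ≈ +1) are fixed by the published description.
All remaining coefficients and every environmental constant are not
stated there; they were calibrated here, once, so that the model
operates in the published regime (a permanently hungry agent consumes
roughly one prey per 200 steps in the 13-prey arena; satiation-limited
conditions equilibrate near the published totals; learning without
satiation leaves behavior essentially unchanged).  Defaults:

| group | values |
|---|---|
| arena | 50 x 50 cells, torus, diffusion_rate 0.5, decay_rate 0.08, emission 0.5/step/odor, consumption radius 1.2 cells |
| prey | step 0.02 cells/step, heading jitter ±30° |
| agent | body length 3 cells, speed 0.06 cells/step, sensor floor 1e-3, engagement threshold 0.3 |
| gains | k0 10, k1 0.3, k3 1.2, k4 0.7, k5 1.3, k6 7.6, k7 0.05, k8 50, k9 8 |

Rationale for the load-bearing ones:

* **k8 = 50** makes the switch effectively a relay while matching the
  published anchor points to <1e-3.
* **k4 = 0.7, k5 = 1.3, k6 = 7.6** place the satiation equilibria: a
  naive agent stops approaching betaine plumes near S* ≈ 0.32
  (nutrition ≈ 0.48), a Flab-trained agent approaches flab plumes only
  below S ≈ 0.1 (near-starvation), and a Hermi-trained agent keeps
  approaching hermi plumes up to S ≈ 0.6.  Because consumption balances
  nutrition decay at 0.0005·N per step, each equilibrium nutrition level
  N̄ fixes a 150,000-step consumption total of ≈ 250·N̄, which is how
  these constants were pinned against the published totals.
* **k3 = 1.2** makes a fully learned flab plume mildly net-aversive
  (I < 0 throughout the plume) — strong enough that a moderately fed
  agent refuses it, weak enough that a starving or satiation-clamped
  agent still attacks, which is what leaves learning-only behavior
  indistinguishable from the naive condition.
* **k0 = 10** gives hard surround suppression, keeping the agent locked
  on the nearest signature plume and reducing incidental Flab captures
  while homing on Hermi.
* **k9 = 8** (degrees/step of maximal turn) gives the agent enough turn
  authority at cruise speed to veer out of a Flab plume discovered a few
  cells ahead, and to capture prey it is homing on; much smaller values
  produce head-on collisions with plumes the agent intended to refuse.
* **sensor floor 1e-3** keeps the log-readings of the dilute inter-plume
  background near zero so that plumes stand out; with a much smaller
  floor every reading saturates several log-units above zero and all
  spatial contrast vanishes.
* **engagement threshold 0.3** separates in-plume decision turning from
  open-field search; with a vanishing threshold the agent is always
  "engaged" and circles instead of covering ground.  `scripts/calibrate.py`
  prints the steady-state plume profile for any config; with the default
  field constants a lone prey's plume crosses the engagement threshold
  at roughly three body lengths, a deliberately tight radius - wider
  plumes flood the small arena with overlapping background odor and the
  agent loses the contrast it steers by.

All of these are plain config fields; none is hard-coded.

## Mechanism toggles

* `learning_enabled=False` freezes Vh = Vf = 0.
* `satiation_enabled=False` pins the satiation value fed to the
  appetitive state at its zero-nutrition value (permanent hunger);
  nutrition itself is still tracked for the trace.

## Faux-Flab

The mimic deposits on the flab odor channel but confers Hermi's
consequences: +0.3 nutrition and an extinction-style Rescorla-Wagner
update of Vf toward 0.  This is one defensible rendering of "Flab's
odor with Hermi's rewarding qualities"; it is isolated in
`learning.on_consumption` and off by default (`n_fauxflab = 0`).

## What the experiments emulate — and what they do not

`experiments.standard_scenarios()` reproduces the published protocol:
four learning x satiation conditions in a 10-Flab/3-Hermi arena plus
13-Flab-only and 13-Hermi-only controls, six trials of 150,000 steps,
reporting totals, Hermi percentage and the selectivity ratio
(Hermis/Flabs consumed, undefined when no Flab is taken) with mean and
SEM (sd/√n).  Per-trial seeds derive from one master seed through
`SeedSequence` spawn keys and are recorded in the output, so any row is
replayable.

With the calibrated defaults the qualitative structure of the published
experiments is robustly reproduced: selectivity requires learning and
satiation *together* (≥5x every other condition), satiation caps
consumption (no-satiation ≫ satiation-only > both), and positive versus
negative learning separates the single-species arenas (13-Hermi ≫
13-Flab).  Quantitatively, most condition means land within ~10% of the
published values; the strongest known deviation is the selectivity
coefficient of the both-mechanisms condition, which here settles around
3–4 rather than ≈5: the re-derived environment produces a few more
incidental Flab captures per trial (each one directly deflates the
ratio) than the original parameterization apparently did.  Since the
original implementation's tuned constants are not part of the published
model description, this residual is a calibration gap, not a structural
one.

The synthetic environment is a caricature of real chemosensory scenes:
no currents or turbulent plume structure, point prey with equal odor
emission, no prey evasion, and abstract time steps.  Passing tests show
the decision circuit reproduces the model's behavioral regimes, not that
it predicts field behavior of real *Pleurobranchaea*.

## Numerical choices

Double precision throughout; logistic evaluated in the numerically
stable branch form; diffusion via an in-place separable 3x3 neighbor sum
(exact mass conservation on the torus to ~1e-15 per step, verified to
1e-9 over tests); nearest-cell sensor lookup without interpolation
(matching the patch-based original); torus metric for all distances;
heading stored in degrees, positive turns counterclockwise.  The steep
switch sigmoid saturates to exactly ±1.0 in floats far from threshold —
tests of its open-interval property therefore probe the unsaturated
neighborhood of the threshold.

## Known limitations

* No interactive GUI, mouse control, or live rendering (headless by
  design); `plotting.plot_path` gives a static path figure.
* Inferential statistics (ANOVA/post-hoc) are out of scope; the tidy
  per-trial CSV is meant for external analysis.
* No explicit pain pathway, habituation, sensitization, or modulation of
  the 0.245 threshold; β of the learning rule is fixed at 1 (all
  config-exposed).
* One odor-deposit/diffusion step per agent step; sub-step concurrency
  of the original turn-taking scheduler is not emulated.
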