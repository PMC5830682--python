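"""The affective homeostat: incentive, satiation, appetitive state, turns.

This is the decision core of the agent.  Sensory readings and the two
learned odor associations are folded into a signed *incentive*; nutrition
drives a sigmoidal *satiation*; both meet in the *appetitive state*,
whose level against a fixed threshold (0.245) sets a smooth switch
between avoidance (switch near +1) and approach (switch near -1).  The
switch and the somatic map together determine the turn executed this
step; away from any odor the agent wanders with tiny random heading
changes.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import Constants
from .sensorium import SensorReading, _logistic


def incentive(reading: SensorReading, Vh: float, Vf: float,
              c: Constants) -> tuple[float, float, float]:
    """Net stimulus value from innate and learned odor components.

    Returns ``(r_plus, r_minus, incentive)`` where

    * ``r_plus``  = betaine / (1 + k1*Vh*hermi) + k3*Vh*hermi - the
      innate resource signal, progressively eclipsed by the learned
      positive hermi association as Vh grows;
    * ``r_minus`` = k3*Vf*flab - the learned aversive flab association;
    * ``incentive`` = r_plus - r_minus.

    A naive agent (Vh = Vf = 0) reduces to pure betaine tracking.
    """
    r_plus = reading.betaine / (1.0 + c.k1 * Vh * reading.hermi) + c.k3 * Vh * reading.hermi
    r_minus = c.k3 * Vf * reading.flab
    return r_plus, r_minus, r_plus - r_minus


def update_nutrition(nutrition: float, n_consumed: int, c: Constants) -> float:
    """One step of the nutrition recursion.

    Nutrition loses a fixed fraction (0.0005) per step and gains 0.3 for
    every prey item consumed this step.
    """
    return nutrition * (1.0 - c.nutrition_decay) + c.feed_gain * n_consumed


def satiation(nutrition: float, c: Constants) -> float:
    """Sigmoid fullness signal in (0, 1), strictly increasing in nutrition.

    satiation = 1 / (1 + k4 * exp(-4*nutrition + 2))**2
    """
    return 1.0 / (1.0 + c.k4 * math.exp(-4.0 * nutrition + 2.0)) ** 2


def app_state(incentive_value: float, satiation_value: float,
              prev_switch: float, c: Constants) -> float:
    """Appetitive state: the excitation level of the virtual feeding network.

    app_state = 0.01 + logistic(k5*incentive - k6*satiation)
                + k7*(prev_switch - 1)

    The last term uses the switch value of the *previous* step (the
    feedback from the turn network is inherently time-lagged) and
    vanishes when that switch sat at +1.
    """
    return (
        c.app_state_baseline
        + _logistic(c.k5 * incentive_value - c.k6 * satiation_value)
        + c.k7 * (prev_switch - 1.0)
    )


def app_state_switch(app_state_value: float, c: Constants) -> float:
    """Smooth approach-avoidance switch in (-1, 1).

    switch = -2 * logistic(k8*(app_state - threshold)) + 1

    Near +1 when appetitive state is well below the 0.245 threshold
    (avoid), near -1 well above it (approach), exactly 0 at threshold.
    Strictly decreasing in appetitive state.
    """
    return -2.0 * _logistic(c.k8 * (app_state_value - c.switch_threshold)) + 1.0


def turn_angle(switch: float, somatic_map_value: float, c: Constants) -> float:
    """Signed heading change (degrees) for an engaged agent.

    turn = k9 * switch / (1 + exp(3*somatic_map - switch))

    The sign follows the switch (positive = avoidance = counterclockwise
    here), the magnitude is modulated by stimulus laterality so the
    agent spirals onto (or away from) the odor source.
    """
    return c.k9 * switch / (1.0 + math.exp(3.0 * somatic_map_value - switch))


def wander_turn(rng: np.random.Generator) -> float:
    """Exploratory heading jitter: uniform in [-1, 1) degrees."""
    return -1.0 + rng.uniform(0.0, 2.0)
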