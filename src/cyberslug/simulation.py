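"""Per-step agent update cycle.

One time step advances the world and the agent in a fixed order:

1.  prey take a random-walk step;
2.  prey deposit odor, fields diffuse and decay;
3.  the sensors are sampled and the somatic map computed;
4.  incentive is formed from the current associations Vh/Vf;
5.  satiation is computed from nutrition (or held at its permanently
    hungry value when the satiation mechanism is disabled);
6.  appetitive state is computed using the previous step's switch;
7.  the switch is updated from the new appetitive state;
8.  a turn is chosen: the decision turn when any averaged odor reading
    exceeds the engagement threshold, otherwise a wander jitter;
9.  the agent advances along its new heading;
10. prey within the consumption radius of the mouth are eaten; nutrition
    and the odor associations are updated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import decision as _decision
from .arena import ArenaConfig, World, consume_and_respawn, deposit_and_diffuse, move_prey
from .constants import Constants
from .learning import LearningState, on_consumption
from .sensorium import SensorGeometry, sample, sensor_positions, somatic_map

#: Default forward speed of the agent, cells per step.
DEFAULT_AGENT_SPEED = 0.06
#: Averaged odor reading above which the agent counts as engaged with a
#: stimulus and uses the decision turn instead of wandering.
DEFAULT_ENGAGE_THRESHOLD = 0.3
#: Floor concentration of the logarithmic sensor transform.
DEFAULT_SENSOR_FLOOR = 1e-3


@dataclass
class Agent:
    """Mutable state of the forager, including its behavior toggles."""

    x: float
    y: float
    heading: float
    nutrition: float
    learning: LearningState = field(default_factory=LearningState)
    satiation_enabled: bool = True
    speed: float = DEFAULT_AGENT_SPEED
    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    engage_threshold: float = DEFAULT_ENGAGE_THRESHOLD
    sensor_floor: float = DEFAULT_SENSOR_FLOOR
    # per-step readouts (the interface variables of the original model)
    satiation: float = 0.0
    incentive: float = 0.0
    app_state: float = 0.0
    switch: float = 1.0
    turn: float = 0.0
    # running tallies
    consumed: dict = field(default_factory=lambda: {"flab": 0, "hermi": 0, "fauxflab": 0})
    last_consumed: list = field(default_factory=list)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def mouth_position(self) -> np.ndarray:
        """The mouth sits at the front of the body."""
        r = 0.5 * self.geometry.body_length
        rad = math.radians(self.heading)
        return np.array([self.x + r * math.cos(rad), self.y + r * math.sin(rad)])


def make_agent(config: ArenaConfig, rng: np.random.Generator,
               constants: Constants, *,
               learning_enabled: bool = True,
               satiation_enabled: bool = True,
               speed: float = DEFAULT_AGENT_SPEED,
               geometry: SensorGeometry | None = None) -> Agent:
    """Agent at the arena center with a random initial heading."""
    agent = Agent(
        x=config.width / 2.0,
        y=config.height / 2.0,
        heading=rng.uniform(0.0, 360.0),
        nutrition=constants.nutrition_init,
        learning=LearningState(enabled=learning_enabled),
        satiation_enabled=satiation_enabled,
        speed=speed,
        geometry=geometry if geometry is not None else SensorGeometry(),
    )
    # the switch starts in its default avoidance pole
    agent.switch = 1.0
    return agent


def step(world: World, agent: Agent, constants: Constants) -> tuple[World, Agent]:
    """Advance world and agent by one time step (see module docstring).

    Mutates both arguments in place and returns them; the species eaten
    this step are available as ``agent.last_consumed``.
    """
    c = constants
    move_prey(world)
    deposit_and_diffuse(world)

    left, right = sensor_positions((agent.x, agent.y), agent.heading, agent.geometry)
    reading = sample(world, left, right, agent.sensor_floor)
    sm = somatic_map(reading, c.k0)

    _, _, inc = _decision.incentive(reading, agent.learning.Vh, agent.learning.Vf, c)
    if agent.satiation_enabled:
        sat = _decision.satiation(agent.nutrition, c)
    else:
        # permanently hungry: satiation pinned at its zero-nutrition value
        sat = _decision.satiation(0.0, c)
    app = _decision.app_state(inc, sat, agent.switch, c)
    switch = _decision.app_state_switch(app, c)

    if reading.max_reading() > agent.engage_threshold:
        turn = _decision.turn_angle(switch, sm, c)
        # The somatic map is the template for the turn: its sign (which
        # side the stimulus is on) selects the motor side, the decision
        # turn supplies amplitude and approach/avoid polarity.  With the
        # convention positive-heading-change = leftward, a stimulus on
        # the right (sm < 0) maps an approach turn (negative) to the
        # right and an avoidance turn (positive) to the left.
        if sm > 0.0:
            turn = -turn
    else:
        turn = _decision.wander_turn(world.rng)

    agent.heading = (agent.heading + turn) % 360.0
    rad = math.radians(agent.heading)
    agent.x += agent.speed * math.cos(rad)
    agent.y += agent.speed * math.sin(rad)
    if world.config.wrap:
        agent.x %= world.config.width
        agent.y %= world.config.height
    else:
        agent.x = min(max(agent.x, 0.0), world.config.width - 1e-9)
        agent.y = min(max(agent.y, 0.0), world.config.height - 1e-9)

    _, consumed = consume_and_respawn(world, agent.mouth_position())
    n_meals = len(consumed)
    agent.nutrition = _decision.update_nutrition(agent.nutrition, n_meals, c)
    for species in consumed:
        agent.learning = on_consumption(agent.learning, species, c)
        agent.consumed[species] += 1

    agent.satiation = sat
    agent.incentive = inc
    agent.app_state = app
    agent.switch = switch
    agent.turn = turn
    agent.last_consumed = consumed
    return world, agent


TRACE_COLUMNS = (
    "step", "x", "y", "heading", "nutrition", "satiation", "incentive",
    "app_state", "app_state_switch", "turn_angle", "Vh", "Vf",
)


def trace_row(step_index: int, agent: Agent) -> tuple:
    """One row of the per-step state trace (the interface readouts)."""
    return (
        step_index, agent.x, agent.y, agent.heading, agent.nutrition,
        agent.satiation, agent.incentive, agent.app_state, agent.switch,
        agent.turn, agent.learning.Vh, agent.learning.Vf,
    )
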