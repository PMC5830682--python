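"""Bilateral odor sensing and the somatic place code.

The agent carries two point sensors slightly less than half a body
length ahead of its center, splayed about 40 degrees to either side of
the heading, abstracting the oral veil of the real animal.  Each sensor
reports a logarithmic function of the odor concentration in the grid
cell under it (nearest-cell lookup, no interpolation).  Per-odor
readings are averaged across the two sensors; the left-right differences
of the two prey signature odors, each gated by a logistic "surround
suppression" term that silences the weaker odor, form the somatic map -
a signed place code of stimulus laterality that templates turn
amplitude.  Positive somatic map means the stimulus lies to the agent's
left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arena import BETAINE, ODOR_FLAB, ODOR_HERMI, World, _cell_index


@dataclass(frozen=True)
class SensorGeometry:
    """Placement of the paired sensors relative to the body.

    ``sensor_distance`` is in body lengths ahead of the center;
    ``sensor_angle`` in degrees off the anteroposterior axis;
    ``body_length`` in grid cells.
    """

    sensor_distance: float = 0.45
    sensor_angle: float = 40.0
    body_length: float = 3.0

    def __post_init__(self) -> None:
        if self.sensor_distance <= 0.0:
            raise ValueError("sensor_distance must be positive")
        if not (0.0 < self.sensor_angle < 90.0):
            raise ValueError("sensor_angle must lie in (0, 90) degrees")
        if self.body_length <= 0.0:
            raise ValueError("body_length must be positive")


@dataclass(frozen=True)
class SensorReading:
    """Log-scaled odor intensities at the two sensors.

    Attributes are per odor channel, left/right, all dimensionless and
    non-negative.  Derived averages and the hermi/flab contrast terms
    are exposed as properties.
    """

    betaine_left: float
    betaine_right: float
    hermi_left: float
    hermi_right: float
    flab_left: float
    flab_right: float

    @property
    def betaine(self) -> float:
        return (self.betaine_left + self.betaine_right) / 2.0

    @property
    def hermi(self) -> float:
        return (self.hermi_left + self.hermi_right) / 2.0

    @property
    def flab(self) -> float:
        return (self.flab_left + self.flab_right) / 2.0

    @property
    def flab_minus_hermi(self) -> float:
        """Contrast F driving the flab gate of the somatic map."""
        return self.flab - self.hermi

    @property
    def hermi_minus_flab(self) -> float:
        """Contrast H driving the hermi gate; always equals -F."""
        return self.hermi - self.flab

    def max_reading(self) -> float:
        return max(self.betaine, self.hermi, self.flab)

    def swapped(self) -> "SensorReading":
        """Reading with left and right sensors exchanged."""
        return SensorReading(
            self.betaine_right, self.betaine_left,
            self.hermi_right, self.hermi_left,
            self.flab_right, self.flab_left,
        )


def sensor_positions(position, heading: float, geometry: SensorGeometry):
    """Return (left, right) sensor points for a pose.

    Heading is in degrees, measured counterclockwise from the +x axis;
    the left sensor sits at ``heading + sensor_angle``.
    """
    x, y = float(position[0]), float(position[1])
    r = geometry.sensor_distance * geometry.body_length
    a_left = math.radians(heading + geometry.sensor_angle)
    a_right = math.radians(heading - geometry.sensor_angle)
    left = np.array([x + r * math.cos(a_left), y + r * math.sin(a_left)])
    right = np.array([x + r * math.cos(a_right), y + r * math.sin(a_right)])
    return left, right


def _log_reading(concentration: float, floor: float) -> float:
    # log10(1 + c/floor): zero at zero concentration, ~log10(c/floor)
    # once c exceeds the floor, never negative or infinite.
    return math.log10(1.0 + concentration / floor)


def sample(world: World, left, right, floor: float = 1e-3) -> SensorReading:
    """Sample all three odor channels at the two sensor points.

    Points are mapped to their nearest grid cell (with wraparound on a
    torus); concentrations pass through the floored log transform.
    """
    cfg = world.config
    il, jl = _cell_index(left[0], left[1], cfg)
    ir, jr = _cell_index(right[0], right[1], cfg)
    odor = world.odor
    return SensorReading(
        betaine_left=_log_reading(odor[BETAINE, il, jl], floor),
        betaine_right=_log_reading(odor[BETAINE, ir, jr], floor),
        hermi_left=_log_reading(odor[ODOR_HERMI, il, jl], floor),
        hermi_right=_log_reading(odor[ODOR_HERMI, ir, jr], floor),
        flab_left=_log_reading(odor[ODOR_FLAB, il, jl], floor),
        flab_right=_log_reading(odor[ODOR_FLAB, ir, jr], floor),
    )


def _logistic(x: float) -> float:
    # numerically stable logistic
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def somatic_map(reading: SensorReading, k0: float) -> float:
    """Signed place code of the dominant signature odor's laterality.

    Each odor's left-right difference is multiplied by a logistic gate
    of its intensity advantage over the other odor, so the weaker
    (farther) odor contributes almost nothing - an analog of surround
    suppression that keeps the agent locked on the nearest prey.
    Antisymmetric under a left-right exchange of all inputs.
    """
    f = reading.flab_minus_hermi
    h = reading.hermi_minus_flab
    return (
        (reading.flab_left - reading.flab_right) * _logistic(k0 * f)
        + (reading.hermi_left - reading.hermi_right) * _logistic(k0 * h)
    )
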