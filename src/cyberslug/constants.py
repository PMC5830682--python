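"""Model constants for the Cyberslug decision circuit.

All coefficients of the sensing/decision equations live in one frozen
dataclass so that a run is fully specified by (arena config, scenario
config, Constants, seed).  The published model text fixes the learning
parameters (alpha, beta, lambda), the nutrition dynamics (decay 0.0005
per step, +0.3 per meal, initial 0.8) and the approach-avoidance switch
threshold (0.245); the remaining gain coefficients k0-k9 were tuned in
the original implementation and are shipped here as calibrated defaults
(see docs/methods.md for how each default was chosen).  Every value can
be overridden from a config file or keyword arguments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping


@dataclass(frozen=True)
class Constants:
    """Coefficients of the sensing, homeostat and motor equations.

    Attributes
    ----------
    k0 : float
        Gain of the logistic gates in the somatic map ("surround
        suppression": the weaker signature odor's laterality signal is
        squelched).
    k1 : float
        Attenuation of the innate betaine term of the appetitive drive
        R+ as the positive hermi association Vh grows.
    k3 : float
        Gain of the learned odor terms (positive hermi term of R+ and
        the whole aversive drive R-).
    k4 : float
        Shape coefficient of the satiation sigmoid.
    k5 : float
        Incentive gain inside the appetitive-state sigmoid.
    k6 : float
        Satiation gain inside the appetitive-state sigmoid (opposes k5).
    k7 : float
        Gain of the transient appetitive-state suppression fed back from
        the turn network; the term k7*(switch - 1) vanishes when the
        switch sits at +1.
    k8 : float
        Steepness of the approach-avoidance switch around its threshold.
    k9 : float
        Turn-amplitude gain, degrees per step.
    switch_threshold : float
        Appetitive-state level at which the switch crosses zero (0.245).
    nutrition_decay : float
        Fractional nutrition loss per time step (0.0005).
    feed_gain : float
        Nutrition increment per prey item consumed (0.3).
    nutrition_init : float
        Nutrition at trial start (0.8).
    app_state_baseline : float
        Additive floor of the appetitive state (0.01).
    alpha, beta, lam : float
        Rescorla-Wagner salience, rate and asymptote parameters
        (0.5, 1, 1 for both prey signature odors).
    """

    k0: float = 10.0
    k1: float = 0.3
    k3: float = 1.2
    k4: float = 0.7
    k5: float = 1.3
    k6: float = 7.6
    k7: float = 0.05
    k8: float = 50.0
    k9: float = 8.0
    switch_threshold: float = 0.245
    nutrition_decay: float = 0.0005
    feed_gain: float = 0.3
    nutrition_init: float = 0.8
    app_state_baseline: float = 0.01
    alpha: float = 0.5
    beta: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_threshold < 1.0):
            raise ValueError("switch_threshold must lie in (0, 1)")
        if not (0.0 <= self.nutrition_decay < 1.0):
            raise ValueError("nutrition_decay must lie in [0, 1)")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lam < 0.0:
            raise ValueError("lam must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Constants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown constant(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **changes: float) -> "Constants":
        return dataclasses.replace(self, **changes)


DEFAULT_CONSTANTS = Constants()
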