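"""Rescorla-Wagner conditioning of prey odor associations.

Two associative strengths are maintained: Vh, the positive value of the
hermi signature odor, and Vf, the negative value of the flab signature
odor.  Both start at zero and move toward the asymptote lambda on each
consumption of the corresponding prey by the classical delta rule
dV = alpha*beta*(lambda - V).  There is no extinction or forgetting,
with one exception: consuming the Batesian mimic Faux-Flab (flab odor,
hermi-like reward) drives Vf back toward zero with the same rule, i.e.
the rewarding outcome extinguishes the aversive flab association.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .constants import Constants


@dataclass(frozen=True)
class LearningState:
    """Current associative strengths and the mechanism toggle."""

    Vh: float = 0.0
    Vf: float = 0.0
    enabled: bool = True


def rw_update(V: float, alpha: float, beta: float, lam: float) -> float:
    """One Rescorla-Wagner step: V + alpha*beta*(lam - V)."""
    return V + alpha * beta * (lam - V)


def on_consumption(state: LearningState, species: str, c: Constants) -> LearningState:
    """Apply the learning consequence of eating one prey item.

    hermi    -> Vh moves toward lambda (reward association)
    flab     -> Vf moves toward lambda (aversive association)
    fauxflab -> Vf moves toward 0 (reward outcome extinguishes the
                aversion bound to the shared flab odor)

    A disabled state is returned unchanged.
    """
    if species not in ("hermi", "flab", "fauxflab"):
        raise ValueError(f"unknown species: {species!r}")
    if not state.enabled:
        return state
    if species == "hermi":
        return replace(state, Vh=rw_update(state.Vh, c.alpha, c.beta, c.lam))
    if species == "flab":
        return replace(state, Vf=rw_update(state.Vf, c.alpha, c.beta, c.lam))
    return replace(state, Vf=rw_update(state.Vf, c.alpha, c.beta, 0.0))
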