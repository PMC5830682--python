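"""Minimal path-trace plotting (headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .arena import SPECIES_NAMES, World  # noqa: E402

_SPECIES_COLORS = {"flab": "tab:red", "hermi": "tab:green", "fauxflab": "tab:orange"}


def plot_path(trace, world: World | None = None, ax=None):
    """Plot the agent's path from a trace table, with prey overlaid.

    ``trace`` is the per-step DataFrame produced by a traced trial.
    Returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.plot(trace["x"], trace["y"], lw=0.5, color="tab:orange", label="agent path")
    if world is not None:
        for code, name in enumerate(SPECIES_NAMES):
            mask = world.prey_species == code
            if mask.any():
                ax.scatter(world.prey_pos[mask, 0], world.prey_pos[mask, 1],
                           s=30, color=_SPECIES_COLORS[name], label=name)
        ax.set_xlim(0, world.config.width)
        ax.set_ylim(0, world.config.height)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cells)")
    ax.set_ylabel("y (cells)")
    ax.legend(loc="upper right", fontsize="small")
    return ax
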