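#!/usr/bin/env python
"""Report odor-plume statistics for an arena configuration.

Equilibrates a single-prey arena and prints the steady-state plume
profile: peak concentration, log-readings at increasing distance from
the source, and the radius at which the reading crosses the engagement
threshold.  Used to choose diffusion/decay/emission defaults; the shipped
defaults put the engagement radius near three body lengths (see
docs/methods.md for why tighter plumes beat wider ones here).

Usage: python scripts/calibrate.py [--config FILE] [--steps 3000]
"""

from __future__ import annotations

import argparse

import numpy as np

from cyberslug.arena import BETAINE, ArenaConfig, deposit_and_diffuse, init_arena
from cyberslug.sensorium import SensorGeometry
from cyberslug.simulation import DEFAULT_ENGAGE_THRESHOLD, DEFAULT_SENSOR_FLOOR


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default=None, help="YAML config file")
    parser.add_argument("--steps", type=int, default=3000,
                        help="equilibration steps")
    args = parser.parse_args()

    if args.config:
        from cyberslug.config import load_config
        scenario, _ = load_config(args.config)
        base = scenario.arena.to_dict()
    else:
        base = ArenaConfig().to_dict()
    base.update(n_flab=0, n_hermi=1, n_fauxflab=0, prey_step_length=0.0)
    cfg = ArenaConfig.from_dict(base)

    world = init_arena(cfg, np.random.default_rng(0))
    world.prey_pos[0] = (cfg.width / 2.0, cfg.height / 2.0)
    for _ in range(args.steps):
        deposit_and_diffuse(world)

    floor = DEFAULT_SENSOR_FLOOR
    body = SensorGeometry().body_length
    src = int(cfg.width // 2), int(cfg.height // 2)
    field = world.odor[BETAINE]
    print(f"arena {cfg.width}x{cfg.height}, diffusion {cfg.diffusion_rate}, "
          f"decay {cfg.decay_rate}, emission {cfg.prey_odor_emission}")
    print(f"peak concentration: {field.max():.4g}")
    print(f"{'r (cells)':>10} {'r (body lengths)':>18} {'reading':>9}")
    detect_r = None
    for r in range(0, min(cfg.width // 2, 25)):
        c = field[(src[0] + r) % cfg.width, src[1]]
        reading = np.log10(1.0 + c / floor)
        print(f"{r:>10d} {r / body:>18.2f} {reading:>9.3f}")
        if detect_r is None and reading < DEFAULT_ENGAGE_THRESHOLD:
            detect_r = r
    if detect_r is None:
        print("engagement threshold not crossed within the printed range")
    else:
        print(f"detectable (reading > {DEFAULT_ENGAGE_THRESHOLD}) out to "
              f"~{detect_r - 1} cells = {(detect_r - 1) / body:.1f} body lengths")


if __name__ == "__main__":
    main()
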