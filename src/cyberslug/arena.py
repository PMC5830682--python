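"""The 2D foraging arena: odor fields, prey, consumption.

The world is a grid of square cells (NetLogo-style "patches").  Three
odor channels are maintained: *betaine*, the innate resource signal that
every prey secretes, and the two species signature odors *odor_hermi*
and *odor_flab*.  Prey deposit odor into the cell under them each step;
the fields then undergo one discrete diffusion step (each cell exchanges
a fixed fraction of its content equally with its eight neighbors)
followed by multiplicative decay.  Prey perform a slow random walk, and
every consumed prey is immediately replaced at a uniform random position
so per-species population counts are invariant for a whole run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numba import njit

# Odor channel indices
BETAINE, ODOR_HERMI, ODOR_FLAB = 0, 1, 2
CHANNELS = ("betaine", "hermi", "flab")

# Species codes
FLAB, HERMI, FAUXFLAB = 0, 1, 2
SPECIES_NAMES = ("flab", "hermi", "fauxflab")
# Faux-Flab is a Batesian mimic: it carries Flab's odor signature but
# Hermi's rewarding consequences on consumption.
SIGNATURE_CHANNEL = {FLAB: ODOR_FLAB, HERMI: ODOR_HERMI, FAUXFLAB: ODOR_FLAB}


@dataclass(frozen=True)
class ArenaConfig:
    """Static description of the arena and its prey population.

    Lengths are in grid cells, rates are per time step.
    """

    width: int = 50
    height: int = 50
    wrap: bool = True
    n_flab: int = 10
    n_hermi: int = 3
    n_fauxflab: int = 0
    diffusion_rate: float = 0.5
    decay_rate: float = 0.08
    prey_step_length: float = 0.02
    max_prey_turn: float = 30.0
    prey_odor_emission: float = 0.5
    consumption_radius: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if min(self.n_flab, self.n_hermi, self.n_fauxflab) < 0:
            raise ValueError("prey counts must be non-negative")
        if not (0.0 <= self.diffusion_rate < 1.0):
            raise ValueError("diffusion_rate must lie in [0, 1)")
        if not (0.0 <= self.decay_rate < 1.0):
            raise ValueError("decay_rate must lie in [0, 1)")
        if self.consumption_radius <= 0.0:
            raise ValueError("consumption_radius must be positive")
        if self.prey_step_length < 0.0:
            raise ValueError("prey_step_length must be >= 0")

    @property
    def n_prey(self) -> int:
        return self.n_flab + self.n_hermi + self.n_fauxflab

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "ArenaConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown arena option(s): {sorted(unknown)}")
        return cls(**d)


class World:
    """Mutable world state: odor grids plus prey positions/headings.

    Created by :func:`init_arena`; advanced in place by
    :func:`move_prey`, :func:`deposit_and_diffuse` and
    :func:`consume_and_respawn`.
    """

    __slots__ = ("config", "rng", "odor", "prey_species", "prey_pos", "prey_heading",
                 "_rowsum")

    def __init__(self, config: ArenaConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.rng = rng
        self.odor = np.zeros((3, config.width, config.height), dtype=np.float64)
        self._rowsum = np.empty((config.width, config.height), dtype=np.float64)
        species = [FLAB] * config.n_flab + [HERMI] * config.n_hermi + [FAUXFLAB] * config.n_fauxflab
        self.prey_species = np.asarray(species, dtype=np.int64)
        n = config.n_prey
        self.prey_pos = np.empty((n, 2), dtype=np.float64)
        self.prey_pos[:, 0] = rng.uniform(0.0, config.width, n)
        self.prey_pos[:, 1] = rng.uniform(0.0, config.height, n)
        self.prey_heading = rng.uniform(0.0, 360.0, n)

    def species_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.prey_species == code))
                for code, name in enumerate(SPECIES_NAMES)}


def init_arena(config: ArenaConfig, rng: np.random.Generator | None = None) -> World:
    """Create a world with zeroed odor fields and uniformly placed prey.

    The RNG is seeded from ``config.seed`` unless an explicit generator
    is supplied (the trial runner passes its own stream so that one seed
    governs the entire trial).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return World(config, rng)


@njit(cache=False)
def _diffuse_decay(odor, rowsum, rate, decay, wrap):  # pragma: no cover - via wrapper
    """One 8-neighbor diffusion step plus multiplicative decay, in place.

    Each cell gives away ``rate`` of its content, split equally over its
    eight neighbor slots; shares aimed at out-of-bounds neighbors (non
    wrapping topology) stay in the cell, so the operator conserves mass
    on any topology before decay is applied.  The 3x3 neighbor sum is
    computed separably (row sums, then column sums) via the ``rowsum``
    scratch buffer.
    """
    nch, w, h = odor.shape
    share = rate / 8.0
    keep = 1.0 - rate
    scale = 1.0 - decay
    for c in range(nch):
        # horizontal pass: rowsum[i, j] = sum of odor[c, i, j-1..j+1]
        for i in range(w):
            for j in range(h):
                jm = j - 1
                jp = j + 1
                left = odor[c, i, jm] if jm >= 0 else (odor[c, i, h - 1] if wrap else 0.0)
                right = odor[c, i, jp] if jp < h else (odor[c, i, 0] if wrap else 0.0)
                rowsum[i, j] = left + odor[c, i, j] + right
        # vertical pass and update; track how many neighbor slots exist
        for i in range(w):
            im = i - 1
            ip = i + 1
            for j in range(h):
                up = rowsum[im, j] if im >= 0 else (rowsum[w - 1, j] if wrap else 0.0)
                down = rowsum[ip, j] if ip < w else (rowsum[0, j] if wrap else 0.0)
                center = odor[c, i, j]
                nsum = up + rowsum[i, j] + down - center
                if wrap:
                    nvalid = 8
                else:
                    ei = 1 if (i == 0 or i == w - 1) else 0
                    ej = 1 if (j == 0 or j == h - 1) else 0
                    nvalid = 8 - (3 * ei + 3 * ej - ei * ej)
                odor[c, i, j] = ((keep + share * (8 - nvalid)) * center + share * nsum) * scale
    return odor


def _cell_index(x: float, y: float, config: ArenaConfig) -> tuple[int, int]:
    i = int(np.floor(x))
    j = int(np.floor(y))
    if config.wrap:
        i %= config.width
        j %= config.height
    else:
        i = min(max(i, 0), config.width - 1)
        j = min(max(j, 0), config.height - 1)
    return i, j


def deposit_and_diffuse(world: World) -> World:
    """Prey deposit odor into their cells, then fields diffuse and decay.

    Every prey adds ``prey_odor_emission`` to the betaine channel and to
    its species signature channel (Faux-Flab deposits on the flab
    channel) at its current cell.
    """
    cfg = world.config
    emission = cfg.prey_odor_emission
    odor = world.odor
    for k in range(len(world.prey_species)):
        i, j = _cell_index(world.prey_pos[k, 0], world.prey_pos[k, 1], cfg)
        odor[BETAINE, i, j] += emission
        odor[SIGNATURE_CHANNEL[int(world.prey_species[k])], i, j] += emission
    _diffuse_decay(odor, world._rowsum, cfg.diffusion_rate, cfg.decay_rate, cfg.wrap)
    return world


def move_prey(world: World) -> World:
    """Advance every prey one random-walk step.

    Headings are perturbed by a uniform angle in
    [-max_prey_turn, +max_prey_turn] and each prey advances
    ``prey_step_length`` cells along its new heading.  Positions wrap on
    a torus, or are clamped to the arena rectangle otherwise.
    """
    cfg = world.config
    n = len(world.prey_species)
    if n == 0:
        return world
    world.prey_heading += world.rng.uniform(-cfg.max_prey_turn, cfg.max_prey_turn, n)
    if cfg.prey_step_length > 0.0:
        rad = np.deg2rad(world.prey_heading)
        world.prey_pos[:, 0] += cfg.prey_step_length * np.cos(rad)
        world.prey_pos[:, 1] += cfg.prey_step_length * np.sin(rad)
        _apply_boundary(world.prey_pos, cfg)
    return world


def _apply_boundary(pos: np.ndarray, config: ArenaConfig) -> None:
    if config.wrap:
        pos[:, 0] %= config.width
        pos[:, 1] %= config.height
    else:
        np.clip(pos[:, 0], 0.0, np.nextafter(float(config.width), 0.0), out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, np.nextafter(float(config.height), 0.0), out=pos[:, 1])


def torus_delta(a: np.ndarray, b: np.ndarray, config: ArenaConfig) -> np.ndarray:
    """Shortest displacement vector(s) from ``b`` to ``a``."""
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    if config.wrap:
        span = np.array([config.width, config.height], dtype=np.float64)
        d = (d + span / 2.0) % span - span / 2.0
    return d


def consume_and_respawn(world: World, agent_position) -> tuple[World, list[str]]:
    """Remove every prey within the consumption radius of the agent's mouth.

    Each removed prey is replaced by a new one of the same species at a
    uniform random position (fresh random heading), so per-species
    counts never change.  Returns the world and the list of consumed
    species names (possibly empty; more than one entry when prey are
    clustered).
    """
    cfg = world.config
    if len(world.prey_species) == 0:
        return world, []
    d = torus_delta(world.prey_pos, np.asarray(agent_position, dtype=np.float64), cfg)
    dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
    hit = np.flatnonzero(dist2 <= cfg.consumption_radius ** 2)
    consumed: list[str] = []
    for k in hit:
        consumed.append(SPECIES_NAMES[int(world.prey_species[k])])
        world.prey_pos[k, 0] = world.rng.uniform(0.0, cfg.width)
        world.prey_pos[k, 1] = world.rng.uniform(0.0, cfg.height)
        world.prey_heading[k] = world.rng.uniform(0.0, 360.0)
    return world, consumed
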