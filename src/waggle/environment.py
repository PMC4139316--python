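"""The 201x201-cell world: forage patches, their turnover, and the clock gate.

Cells are indexed by integer offsets from the nest at (0, 0); internally the
arrays are shifted by ``grid_half_extent``.  Agents live on the continuous
plane; :func:`cell_of` maps a continuous position to the cell whose unit
square (centred on the integer coordinates, half-open on the upper edges)
contains it.

Patch dynamics: patches age by one day per day and die once their age
exceeds ``a_max``; empty cells are (re)born as forage with a per-day birth
probability that depends on ``patch_birth_mode``:

``stationary``
    birth rate ``b = d_patch / (a_max * (1 - d_patch))`` balances the death
    flow ``occupancy / a_max`` so the expected long-run occupancy stays at
    ``d_patch`` (the label of the density parameter).
``literal``
    birth probability ``b = d_patch`` per empty cell per day, which drives
    occupancy far above ``d_patch`` whenever ``a_max > 1``; retained for
    comparison with the literal reading of the turnover rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import Params

__all__ = [
    "World", "init_world", "daily_turnover", "foraging_allowed", "cell_of",
    "birth_rate", "draw_quality", "snapshot",
]

QUALITY_MIN = 0.05  # mol/l; truncation of the quality normal (redraw below)


@dataclasses.dataclass
class World:
    """Grid state; arrays are indexed ``[ix + half, iy + half]``."""

    is_forage: np.ndarray   # bool (n, n)
    quality: np.ndarray     # float64 (n, n), mol/l (0 where empty)
    age: np.ndarray         # int64 (n, n), days (0 where empty)
    half_extent: int
    day_index: int = 0

    @property
    def n_cells(self) -> int:
        side = 2 * self.half_extent + 1
        return side * side

    def occupancy(self) -> float:
        return float(self.is_forage.mean())


def draw_quality(rng: np.random.Generator, size: int, q_mean: float,
                 q_sd: float) -> np.ndarray:
    """Nectar qualities ~ Normal(q_mean, q_sd) truncated by redraw to stay
    above QUALITY_MIN mol/l."""
    out = rng.normal(q_mean, q_sd, size)
    bad = out <= QUALITY_MIN
    while bad.any():
        out[bad] = rng.normal(q_mean, q_sd, int(bad.sum()))
        bad = out <= QUALITY_MIN
    return out


def birth_rate(params: Params) -> float:
    """Per-day forage birth probability for an empty cell."""
    if params.patch_birth_mode == "literal":
        return params.d_patch
    # stationary: (1 - p) * b = p / a_max at p = d_patch
    return params.d_patch / (params.a_max * (1.0 - params.d_patch))


def init_world(params: Params, rng: np.random.Generator) -> World:
    """Fresh world: each non-nest cell is forage with probability d_patch,
    with truncated-normal quality and age uniform on {1..a_max}."""
    half = params.grid_half_extent
    side = 2 * half + 1
    is_forage = rng.random((side, side)) < params.d_patch
    is_forage[half, half] = False   # no foraging on the nest cell
    quality = np.zeros((side, side))
    age = np.zeros((side, side), dtype=np.int64)
    k = int(is_forage.sum())
    quality[is_forage] = draw_quality(rng, k, params.q_mean, params.q_sd)
    age[is_forage] = rng.integers(1, params.a_max + 1, k)
    return World(is_forage, quality, age, half)


def daily_turnover(world: World, params: Params,
                   rng: np.random.Generator) -> World:
    """Advance the world by one day in place: age, kill, and give birth."""
    world.age[world.is_forage] += 1
    dead = world.is_forage & (world.age > params.a_max)
    world.is_forage[dead] = False
    world.quality[dead] = 0.0
    world.age[dead] = 0

    b = birth_rate(params)
    empty = ~world.is_forage
    empty[world.half_extent, world.half_extent] = False
    born = empty & (rng.random(world.is_forage.shape) < b)
    k = int(born.sum())
    if k:
        world.is_forage[born] = True
        world.quality[born] = draw_quality(rng, k, params.q_mean, params.q_sd)
        world.age[born] = 1
    world.day_index += 1
    return world


def foraging_allowed(step_of_day: int, params: Params) -> bool:
    """True iff the step falls inside the daily foraging window."""
    if not 0 <= step_of_day < params.t_day:
        raise ValueError(
            f"step_of_day={step_of_day} outside [0, {params.t_day})")
    return params.forage_open <= step_of_day <= params.forage_close


def cell_of(x: float, y: float, half_extent: int) -> tuple[int, int]:
    """Cell index containing continuous position (x, y), in cell units.

    Cell (i, j) is the square [i-0.5, i+0.5) x [j-0.5, j+0.5)."""
    ix = int(np.floor(x + 0.5))
    iy = int(np.floor(y + 0.5))
    if abs(ix) > half_extent or abs(iy) > half_extent:
        raise ValueError(f"position ({x}, {y}) outside the world")
    return ix, iy


def snapshot(world: World) -> pd.DataFrame:
    """Tidy table of live forage cells (cell_x, cell_y, quality, age)."""
    half = world.half_extent
    xs, ys = np.nonzero(world.is_forage)
    return pd.DataFrame({
        "cell_x": xs - half,
        "cell_y": ys - half,
        "is_forage": True,
        "quality": world.quality[xs, ys],
        "age": world.age[xs, ys],
    })
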