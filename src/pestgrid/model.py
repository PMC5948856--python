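"""Domain types and environment dynamics of the pest-control lattice.

The field is an M x N grid; each cell is a crop zone monitored by one
sensor station.  Bugs appear stochastically, perform a clamped lattice
random walk, eat unprotected crop, and die after accumulating enough
hours of pesticide exposure.  The crop slowly regrows toward 100% health.

All stochastic primitives draw from a caller-supplied
:class:`numpy.random.Generator` so that the engine owns a single seeded
stream and runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import World

__all__ = [
    "GridPosition",
    "BugAgent",
    "CropZone",
    "spawn_count",
    "place_new_bugs",
    "move_bug",
    "apply_exposure",
    "bug_eat",
    "crop_grow",
]


class GridPosition(NamedTuple):
    """Zone index on the grid: ``x`` is the column, ``y`` the row."""

    x: int
    y: int


@dataclass
class BugAgent:
    """A bug at zone granularity.

    ``exposure_hours`` counts cumulative (not necessarily consecutive)
    hours spent in a fumigated zone; the bug dies when the count reaches
    the configured lethal threshold.
    """

    id: int
    position: GridPosition
    alive: bool = True
    exposure_hours: int = 0
    born_at: int = 0


@dataclass
class CropZone:
    """One 100 x 100 m crop cell and its pesticide bookkeeping."""

    position: GridPosition
    health: float = 100.0
    fumigated_now: bool = False
    fumigated_prev: bool = False
    pesticide_dispensed: float = 0.0


def spawn_count(pa: float, mb: int, rng: np.random.Generator) -> int:
    """Number of bugs appearing this hour.

    With probability ``pa`` an appearance event fires and the count is
    uniform on ``{0, ..., mb}``; otherwise the count is 0.  The strict
    comparison of the uniform draw against ``pa`` makes ``pa=0``
    deterministically silent and ``pa=1`` deterministically firing.
    """
    if not 0.0 <= pa <= 1.0:
        raise ValueError(f"appearance probability must be in [0, 1], got {pa}")
    if mb < 1:
        raise ValueError(f"max new bugs must be >= 1, got {mb}")
    ra = rng.random()
    if ra < pa:
        return int(rng.integers(0, mb + 1))
    return 0


def place_new_bugs(world: "World", count: int, rng: np.random.Generator) -> None:
    """Add ``count`` alive bugs at independent uniform-random zones."""
    if count < 0:
        raise ValueError("count must be >= 0")
    m, n = world.config.columns, world.config.rows
    for _ in range(count):
        flat = int(rng.integers(0, m * n))
        world.add_bug(GridPosition(flat % m, flat // m))


def move_bug(
    pos: GridPosition, rng: np.random.Generator, columns: int, rows: int
) -> GridPosition:
    """One step of the clamped lattice walk.

    Each coordinate independently shifts by a uniform draw from
    ``{-1, 0, +1}`` and is clamped to its own dimension's index range, so
    the result is always within Chebyshev distance 1 of ``pos`` and never
    leaves the grid.
    """
    rx = int(rng.integers(-1, 2))
    ry = int(rng.integers(-1, 2))
    x = min(max(pos.x + rx, 0), columns - 1)
    y = min(max(pos.y + ry, 0), rows - 1)
    return GridPosition(x, y)


def apply_exposure(bug: BugAgent, zone_fumigated_now: bool, h_die: int) -> None:
    """Accrue one fumigated hour; kill the bug at the lethal threshold."""
    if not bug.alive:
        raise ValueError("apply_exposure called on a dead bug")
    if zone_fumigated_now:
        bug.exposure_hours += 1
        if bug.exposure_hours >= h_die:
            bug.alive = False


def bug_eat(zone: CropZone, eat_rate: float, n_bugs: int = 1) -> None:
    """Feeding by ``n_bugs`` alive bugs occupying ``zone`` this hour.

    Eating is blocked only when the zone was fumigated in the *previous*
    hour; same-hour fumigation does not protect the crop (it drives
    exposure instead).  Health is floored at 0.
    """
    if zone.fumigated_prev:
        return
    zone.health = max(0.0, zone.health - eat_rate * n_bugs)


def crop_grow(zone: CropZone, grow_rate: float) -> None:
    """Hourly regrowth, capped at 100% health."""
    zone.health = min(100.0, zone.health + grow_rate)
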