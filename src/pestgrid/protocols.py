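"""Communication strategies for the sensor network.

A strategy is a pair of behavioural hooks over a fixed sensor capability
set:

* the *periodic* hook (``live``) runs once per sensor per simulated hour
  and typically senses bugs and decides whether to fumigate and whom to
  warn;
* the *reactive* hook (``manage``) runs when the sensor receives a
  message from a peer.

Strategies interact with the world only through the six capabilities of
:class:`Sensor` — ``sense_bugs``, ``fumigate``, ``send``, ``broadcast``,
``send_neighbors`` and ``get_iteration`` — so third-party strategies
plug in without touching the engine.

Three strategies ship with the package:

``broadcast``
    On detection, fumigate and warn every other sensor; a warned sensor
    fumigates.  Simple and effective, but the whole field is fumigated
    for a single detection.
``neighbor``
    On detection, fumigate and warn only the 8-neighbourhood, relying on
    bugs moving at most one zone per hour; a warned sensor fumigates.
``lowcost_neighbor``
    Like ``neighbor``, but each sensor remembers when each neighbour
    last warned it (a 3x3 "last warnings" matrix) and when it last
    detected bugs.  A detection opens a fumigation window of ``d`` hours
    and warnings are suppressed toward neighbours that themselves warned
    within the last ``d`` hours — they are already fumigating, so the
    message would be redundant.  This learning cuts the energy spent on
    communication.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterator

from .model import GridPosition

if TYPE_CHECKING:  # pragma: no cover
    from .engine import World

__all__ = [
    "MessageKind",
    "Message",
    "NEVER",
    "LowCostState",
    "Sensor",
    "Strategy",
    "BroadcastStrategy",
    "NeighborStrategy",
    "LowCostNeighborStrategy",
    "iter_neighbors",
    "global_to_local",
    "local_to_global",
    "get_strategy",
    "register_strategy",
    "available_strategies",
]


class MessageKind(enum.Enum):
    WARN_BUGS = "warn_bugs"


@dataclass(frozen=True)
class Message:
    """A delivered message; sender position and hour are stamped on send."""

    kind: MessageKind
    sender: GridPosition
    iteration: int


#: Sentinel for "no warning / no detection has ever happened"; behaves as
#: minus infinity in every window comparison, so nothing is suppressed
#: before the first event.
NEVER = float("-inf")


class LowCostState:
    """Per-sensor memory of the low-cost neighbour strategy.

    ``b`` is the hour of the last own detection; ``w`` is the 3x3
    last-warnings matrix indexed by local position (``w[1][1]`` is the
    sensor itself and stays unused).
    """

    __slots__ = ("b", "w")

    def __init__(self) -> None:
        self.b: float = NEVER
        self.w: list[list[float]] = [[NEVER] * 3 for _ in range(3)]


def iter_neighbors(pos: GridPosition, columns: int, rows: int) -> Iterator[GridPosition]:
    """In-bounds grid cells at Chebyshev distance exactly 1 from ``pos``."""
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            x, y = pos.x + dx, pos.y + dy
            if 0 <= x < columns and 0 <= y < rows:
                yield GridPosition(x, y)


def global_to_local(g: GridPosition, r: GridPosition) -> tuple[int, int]:
    """Map a neighbour's global position into the 3x3 local frame of ``r``.

    The local index is ``(g - r) + (1, 1)``; the centre ``(1, 1)`` is the
    reference sensor itself.
    """
    lx, ly = g.x - r.x + 1, g.y - r.y + 1
    if not (0 <= lx <= 2 and 0 <= ly <= 2):
        raise ValueError(f"{g} is not within the 3x3 neighbourhood of {r}")
    return lx, ly


def local_to_global(r: GridPosition, local: tuple[int, int]) -> GridPosition:
    """Inverse of :func:`global_to_local`: ``(local - (1, 1)) + r``."""
    lx, ly = local
    if not (0 <= lx <= 2 and 0 <= ly <= 2):
        raise ValueError(f"local index {local} outside {{0,1,2}}^2")
    return GridPosition(r.x + lx - 1, r.y + ly - 1)


class Sensor:
    """One sensor station: the capability surface offered to strategies."""

    __slots__ = ("position", "world", "state")

    def __init__(self, position: GridPosition, world: "World", state: object = None):
        self.position = position
        self.world = world
        self.state = state

    # -- the six capabilities -------------------------------------------

    def sense_bugs(self) -> bool:
        """True iff at least one *alive* bug occupies this sensor's zone."""
        return self.world.alive_count[self.position.x, self.position.y] > 0

    def fumigate(self) -> None:
        """Fumigate this zone for the current hour (idempotent per hour)."""
        self.world.fumigate(self.position)

    def send(self, target: GridPosition, kind: MessageKind) -> None:
        """Send a message; sender position and hour are stamped automatically."""
        self.world.send(self.position, target, kind)

    def broadcast(self, kind: MessageKind) -> None:
        """Send to every sensor on the grid except this one."""
        m, n = self.world.config.columns, self.world.config.rows
        for y in range(n):
            for x in range(m):
                if (x, y) != (self.position.x, self.position.y):
                    self.send(GridPosition(x, y), kind)

    def send_neighbors(self, kind: MessageKind) -> None:
        """Send to the boundary-clipped 8-neighbourhood."""
        m, n = self.world.config.columns, self.world.config.rows
        for nbr in iter_neighbors(self.position, m, n):
            self.send(nbr, kind)

    def get_iteration(self) -> int:
        return self.world.t


class Strategy:
    """Base class: a named (periodic hook, reactive hook, state) triple."""

    name: str = "abstract"

    def initial_state(self) -> object:
        return None

    def live(self, sensor: Sensor, t: int) -> None:  # pragma: no cover
        raise NotImplementedError

    def manage(self, sensor: Sensor, msg: Message) -> None:  # pragma: no cover
        raise NotImplementedError


def _warn_fumigate(sensor: Sensor, msg: Message) -> None:
    # Shared reactive rule of the broadcast and neighbor strategies: a
    # warned sensor fumigates unconditionally, and never sends onward
    # (no message cascades).
    if msg.kind is not MessageKind.WARN_BUGS:
        raise ValueError(f"unknown message kind: {msg.kind!r}")
    sensor.fumigate()


class BroadcastStrategy(Strategy):
    """Detect -> fumigate and warn the whole grid; warned -> fumigate."""

    name = "broadcast"

    def live(self, sensor: Sensor, t: int) -> None:
        if sensor.sense_bugs():
            sensor.fumigate()
            sensor.broadcast(MessageKind.WARN_BUGS)

    def manage(self, sensor: Sensor, msg: Message) -> None:
        _warn_fumigate(sensor, msg)


class NeighborStrategy(Strategy):
    """Detect -> fumigate and warn the 8-neighbourhood; warned -> fumigate."""

    name = "neighbor"

    def live(self, sensor: Sensor, t: int) -> None:
        if sensor.sense_bugs():
            sensor.fumigate()
            sensor.send_neighbors(MessageKind.WARN_BUGS)

    def manage(self, sensor: Sensor, msg: Message) -> None:
        _warn_fumigate(sensor, msg)


class LowCostNeighborStrategy(Strategy):
    """Neighbour warnings with redundancy suppression and fumigation windows.

    A fresh detection at hour ``t`` (i.e. ``t - b > d``) triggers a smart
    neighbour warning and sets ``b := t``; the window test ``t - b <= d``
    is evaluated after that assignment, so a detecting sensor starts
    fumigating the same hour and keeps fumigating through ``t + d``.
    Warnings are suppressed toward neighbours whose last warning arrived
    within the last ``d`` hours.
    """

    name = "lowcost_neighbor"

    def initial_state(self) -> LowCostState:
        return LowCostState()

    def live(self, sensor: Sensor, t: int) -> None:
        state: LowCostState = sensor.state
        d = sensor.world.config.fumigation_window
        if sensor.sense_bugs() and t - state.b > d:
            self.send_neighbors_smartly(sensor, t)
            state.b = t
        if t - state.b <= d:
            sensor.fumigate()

    def manage(self, sensor: Sensor, msg: Message) -> None:
        if msg.kind is not MessageKind.WARN_BUGS:
            raise ValueError(f"unknown message kind: {msg.kind!r}")
        state: LowCostState = sensor.state
        sensor.fumigate()
        lx, ly = global_to_local(msg.sender, sensor.position)
        state.w[lx][ly] = msg.iteration

    @staticmethod
    def send_neighbors_smartly(sensor: Sensor, t: int) -> None:
        """Warn only the neighbours that did not warn within ``d`` hours."""
        state: LowCostState = sensor.state
        cfg = sensor.world.config
        d = cfg.fumigation_window
        for nbr in iter_neighbors(sensor.position, cfg.columns, cfg.rows):
            lx, ly = global_to_local(nbr, sensor.position)
            if t - state.w[lx][ly] > d:
                sensor.send(nbr, MessageKind.WARN_BUGS)


_REGISTRY: dict[str, Callable[[], Strategy]] = {
    "broadcast": BroadcastStrategy,
    "neighbor": NeighborStrategy,
    "lowcost_neighbor": LowCostNeighborStrategy,
}


def register_strategy(name: str, factory: Callable[[], Strategy]) -> None:
    """Register a third-party strategy factory under ``name``."""
    _REGISTRY[name] = factory


def available_strategies() -> list[str]:
    return sorted(_REGISTRY)


def get_strategy(name: str) -> Strategy:
    """Instantiate a registered strategy by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown strategy {name!r}; registered strategies: "
            f"{', '.join(available_strategies())}"
        ) from None
    return factory()
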