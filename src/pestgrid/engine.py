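"""Hourly scheduler and metric observer.

Each simulated hour advances through a fixed phase order (the order
matters for reproducibility and is part of the engine contract):

1. fumigation flags shift: last hour's ``fumigated_now`` becomes
   ``fumigated_prev`` and the current-hour flag resets;
2. stochastic bug appearance (plus any scripted spawns);
3. every alive bug takes one clamped random-walk step, in creation order;
4. every sensor's periodic hook runs in row-major raster order, with
   messages delivered synchronously (the receiver's reactive hook runs
   inline during the sender's turn);
5. bugs standing in a zone fumigated this hour accrue exposure and may
   die;
6. surviving bugs eat crop in zones not fumigated the previous hour;
7. all zones regrow;
8. the observer appends a :class:`MetricRecord`.

A single seeded :class:`numpy.random.Generator` drives phases 2-3, and
strategies draw no randomness, so identical ``(config, seed)`` pairs
yield bitwise-identical traces.

The four tracked metrics mirror what a practitioner would read off the
sensor network: average electric power per active station, mean crop
health, percentage of alive bugs (over all bugs ever present), and
cumulative pesticide per station.  A station is *active* in an hour if
it sent at least one message or fumigated; instantaneous power of an
hour is (messages x energy-per-message) / (active stations), and the
reported power is the running mean of that quantity over hours with at
least one active station.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, ScenarioScript, SimConfig
from .model import (
    BugAgent,
    CropZone,
    GridPosition,
    apply_exposure,
    bug_eat,
    crop_grow,
    move_bug,
    place_new_bugs,
    spawn_count,
)
from .protocols import Message, MessageKind, Sensor, Strategy, get_strategy

__all__ = [
    "MetricRecord",
    "EvolutionTrace",
    "World",
    "initialize",
    "run_iteration",
    "compute_metrics",
    "run_simulation",
    "write_trace_csv",
    "read_trace_csv",
]

logger = logging.getLogger(__name__)

#: Column order of the evolution CSV.
TRACE_COLUMNS = (
    "iteration",
    "avg_power",
    "crop_health_pct",
    "alive_bugs_pct",
    "pesticide_per_station",
    "messages_this_hour",
    "active_stations",
    "alive_bugs",
)


@dataclass(frozen=True)
class MetricRecord:
    """The four tracked metrics plus per-hour diagnostics."""

    iteration: int
    avg_power: float
    crop_health_pct: float
    alive_bugs_pct: float
    pesticide_per_station: float
    messages_this_hour: int
    active_stations: int
    alive_bugs: int


@dataclass
class EvolutionTrace:
    """Ordered per-hour metric records of one simulation run."""

    records: list[MetricRecord] = field(default_factory=list)

    @property
    def final(self) -> MetricRecord:
        if not self.records:
            raise ValueError("empty trace has no final record")
        return self.records[-1]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=TRACE_COLUMNS)


class World:
    """Full simulation state at hour ``t`` plus the activity ledgers."""

    def __init__(self, config: SimConfig, strategy: Strategy):
        self.config = config
        self.strategy = strategy
        self.t = 0
        self.zones: list[list[CropZone]] = [
            [CropZone(GridPosition(x, y)) for y in range(config.rows)]
            for x in range(config.columns)
        ]
        self.sensors: list[list[Sensor]] = [
            [
                Sensor(GridPosition(x, y), self, strategy.initial_state())
                for y in range(config.rows)
            ]
            for x in range(config.columns)
        ]
        self.bugs: list[BugAgent] = []
        self.alive_count = np.zeros((config.columns, config.rows), dtype=np.int64)
        # ledgers
        self.total_energy = 0.0
        self.messages_this_hour = 0
        self.active_this_hour: set[GridPosition] = set()
        self.hourly_messages: list[int] = []
        self.hourly_active: list[int] = []
        self.power_samples: list[float] = []  # hours with >= 1 active station

    # -- bug bookkeeping -------------------------------------------------

    def add_bug(self, position: GridPosition) -> BugAgent:
        bug = BugAgent(id=len(self.bugs), position=position, born_at=self.t)
        self.bugs.append(bug)
        self.alive_count[position.x, position.y] += 1
        return bug

    @property
    def alive_bugs(self) -> int:
        return int(self.alive_count.sum())

    @property
    def total_bugs_ever(self) -> int:
        return len(self.bugs)

    def zone(self, pos: GridPosition) -> CropZone:
        return self.zones[pos.x][pos.y]

    # -- capability backends (called through Sensor) ---------------------

    def fumigate(self, pos: GridPosition) -> None:
        # Idempotent within the hour: a fixed pesticide quantity per zone
        # per fumigated hour, however many times the strategy calls it.
        zone = self.zones[pos.x][pos.y]
        self.active_this_hour.add(pos)
        if not zone.fumigated_now:
            zone.fumigated_now = True
            zone.pesticide_dispensed += self.config.pesticide_per_fumigation

    def send(self, sender: GridPosition, target: GridPosition, kind: MessageKind) -> None:
        cfg = self.config
        if not (0 <= target.x < cfg.columns and 0 <= target.y < cfg.rows):
            raise ValueError(f"send target {target} outside the grid")
        if target == sender:
            raise ValueError("a sensor cannot send a message to itself")
        self.messages_this_hour += 1
        self.total_energy += cfg.energy_per_message
        self.active_this_hour.add(sender)
        receiver = self.sensors[target.x][target.y]
        self.strategy.manage(receiver, Message(kind, sender, self.t))

    # -- aggregates ------------------------------------------------------

    def total_pesticide(self) -> float:
        return sum(z.pesticide_dispensed for col in self.zones for z in col)

    def mean_health(self) -> float:
        return float(
            np.mean([z.health for col in self.zones for z in col])
        )


def initialize(
    config: SimConfig,
    rng: np.random.Generator,
    strategy: Strategy | None = None,
) -> World:
    """Fresh world: all zones at 100% health, initial infestations placed.

    The initially affected zones are ``initial_affected_areas`` *distinct*
    cells drawn uniformly at random, each seeded with
    ``bugs_per_initial_area`` alive bugs.
    """
    if strategy is None:
        strategy = get_strategy(config.strategy)
    world = World(config, strategy)
    k = config.initial_affected_areas
    if k > 0:
        flats = rng.choice(config.n_zones, size=k, replace=False)
        for flat in flats:
            pos = GridPosition(int(flat) % config.columns, int(flat) // config.columns)
            for _ in range(config.bugs_per_initial_area):
                world.add_bug(pos)
    return world


def run_iteration(
    world: World,
    rng: np.random.Generator,
    scenario: ScenarioScript | None = None,
) -> MetricRecord:
    """Advance the world by one hour through the eight phases."""
    cfg = world.config
    t = world.t

    # 1. shift fumigation flags, reset per-hour ledgers
    for col in world.zones:
        for zone in col:
            zone.fumigated_prev = zone.fumigated_now
            zone.fumigated_now = False
    world.messages_this_hour = 0
    world.active_this_hour = set()

    # 2. bug appearance
    if scenario is None or not scenario.disable_appearance:
        count = spawn_count(cfg.p_appear, cfg.max_new_bugs, rng)
        place_new_bugs(world, count, rng)
    if scenario is not None:
        for pos, count in scenario.spawns_at(t):
            for _ in range(count):
                world.add_bug(GridPosition(*pos))

    # 3. movement (creation order)
    if scenario is None or not scenario.disable_movement:
        for bug in world.bugs:
            if not bug.alive:
                continue
            new_pos = move_bug(bug.position, rng, cfg.columns, cfg.rows)
            if new_pos != bug.position:
                world.alive_count[bug.position.x, bug.position.y] -= 1
                world.alive_count[new_pos.x, new_pos.y] += 1
                bug.position = new_pos

    # 4. periodic hooks, raster order, synchronous delivery
    for y in range(cfg.rows):
        for x in range(cfg.columns):
            world.strategy.live(world.sensors[x][y], t)

    # 5. pesticide exposure and death
    for bug in world.bugs:
        if bug.alive and world.zone(bug.position).fumigated_now:
            apply_exposure(bug, True, cfg.exposure_hours_to_die)
            if not bug.alive:
                world.alive_count[bug.position.x, bug.position.y] -= 1

    # 6. surviving bugs eat
    for bug in world.bugs:
        if bug.alive:
            bug_eat(world.zone(bug.position), cfg.eat_rate)

    # 7. regrowth
    for col in world.zones:
        for zone in col:
            crop_grow(zone, cfg.grow_rate)

    # 8. observer
    world.hourly_messages.append(world.messages_this_hour)
    world.hourly_active.append(len(world.active_this_hour))
    if world.active_this_hour:
        world.power_samples.append(
            world.messages_this_hour * cfg.energy_per_message
            / len(world.active_this_hour)
        )
    record = compute_metrics(world)
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "hour %d: %d msgs, %d active, %d alive bugs, health %.2f%%",
            t, record.messages_this_hour, record.active_stations,
            record.alive_bugs, record.crop_health_pct,
        )
    world.t += 1
    return record


def compute_metrics(world: World) -> MetricRecord:
    """The four metrics at the current hour.

    * power: running mean of per-hour (messages x E_msg / active
      stations) over hours with at least one active station, 0 before
      any activity;
    * crop health: mean zone health;
    * alive bugs: 100 x alive / total-ever, reported as 100 before any
      bug has ever existed (the convention the evolutions start from);
    * pesticide: cumulative total dispensed / number of stations.
    """
    total_ever = world.total_bugs_ever
    alive_pct = 100.0 if total_ever == 0 else 100.0 * world.alive_bugs / total_ever
    avg_power = float(np.mean(world.power_samples)) if world.power_samples else 0.0
    return MetricRecord(
        iteration=world.t,
        avg_power=avg_power,
        crop_health_pct=world.mean_health(),
        alive_bugs_pct=alive_pct,
        pesticide_per_station=world.total_pesticide() / world.config.n_zones,
        messages_this_hour=world.messages_this_hour,
        active_stations=len(world.active_this_hour),
        alive_bugs=world.alive_bugs,
    )


def run_simulation(
    config: SimConfig,
    scenario: ScenarioScript | None = None,
    strategy: Strategy | None = None,
) -> EvolutionTrace:
    """Run a full simulation and return the per-hour evolution trace."""
    if scenario is not None:
        scenario.validate(config)
    rng = np.random.default_rng(config.seed)
    world = initialize(config, rng, strategy)
    trace = EvolutionTrace()
    for _ in range(config.hours):
        trace.records.append(run_iteration(world, rng, scenario))
    return trace


def write_trace_csv(trace: EvolutionTrace, path: str | Path) -> None:
    """Write the per-iteration evolution records as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_COLUMNS)
        for r in trace.records:
            writer.writerow([getattr(r, c) for c in TRACE_COLUMNS])


def read_trace_csv(path: str | Path) -> EvolutionTrace:
    """Read an evolution CSV back into an :class:`EvolutionTrace`."""
    df = pd.read_csv(path, float_precision="round_trip")
    records = [
        MetricRecord(
            iteration=int(row.iteration),
            avg_power=float(row.avg_power),
            crop_health_pct=float(row.crop_health_pct),
            alive_bugs_pct=float(row.alive_bugs_pct),
            pesticide_per_station=float(row.pesticide_per_station),
            messages_this_hour=int(row.messages_this_hour),
            active_stations=int(row.active_stations),
            alive_bugs=int(row.alive_bugs),
        )
        for row in df.itertuples()
    ]
    return EvolutionTrace(records)
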