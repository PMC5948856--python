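"""Simulation configuration and scripted-scenario fixtures.

:class:`SimConfig` collects every tunable parameter of the simulated field:
grid geometry, the stochastic bug-appearance process, bug mortality and
feeding rates, the communication strategy and its fumigation window, and
the calibration constants that convert message counts and fumigated hours
into energy and pesticide units.  Configurations are immutable and
validated on construction.

:class:`ScenarioScript` deterministically injects bugs at scripted hours
and positions while optionally disabling the stochastic appearance and
movement processes.  Scripts make strategy semantics reproducible
hour-by-hour, which is what the step-through oracles in the test-suite
rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "STRATEGY_NAMES",
    "SimConfig",
    "ScenarioScript",
    "ConfigError",
    "load_config",
    "save_config",
    "load_scenario",
]

#: Names of the bundled communication strategies.
STRATEGY_NAMES = ("broadcast", "neighbor", "lowcost_neighbor")


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass(frozen=True)
class SimConfig:
    """Immutable bundle of simulation parameters.

    Parameters
    ----------
    columns, rows
        Grid dimensions M x N; one sensor and one crop zone per cell.
    initial_affected_areas
        Number of distinct zones seeded with bugs at hour 0.
    p_appear
        Probability per simulated hour that new bugs appear in the field.
    max_new_bugs
        When an appearance event fires, the bug count is drawn uniformly
        from ``{0, ..., max_new_bugs}``.
    hours
        Simulated duration in hours (one iteration per hour).
    strategy
        Registered strategy name; the bundled ones are
        ``broadcast``, ``neighbor`` and ``lowcost_neighbor``.
    fumigation_window
        Hours ``d`` a low-cost sensor keeps fumigating after a detection;
        also the horizon for suppressing redundant re-warnings.
    bugs_per_initial_area
        Bugs placed in each initially affected zone.
    exposure_hours_to_die
        Cumulative fumigated hours after which a bug dies.
    eat_rate
        Crop health (percentage points) one bug eats per unprotected hour.
    grow_rate
        Crop health regrown per hour (capped at 100); must be below
        ``eat_rate`` (bugs eat much faster than the crop regrows).
    energy_per_message
        Energy units accrued per sent message (calibration constant).
    pesticide_per_fumigation
        Pesticide dispensed per zone per fumigated hour (calibration
        constant, mL in physical terms).
    seed
        Seed of the single RNG that drives the whole run.
    """

    columns: int = 10
    rows: int = 16
    initial_affected_areas: int = 2
    p_appear: float = 0.10
    max_new_bugs: int = 3
    hours: int = 48
    strategy: str = "neighbor"
    fumigation_window: int = 3
    bugs_per_initial_area: int = 1
    exposure_hours_to_die: int = 3
    eat_rate: float = 2.0
    grow_rate: float = 0.1
    energy_per_message: float = 1.0
    pesticide_per_fumigation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.columns < 1 or self.rows < 1:
            raise ConfigError("grid dimensions must be >= 1")
        if not 0.0 <= self.p_appear <= 1.0:
            raise ConfigError(f"p_appear must be in [0, 1], got {self.p_appear}")
        if self.initial_affected_areas < 0:
            raise ConfigError("initial_affected_areas must be >= 0")
        if self.initial_affected_areas > self.columns * self.rows:
            raise ConfigError(
                "initial_affected_areas exceeds the number of zones "
                f"({self.initial_affected_areas} > {self.columns * self.rows})"
            )
        if self.max_new_bugs < 1:
            raise ConfigError("max_new_bugs must be >= 1")
        if self.hours < 0:
            raise ConfigError("hours must be >= 0")
        if self.fumigation_window < 1:
            raise ConfigError("fumigation_window must be >= 1")
        if self.bugs_per_initial_area < 1:
            raise ConfigError("bugs_per_initial_area must be >= 1")
        if self.exposure_hours_to_die < 1:
            raise ConfigError("exposure_hours_to_die must be >= 1")
        for name in ("eat_rate", "grow_rate", "energy_per_message",
                     "pesticide_per_fumigation"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.grow_rate < self.eat_rate:
            raise ConfigError("grow_rate must be strictly below eat_rate")

    @property
    def n_zones(self) -> int:
        return self.columns * self.rows

    def replace(self, **changes: Any) -> "SimConfig":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ScenarioScript:
    """Deterministic infestation schedule for reproducible runs.

    ``spawns`` is a sequence of ``(hour, (x, y), count)`` directives: at
    the start of the given hour, ``count`` bugs are placed in zone
    ``(x, y)``.  With both disabling flags set (the default) a run is a
    pure function of the script, which is what the hand-computed traces
    in the tests require.
    """

    spawns: tuple[tuple[int, tuple[int, int], int], ...] = ()
    disable_movement: bool = True
    disable_appearance: bool = True

    def __post_init__(self) -> None:
        spawns = tuple(
            (int(h), (int(p[0]), int(p[1])), int(c)) for h, p, c in self.spawns
        )
        object.__setattr__(self, "spawns", spawns)

    def validate(self, config: SimConfig) -> None:
        for hour, (x, y), count in self.spawns:
            if not 0 <= hour < config.hours:
                raise ConfigError(f"scripted hour {hour} outside [0, {config.hours})")
            if not (0 <= x < config.columns and 0 <= y < config.rows):
                raise ConfigError(f"scripted zone ({x}, {y}) outside the grid")
            if count < 0:
                raise ConfigError("scripted bug count must be >= 0")

    def spawns_at(self, hour: int) -> list[tuple[tuple[int, int], int]]:
        return [(pos, count) for h, pos, count in self.spawns if h == hour]


_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(SimConfig)}


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> SimConfig:
    """Build a :class:`SimConfig` from defaults, a YAML file and overrides.

    Precedence: explicit ``overrides`` (e.g. CLI flags) > file values >
    built-in defaults.  Unknown keys in either source are rejected with a
    descriptive :class:`ConfigError`.
    """
    values: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(raw)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(values) - set(_CONFIG_FIELDS))
    if unknown:
        raise ConfigError(
            f"unknown configuration keys: {', '.join(unknown)}; "
            f"valid keys are: {', '.join(sorted(_CONFIG_FIELDS))}"
        )
    return SimConfig(**values)


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_scenario(path: str | Path) -> ScenarioScript:
    """Load a scripted scenario from YAML.

    Expected keys: ``spawns`` (list of ``[hour, [x, y], count]``),
    ``disable_movement`` and ``disable_appearance`` (booleans).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"scenario file {path} must contain a mapping")
    known = {"spawns", "disable_movement", "disable_appearance"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown scenario keys: {', '.join(unknown)}")
    spawns = tuple(
        (int(h), (int(p[0]), int(p[1])), int(c))
        for h, p, c in raw.get("spawns", ())
    )
    return ScenarioScript(
        spawns=spawns,
        disable_movement=bool(raw.get("disable_movement", True)),
        disable_appearance=bool(raw.get("disable_appearance", True)),
    )
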