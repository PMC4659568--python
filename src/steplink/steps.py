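"""Declarative definition of the stepwise relaxation schedule.

Every step compares treatment site, gender, birth year and birth month
exactly; the steps differ only in how they treat the event (enrollment /
admission) year and month. The shipped default is the four-step schedule:

====  ==========  ===========
step  event year  event month
====  ==========  ===========
1     exact       exact
2     exact       ignored
3     ignored     ignored
4     within ±1   ignored
====  ==========  ===========
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

import yaml

from .errors import ConfigError

__all__ = [
    "YearMode",
    "MonthMode",
    "MatchStep",
    "DEFAULT_STEPS",
    "default_steps_path",
    "load_steps",
    "dump_steps",
]


def default_steps_path() -> Path:
    """Path of the shipped YAML file encoding the default schedule."""
    return Path(__file__).with_name("default_steps.yaml")


class YearMode(str, Enum):
    EXACT = "EXACT"
    TOLERANCE = "TOLERANCE"
    IGNORED = "IGNORED"


class MonthMode(str, Enum):
    EXACT = "EXACT"
    IGNORED = "IGNORED"


@dataclass(frozen=True)
class MatchStep:
    """One relaxation step's comparison rule for the event date.

    ``year_tolerance`` is calendar-year arithmetic (|2008 − 2007| = 1) and
    is consulted only when ``year_mode`` is TOLERANCE.
    """

    step_number: int
    year_mode: YearMode
    month_mode: MonthMode
    year_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.step_number < 1:
            raise ConfigError(f"step_number must be >= 1, got {self.step_number}")
        if self.year_tolerance < 0:
            raise ConfigError(f"year_tolerance must be >= 0, got {self.year_tolerance}")
        if self.month_mode is MonthMode.EXACT and self.year_mode is not YearMode.EXACT:
            raise ConfigError(
                f"step {self.step_number}: month_mode EXACT requires year_mode EXACT"
            )


DEFAULT_STEPS: tuple[MatchStep, ...] = (
    MatchStep(1, YearMode.EXACT, MonthMode.EXACT),
    MatchStep(2, YearMode.EXACT, MonthMode.IGNORED),
    MatchStep(3, YearMode.IGNORED, MonthMode.IGNORED),
    MatchStep(4, YearMode.TOLERANCE, MonthMode.IGNORED, year_tolerance=1),
)


def steps_from_config(items: Sequence[dict]) -> tuple[MatchStep, ...]:
    """Build a step list from parsed YAML/JSON: an ordered list of
    ``{year_mode, month_mode[, year_tolerance]}`` dicts. Step numbers are
    positional (1-based) unless given explicitly."""
    if not items:
        raise ConfigError("steps config is empty")
    steps = []
    for i, item in enumerate(items, start=1):
        try:
            steps.append(
                MatchStep(
                    step_number=int(item.get("step_number", i)),
                    year_mode=YearMode(str(item["year_mode"]).upper()),
                    month_mode=MonthMode(str(item["month_mode"]).upper()),
                    year_tolerance=int(item.get("year_tolerance", 0)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad step entry #{i}: {item!r} ({exc})") from exc
    return tuple(steps)


def load_steps(path: Union[str, Path]) -> tuple[MatchStep, ...]:
    """Load a step schedule from a YAML or JSON file (a list of step dicts,
    or a mapping with a ``steps`` key)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("steps")
    if not isinstance(data, list):
        raise ConfigError(f"{path}: expected a list of steps")
    return steps_from_config(data)


def dump_steps(steps: Sequence[MatchStep], path: Union[str, Path]) -> None:
    data = [
        {
            "step_number": s.step_number,
            "year_mode": s.year_mode.value,
            "month_mode": s.month_mode.value,
            "year_tolerance": s.year_tolerance,
        }
        for s in steps
    ]
    Path(path).write_text(json.dumps({"steps": data}, indent=2) + "\n")
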