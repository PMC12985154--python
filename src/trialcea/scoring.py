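"""Health-state scoring engines.

Two generic additive scorers are provided:

* :func:`score_eq5d` — maps a five-dimension, five-level (EQ-5D-5L style)
  health profile to a utility through a :class:`ValueSet` (a country tariff:
  full-health constant minus per-dimension, per-level decrements, plus an
  optional constant triggered by any dimension at or beyond a severity level).
* :func:`score_sf6d` — maps a six-dimension (SF-6D style) profile to a
  utility through :class:`SF6DCoefficients` (intercept minus decrements,
  minus an optional "most severe" adjustment).

Real national tariffs are copyrighted tables and are therefore supplied by
the user as structured-text config files; the package ships small synthetic
("toy") coefficient sets for testing only — see :mod:`trialcea.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .exceptions import ConfigurationError, ValidationError

EQ5D_DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")
SF6D_DIMENSIONS: tuple[str, ...] = ("PF", "RL", "SF", "PAIN", "MH", "VIT")


@dataclass(frozen=True)
class HealthState:
    """A five-dimension, five-level health profile (e.g. ``21132``)."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 5:
            raise ValidationError(f"health state needs 5 dimension levels, got {len(self.levels)}")
        for dim, lev in zip(EQ5D_DIMENSIONS, self.levels):
            if not (isinstance(lev, (int,)) and 1 <= lev <= 5):
                raise ValidationError(f"level for dimension {dim} must be an integer in 1..5, got {lev!r}")

    @classmethod
    def from_digits(cls, digits: str | int) -> "HealthState":
        s = str(digits)
        if len(s) != 5 or not s.isdigit():
            raise ValidationError(f"expected a 5-digit profile, got {digits!r}")
        return cls(tuple(int(c) for c in s))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)


def _validate_decrements(decrements: Mapping[str, Mapping[int, float]],
                         dimensions: Sequence[str], max_level: int | None) -> None:
    for dim in dimensions:
        if dim not in decrements:
            raise ConfigurationError(f"value set is missing dimension {dim!r}")
        table = decrements[dim]
        prev = 0.0
        levels = sorted(table)
        if any(l < 2 for l in levels):
            raise ConfigurationError(f"dimension {dim!r}: level-1 decrement is implicitly 0; do not list level 1")
        if max_level is not None and levels and max(levels) > max_level:
            raise ConfigurationError(f"dimension {dim!r}: level beyond {max_level}")
        for lev in levels:
            dec = float(table[lev])
            if dec < 0:
                raise ConfigurationError(f"dimension {dim!r} level {lev}: negative decrement")
            if dec < prev:
                raise ConfigurationError(f"dimension {dim!r}: decrements must be non-decreasing in level")
            prev = dec


@dataclass
class ValueSet:
    """Additive tariff for five-level profiles.

    ``decrements[dim][level]`` is subtracted from ``full_health_value``;
    level 1 always contributes 0. If any dimension's level is at or above
    ``n_level_threshold``, ``n_level_constant`` is subtracted once (the
    shape of the "N5" term found in several national tariffs).
    """

    label: str
    full_health_value: float = 1.0
    decrements: dict[str, dict[int, float]] = field(default_factory=dict)
    n_level_constant: float = 0.0
    n_level_threshold: int = 5

    def __post_init__(self) -> None:
        _validate_decrements(self.decrements, EQ5D_DIMENSIONS, max_level=5)
        worst = self.full_health_value - self.max_total_decrement()
        if not (-1.0 <= worst <= 1.0) or not (-1.0 <= self.full_health_value <= 1.0):
            raise ConfigurationError("value set scores must lie in [-1, 1] for every state")

    def max_total_decrement(self) -> float:
        total = self.n_level_constant
        for dim in EQ5D_DIMENSIONS:
            table = self.decrements[dim]
            total += max(table.values()) if table else 0.0
        return total

    def score(self, state: HealthState | str | int) -> float:
        return score_eq5d(state, self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValueSet":
        decs = {dim: {int(k): float(v) for k, v in tbl.items()}
                for dim, tbl in dict(d.get("decrements", {})).items()}
        return cls(
            label=str(d.get("label", "unnamed")),
            full_health_value=float(d.get("full_health_value", 1.0)),
            decrements=decs,
            n_level_constant=float(d.get("n_level_constant", 0.0)),
            n_level_threshold=int(d.get("n_level_threshold", 5)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValueSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "full_health_value": self.full_health_value,
            "decrements": {d: dict(t) for d, t in self.decrements.items()},
            "n_level_constant": self.n_level_constant,
            "n_level_threshold": self.n_level_threshold,
        }


def score_eq5d(state: HealthState | str | int, value_set: ValueSet) -> float:
    """Utility of a five-level profile under an additive tariff.

    ``full_health_value − Σ decrement(dim, level) − N-level constant``.
    Pure function: deterministic in its inputs.
    """
    if not isinstance(state, HealthState):
        state = HealthState.from_digits(state)
    u = value_set.full_health_value
    for dim, lev in zip(EQ5D_DIMENSIONS, state.levels):
        if lev > 1:
            table = value_set.decrements[dim]
            if lev not in table:
                raise ConfigurationError(f"value set {value_set.label!r} has no decrement for {dim} level {lev}")
            u -= table[lev]
    if value_set.n_level_constant and any(l >= value_set.n_level_threshold for l in state.levels):
        u -= value_set.n_level_constant
    return u


@dataclass
class SF6DCoefficients:
    """Additive SF-6D style scoring equation.

    Six dimensions with heterogeneous level counts; ``most_severe_constant``
    is subtracted once if any dimension sits at its own worst listed level
    (the "MOST" term of the published scoring equations).
    """

    label: str
    intercept: float = 1.0
    decrements: dict[str, dict[int, float]] = field(default_factory=dict)
    most_severe_constant: float = 0.0

    def __post_init__(self) -> None:
        _validate_decrements(self.decrements, SF6D_DIMENSIONS, max_level=None)
        worst = self.intercept - self.max_total_decrement()
        if not (0.0 < worst <= 1.0):
            raise ConfigurationError("SF-6D coefficients must score every profile in (0, 1]")

    def max_total_decrement(self) -> float:
        total = self.most_severe_constant
        for dim in SF6D_DIMENSIONS:
            table = self.decrements[dim]
            total += max(table.values()) if table else 0.0
        return total

    def worst_level(self, dim: str) -> int:
        table = self.decrements[dim]
        return max(table) if table else 1

    def score(self, levels: Sequence[int]) -> float:
        return score_sf6d(levels, self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SF6DCoefficients":
        decs = {dim: {int(k): float(v) for k, v in tbl.items()}
                for dim, tbl in dict(d.get("decrements", {})).items()}
        return cls(
            label=str(d.get("label", "unnamed")),
            intercept=float(d.get("intercept", 1.0)),
            decrements=decs,
            most_severe_constant=float(d.get("most_severe_constant", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SF6DCoefficients":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "intercept": self.intercept,
            "decrements": {d: dict(t) for d, t in self.decrements.items()},
            "most_severe_constant": self.most_severe_constant,
        }


def score_sf6d(levels: Sequence[int], coef: SF6DCoefficients) -> float:
    """Utility of a six-dimension profile: intercept − Σ decrements − MOST term."""
    levels = tuple(int(v) for v in levels)
    if len(levels) != 6:
        raise ValidationError(f"SF-6D profile needs 6 dimension levels, got {len(levels)}")
    u = coef.intercept
    most_severe = False
    for dim, lev in zip(SF6D_DIMENSIONS, levels):
        table = coef.decrements[dim]
        worst = max(table) if table else 1
        if lev < 1 or lev > worst:
            raise ValidationError(f"dimension {dim}: level {lev} outside 1..{worst}")
        if lev > 1:
            u -= table[lev]
        if lev == worst and worst > 1:
            most_severe = True
    if most_severe:
        u -= coef.most_severe_constant
    return u
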