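"""All-cause mortality life tables and residual life expectancy.

The cohort model charges each premature cancer death with the remaining life
expectancy the person would otherwise have enjoyed, taken from a standard
population life table.  The published Hong Kong table this model emulates is
not reproduced here; a Gompertz–Makeham synthetic stand-in with comparable
longevity (residual life expectancy at 50 of roughly 33 years) ships as the
default, and any (age, qx) CSV can be substituted.

Deaths are end-of-year events (no half-cycle correction), matching a simple
annual-cycle spreadsheet cohort model, so expectations are curtate:
``ex = sum_{t>=1} prod_{k<t} (1 - q(age+k))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MakehamSpec",
    "synthesize_life_table",
    "residual_life_expectancy",
    "discounted_residual_life_years",
    "read_life_table",
    "write_life_table",
    "default_life_table",
    "DEFAULT_MAKEHAM",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx for contiguous integer ages.

    Closure: qx at ``max_age`` is 1 (nobody survives the final age).
    """

    start_age: int
    qx: np.ndarray = field(repr=False)  # qx[i] applies at age start_age + i

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", q)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("qx must be a non-empty 1-D array")
        if np.any((q < 0) | (q > 1)):
            bad = int(np.argmax((q < 0) | (q > 1)))
            raise ValueError(f"qx out of [0,1] at age {self.start_age + bad}: {q[bad]}")
        if q[-1] != 1.0:
            raise ValueError(f"life table must close with qx=1 at max_age {self.max_age}")

    @property
    def max_age(self) -> int:
        return self.start_age + len(self.qx) - 1

    def q_at(self, age: int) -> float:
        if not (self.start_age <= age <= self.max_age):
            raise ValueError(f"age {age} outside life table [{self.start_age}, {self.max_age}]")
        return float(self.qx[age - self.start_age])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LifeTable)
            and self.start_age == other.start_age
            and np.array_equal(self.qx, other.qx)
        )


@dataclass(frozen=True)
class MakehamSpec:
    """Gompertz–Makeham hazard: mu(age) = c + a * exp(b * age).

    ``a`` scales the senescent (Gompertz) component, ``b`` is its slope per
    year of age, ``c`` is the age-independent background hazard.  All are
    annual hazards.  ``seed`` is kept for interface symmetry; the default
    synthesis is deterministic and applies no jitter.
    """

    a: float = 2e-5
    b: float = 0.095
    c: float = 5e-4
    max_age: int = 100
    start_age: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("Makeham parameters must be non-negative")


DEFAULT_MAKEHAM = MakehamSpec()


def synthesize_life_table(spec: MakehamSpec = DEFAULT_MAKEHAM) -> LifeTable:
    """Deterministic life table from a Gompertz–Makeham hazard.

    qx(age) = 1 - exp(-(c + a*exp(b*age))) for age < max_age; qx(max_age)=1.
    Raises if the hazard drives qx above 1 before max_age (with the age).
    """
    ages = np.arange(spec.start_age, spec.max_age + 1)
    hazard = spec.c + spec.a * np.exp(spec.b * ages.astype(float))
    q = 1.0 - np.exp(-hazard)
    # exp() keeps q < 1 mathematically; guard against overflow to inf
    bad = np.nonzero(~np.isfinite(q) | (q > 1))[0]
    if bad.size and ages[bad[0]] < spec.max_age:
        raise ValueError(f"hazard produces qx>1 at age {int(ages[bad[0]])}")
    q[-1] = 1.0
    return LifeTable(start_age=spec.start_age, qx=q)


def residual_life_expectancy(table: LifeTable, age: int) -> float:
    """Curtate expected remaining years at ``age`` (survival-product sum)."""
    if not (table.start_age <= age <= table.max_age):
        raise ValueError(f"age {age} outside life table [{table.start_age}, {table.max_age}]")
    q = table.qx[age - table.start_age :]
    surv = np.cumprod(1.0 - q)  # surv[t-1] = P(alive after year t)
    return float(surv.sum())


def discounted_residual_life_years(
    table: LifeTable, age: int, r: float, years_from_model_start: float = 0.0
) -> float:
    """Present value of remaining life years at ``age``.

    Year ``t`` of remaining survival (t = 1, 2, ...) is discounted by
    ``(1+r)^-(years_from_model_start + t)``; anchoring at model start keeps
    life-year and cost discounting on one clock.  Reduces to
    :func:`residual_life_expectancy` at ``r = 0``.
    """
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    if not (table.start_age <= age <= table.max_age):
        raise ValueError(f"age {age} outside life table [{table.start_age}, {table.max_age}]")
    q = table.qx[age - table.start_age :]
    surv = np.cumprod(1.0 - q)
    t = np.arange(1, len(surv) + 1, dtype=float)
    disc = (1.0 + r) ** (-(years_from_model_start + t))
    return float((surv * disc).sum())


def read_life_table(path: str | Path) -> LifeTable:
    """Read an (age, qx) CSV with header; ages must be contiguous."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "age" not in cols or "qx" not in cols:
        raise ValueError(f"life table CSV {path} must have 'age' and 'qx' columns")
    ages = df[cols["age"]].to_numpy(dtype=int)
    if len(ages) == 0:
        raise ValueError(f"life table CSV {path} is empty")
    if len(np.unique(ages)) != len(ages):
        raise ValueError(f"duplicate ages in life table {path}")
    order = np.argsort(ages)
    ages = ages[order]
    gaps = np.nonzero(np.diff(ages) != 1)[0]
    if gaps.size:
        raise ValueError(f"non-contiguous ages in {path}: gap after age {int(ages[gaps[0]])}")
    q = df[cols["qx"]].to_numpy(dtype=float)[order]
    return LifeTable(start_age=int(ages[0]), qx=q)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    ages = np.arange(table.start_age, table.max_age + 1)
    # %.17g keeps the float64 values exact across a write/read round trip
    pd.DataFrame({"age": ages, "qx": table.qx}).to_csv(path, index=False, float_format="%.17g")


def default_life_table() -> LifeTable:
    """The shipped synthetic high-longevity table (Makeham defaults)."""
    return synthesize_life_table(DEFAULT_MAKEHAM)


def resolve_life_table(source: str) -> LifeTable:
    """Resolve a ModelConfig ``life_table_source`` string.

    ``"synthetic:default"`` → shipped Makeham table; any other string is a
    CSV path.
    """
    if source == "synthetic:default":
        return default_life_table()
    if source.startswith("synthetic:"):
        raise ValueError(f"unknown synthetic life-table spec {source!r}")
    return read_life_table(source)
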