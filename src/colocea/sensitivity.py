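"""Deterministic one-way and two-way sensitivity analyses with thresholds.

Each sweep re-runs the full strategy comparison at every grid value of a
parameter (all other parameters held at their configured values) and
extracts ICER curves.  The special parameter path ``"compliance.all"``
moves the FIT, primary-colonoscopy, and follow-up compliance rates
together, the convention used when testing programme uptake.  Threshold
detection finds parameter values where a criterion (for example the ICER
difference between two strategies) changes sign, by linear interpolation
between adjacent grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import StrategyComparison
from .config import STRATEGY_IDS, ModelConfig
from .lifetables import LifeTable, resolve_life_table
from .pipeline import run_comparison

__all__ = [
    "SweepSpec",
    "SweepResult",
    "one_way_sweep",
    "two_way_sweep",
    "find_threshold",
    "DEFAULT_GRIDS",
    "apply_parameter",
]

#: Default grids: compliance over its tested 10%-100% range; FIT specificity
#: down to 20%; colonoscopy and stage-care costs at 0.5x-2x base.
DEFAULT_GRIDS: dict[str, list[float]] = {
    "compliance.all": [round(0.1 * k, 1) for k in range(1, 11)],
    "tests.fit_specificity": list(np.round(np.linspace(0.20, 0.919, 8), 4)),
    "tests.fit_sensitivity": list(np.round(np.linspace(0.40, 1.00, 7), 4)),
    "costs.colonoscopy": [round(1259 * f) for f in (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)],
}

_COMPLIANCE_FIELDS = (
    "compliance.fit_compliance",
    "compliance.colonoscopy_primary_compliance",
    "compliance.colonoscopy_after_positive_compliance",
)


@dataclass(frozen=True)
class SweepSpec:
    """One swept parameter: dotted path, monotone grid, comparison focus."""

    parameter_path: str
    grid: tuple[float, ...]
    comparison: str = "all_vs_none"

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        diffs = np.diff(self.grid)
        if len(self.grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sweep grid must be strictly monotone")


def apply_parameter(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """Override one dotted-path parameter (compliance.all moves all three)."""
    if path == "compliance.all":
        return config.with_overrides(**{f: value for f in _COMPLIANCE_FIELDS})
    return config.with_overrides(**{path: value})


@dataclass
class SweepResult:
    spec: SweepSpec
    comparisons: list[StrategyComparison]
    spec_b: Optional[SweepSpec] = None
    grid_points: list[tuple] = field(default_factory=list)

    def icer_curve(self, strategy_id: str, comparator_id: str = "none") -> np.ndarray:
        """ICER values (may contain NaN where undefined) along the grid."""
        return np.array([c.icer(strategy_id, comparator_id).value for c in self.comparisons])

    def to_long(self) -> pd.DataFrame:
        """Long-format table: grid value(s) x strategy x measure."""
        rows = []
        for point, comp in zip(self.grid_points, self.comparisons):
            df = comp.to_dataframe()
            for _, row in df.iterrows():
                base = {"parameter": self.spec.parameter_path, "value": point[0]}
                if self.spec_b is not None:
                    base["parameter_b"] = self.spec_b.parameter_path
                    base["value_b"] = point[1]
                for measure in (
                    "crc_cases", "cancer_life_years_lost", "life_years_saved",
                    "total_cost", "additional_cost", "icer_vs_baseline",
                    "cost_per_life_year_saved",
                ):
                    rows.append({**base, "strategy": row["strategy"], "measure": measure,
                                 "result": row[measure]})
        return pd.DataFrame(rows)


def one_way_sweep(
    config: ModelConfig,
    spec: SweepSpec,
    table: Optional[LifeTable] = None,
    strategies: Sequence[str] = STRATEGY_IDS,
) -> SweepResult:
    """Re-run the comparison at each grid value of one parameter."""
    if table is None:
        table = resolve_life_table(config.life_table_source)
    comparisons = []
    points = []
    for value in spec.grid:
        cfg = apply_parameter(config, spec.parameter_path, value)
        comparisons.append(run_comparison(cfg, table, strategies))
        points.append((value,))
    return SweepResult(spec=spec, comparisons=comparisons, grid_points=points)


def two_way_sweep(
    config: ModelConfig,
    spec_a: SweepSpec,
    spec_b: SweepSpec,
    table: Optional[LifeTable] = None,
    strategies: Sequence[str] = STRATEGY_IDS,
) -> SweepResult:
    """Cartesian grid over two parameters (row-major: a outer, b inner)."""
    if table is None:
        table = resolve_life_table(config.life_table_source)
    comparisons = []
    points = []
    for va in spec_a.grid:
        cfg_a = apply_parameter(config, spec_a.parameter_path, va)
        for vb in spec_b.grid:
            cfg = apply_parameter(cfg_a, spec_b.parameter_path, vb)
            comparisons.append(run_comparison(cfg, table, strategies))
            points.append((va, vb))
    return SweepResult(spec=spec_a, comparisons=comparisons, spec_b=spec_b, grid_points=points)


def find_threshold(x: Sequence[float], y: Sequence[float]) -> list[float]:
    """Parameter values where ``y`` crosses zero, by linear interpolation.

    Returns every crossing (empty list when the curve is one-signed); exact
    zeros at grid points are reported at the grid value.  Callers wanting a
    single answer take the first element.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    crossings: list[float] = []
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if np.isnan(y0) or np.isnan(y1):
            continue
        if y0 == 0.0:
            crossings.append(float(x[i]))
        elif y0 * y1 < 0:
            crossings.append(float(x[i] + (x[i + 1] - x[i]) * (-y0) / (y1 - y0)))
    if len(y) and y[-1] == 0.0:
        crossings.append(float(x[-1]))
    return crossings
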