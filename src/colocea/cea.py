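"""Cost-effectiveness outcome measures and the ICER/dominance comparison.

Effectiveness is measured in life years saved: the reduction in discounted
cancer-related life years lost relative to the no-screening comparator.  The
incremental cost-effectiveness ratio (ICER) between two strategies is the
cost difference divided by the effectiveness difference; when one strategy
is both cheaper and more effective it dominates the other and the pairwise
ratio is reported negative with a dominance flag.  All derived rows keep
full precision internally; rounding (integer counts, whole dollars, one
decimal for percentages, half-up) happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .pathways import ComplicationCounts, ProcedureCounts

__all__ = [
    "StrategyOutcome",
    "IcerResult",
    "StrategyComparison",
    "cases_prevented",
    "proportion_prevented",
    "life_years_saved",
    "additional_cost",
    "icer",
    "cost_per_life_year_saved",
    "comparison_table",
    "round_half_up",
]

STRATEGY_LABELS = {
    "none": "No screening",
    "fit_colo": "FIT + colonoscopy",
    "fit_ai": "FIT + AI colonoscopy",
    "colo": "Direct colonoscopy",
    "ai_colo": "Direct AI colonoscopy",
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), presentation only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StrategyOutcome:
    """Per-strategy totals feeding the comparison (discounted money/LYs)."""

    strategy_id: str
    crc_cases: float
    cancer_life_years_lost: float
    total_cost: float
    procedures: ProcedureCounts = field(default_factory=ProcedureCounts)
    complications: ComplicationCounts = field(default_factory=ComplicationCounts)
    cost_by_category: Optional[dict] = None


@dataclass(frozen=True)
class IcerResult:
    """Pairwise incremental ratio with a dominance/undefined flag.

    ``flag`` is one of ``""`` (ordinary trade-off), ``"dominant"`` (the first
    strategy is cheaper and more effective), ``"dominated"`` (the first is
    pricier and less effective), ``"undefined"`` (equal effectiveness, no
    division performed — ``value`` is NaN).
    """

    value: float
    flag: str = ""

    @property
    def defined(self) -> bool:
        return self.flag != "undefined"


def cases_prevented(baseline_cases: float, strategy_cases: float) -> float:
    """Baseline minus strategy case count (may be negative; never clipped)."""
    return baseline_cases - strategy_cases


def proportion_prevented(prevented: float, baseline_cases: float) -> float:
    """Percent of baseline cases prevented, reported to one decimal."""
    if baseline_cases <= 0:
        raise ValueError("baseline case count must be positive")
    return round_half_up(100.0 * prevented / baseline_cases, 1)


def life_years_saved(baseline_lyl: float, strategy_lyl: float) -> float:
    return baseline_lyl - strategy_lyl


def additional_cost(strategy_total: float, baseline_total: float) -> float:
    return strategy_total - baseline_total


def icer(a: StrategyOutcome, b: StrategyOutcome) -> IcerResult:
    """ICER of strategy ``a`` against comparator ``b``.

    Effectiveness differences reduce to ``b.lyl - a.lyl`` (the common
    no-screening baseline cancels), so no baseline is needed here.
    """
    d_cost = a.total_cost - b.total_cost
    d_eff = b.cancer_life_years_lost - a.cancer_life_years_lost
    if d_eff == 0.0:
        return IcerResult(math.nan, "undefined")
    flag = ""
    if d_cost < 0 and d_eff > 0:
        flag = "dominant"
    elif d_cost > 0 and d_eff < 0:
        flag = "dominated"
    return IcerResult(d_cost / d_eff, flag)


def cost_per_life_year_saved(total: float, lys: float) -> IcerResult:
    """Average total cost per life year saved (undefined at zero effect)."""
    if lys < 0:
        raise ValueError("life years saved must be non-negative here")
    if lys == 0.0:
        return IcerResult(math.nan, "undefined")
    return IcerResult(total / lys)


@dataclass
class StrategyComparison:
    """The per-strategy outcome table plus the pairwise ICER matrix."""

    outcomes: dict[str, StrategyOutcome]
    baseline_id: str = "none"

    def __post_init__(self) -> None:
        if self.baseline_id not in self.outcomes:
            raise ValueError(f"missing baseline strategy {self.baseline_id!r}")

    @property
    def baseline(self) -> StrategyOutcome:
        return self.outcomes[self.baseline_id]

    def cases_prevented(self, strategy_id: str) -> float:
        return cases_prevented(self.baseline.crc_cases, self.outcomes[strategy_id].crc_cases)

    def proportion_prevented(self, strategy_id: str) -> float:
        return proportion_prevented(self.cases_prevented(strategy_id), self.baseline.crc_cases)

    def life_years_saved(self, strategy_id: str) -> float:
        return life_years_saved(
            self.baseline.cancer_life_years_lost, self.outcomes[strategy_id].cancer_life_years_lost
        )

    def additional_cost(self, strategy_id: str) -> float:
        return additional_cost(self.outcomes[strategy_id].total_cost, self.baseline.total_cost)

    def icer(self, strategy_id: str, comparator_id: str) -> IcerResult:
        return icer(self.outcomes[strategy_id], self.outcomes[comparator_id])

    def cost_per_life_year_saved(self, strategy_id: str) -> IcerResult:
        return cost_per_life_year_saved(
            self.outcomes[strategy_id].total_cost, max(self.life_years_saved(strategy_id), 0.0)
        )

    def icer_matrix(self) -> pd.DataFrame:
        ids = list(self.outcomes)
        rows = []
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                res = self.icer(a, b)
                rows.append({"strategy": a, "comparator": b, "icer": res.value, "flag": res.flag})
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Full-precision per-strategy summary (baseline first)."""
        ids = [self.baseline_id] + sorted(i for i in self.outcomes if i != self.baseline_id)
        rows = []
        for sid in ids:
            o = self.outcomes[sid]
            lys = self.life_years_saved(sid)
            cpl = self.cost_per_life_year_saved(sid)
            ic = self.icer(sid, self.baseline_id) if sid != self.baseline_id else IcerResult(math.nan, "undefined")
            rows.append({
                "strategy": sid,
                "label": STRATEGY_LABELS.get(sid, sid),
                "crc_cases": o.crc_cases,
                "cancer_life_years_lost": o.cancer_life_years_lost,
                "cases_prevented": self.cases_prevented(sid),
                "proportion_prevented_pct": self.proportion_prevented(sid),
                "life_years_saved": lys,
                "fit_count": o.procedures.fit,
                "colonoscopy_count": o.procedures.colonoscopy_total,
                "colonoscopy_diagnostic": o.procedures.colonoscopy_diagnostic,
                "colonoscopy_therapeutic": o.procedures.colonoscopy_therapeutic,
                "bleeding": o.complications.bleeding,
                "perforation": o.complications.perforation,
                "total_cost": o.total_cost,
                "additional_cost": self.additional_cost(sid),
                "cost_per_life_year_saved": cpl.value,
                "icer_vs_baseline": ic.value,
                "icer_flag": ic.flag,
            })
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        """Aligned presentation table with rounded values."""
        df = self.to_dataframe()
        lines = []
        header = f"{'Strategy':<24}{'Cases':>8}{'LYL':>10}{'Prev %':>8}{'LYS':>10}{'Total cost':>16}{'ICER vs none':>14}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, row in df.iterrows():
            ic = row["icer_vs_baseline"]
            ic_s = "-" if not math.isfinite(ic) else f"{round_half_up(ic):,.0f}"
            lines.append(
                f"{row['label']:<24}{round_half_up(row['crc_cases']):>8,.0f}"
                f"{round_half_up(row['cancer_life_years_lost']):>10,.0f}"
                f"{row['proportion_prevented_pct']:>8.1f}"
                f"{round_half_up(row['life_years_saved']):>10,.0f}"
                f"{round_half_up(row['total_cost']):>16,.0f}"
                f"{ic_s:>14}"
            )
        return "\n".join(lines)


def comparison_table(outcomes: list[StrategyOutcome], baseline_id: str = "none") -> StrategyComparison:
    """Assemble the comparison from per-strategy outcomes (order-invariant)."""
    mapping = {o.strategy_id: o for o in outcomes}
    if len(mapping) != len(outcomes):
        raise ValueError("duplicate strategy ids in outcomes")
    return StrategyComparison(outcomes=mapping, baseline_id=baseline_id)
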