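"""End-to-end helpers: config + life table -> per-strategy outcomes -> comparison."""

from __future__ import annotations

from typing import Iterable, Optional

from .cea import StrategyComparison, StrategyOutcome, comparison_table
from .config import STRATEGY_IDS, ModelConfig, config_digest
from .costing import accumulate_costs
from .engine import CohortTrace, run_cohort
from .lifetables import LifeTable, resolve_life_table

__all__ = ["strategy_outcome", "run_all_strategies", "run_comparison"]


def strategy_outcome(
    config: ModelConfig,
    strategy_id: str,
    table: Optional[LifeTable] = None,
    trace: Optional[CohortTrace] = None,
) -> StrategyOutcome:
    """Run one strategy and fold its trace into comparison-ready totals.

    Effectiveness uses the discounted cancer-related life-years-lost ledger;
    costs are discounted at the configured rate.
    """
    if trace is None:
        if table is None:
            table = resolve_life_table(config.life_table_source)
        trace = run_cohort(config, strategy_id, table)
    costs = accumulate_costs(trace, config.costs, config.economics.discount_rate)
    return StrategyOutcome(
        strategy_id=trace.strategy_id,
        crc_cases=trace.total_cases,
        cancer_life_years_lost=trace.life_years_lost_discounted,
        total_cost=costs.total,
        procedures=trace.procedures(),
        complications=trace.complications(),
        cost_by_category=costs.by_category(),
    )


def run_all_strategies(
    config: ModelConfig,
    table: Optional[LifeTable] = None,
    strategies: Iterable[str] = STRATEGY_IDS,
) -> list[StrategyOutcome]:
    if table is None:
        table = resolve_life_table(config.life_table_source)
    return [strategy_outcome(config, sid, table) for sid in strategies]


def run_comparison(
    config: ModelConfig,
    table: Optional[LifeTable] = None,
    strategies: Iterable[str] = STRATEGY_IDS,
) -> StrategyComparison:
    """Full base-model comparison across strategies (baseline: no screening)."""
    return comparison_table(run_all_strategies(config, table, strategies))
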