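"""Reference per-strategy outcome totals for the comparison arithmetic.

These are the published base-case totals for a 100,000-person average-risk
Hong Kong cohort screened from age 50 to 75 — CRC cases, discounted
cancer-related life years lost, discounted total cost, and procedure /
complication counts for each strategy.  They serve as a fixed input for
exercising the incremental cost-effectiveness arithmetic independently of
the cohort engine (``colocea fixtures table3`` on the command line).
"""

from __future__ import annotations

from .cea import StrategyOutcome, comparison_table
from .pathways import ComplicationCounts, ProcedureCounts

__all__ = ["reference_outcomes", "reference_comparison"]

_ROWS = {
    # strategy_id: (cases, life-years lost, total cost,
    #               fit, colo_diag, colo_ther, bleeding, perforation)
    "none":     (3233, 5635, 225_515_010, 0, 0, 0, 0, 0),
    "fit_colo": (3113, 5355, 264_303_185, 236_883, 9_891, 26_744, 73, 29),
    "fit_ai":   (3100, 5327, 263_275_923, 236_897, 9_896, 26_756, 73, 29),
    "colo":     (1879, 3251, 711_728_628, 0, 141_505, 367_452, 1018, 403),
    "ai_colo":  (1733, 2996, 701_769_288, 0, 141_505, 367_638, 1018, 403),
}


def reference_outcomes() -> list[StrategyOutcome]:
    """The reference totals as StrategyOutcome records."""
    out = []
    for sid, (cases, lyl, cost, fit, diag, ther, bleed, perf) in _ROWS.items():
        out.append(
            StrategyOutcome(
                strategy_id=sid,
                crc_cases=float(cases),
                cancer_life_years_lost=float(lyl),
                total_cost=float(cost),
                procedures=ProcedureCounts(
                    fit=float(fit),
                    colonoscopy_diagnostic=float(diag),
                    colonoscopy_therapeutic=float(ther),
                ),
                complications=ComplicationCounts(bleeding=float(bleed), perforation=float(perf)),
            )
        )
    return out


def reference_comparison():
    """Comparison table built from the reference totals."""
    return comparison_table(reference_outcomes())
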