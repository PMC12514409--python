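"""Seeded individual-level simulation mirroring the cohort recursion.

This is a test oracle: it draws each person's annual events (other-cause
death, screening uptake, FIT result, colonoscopy findings, complications,
cancer incidence, stage, CRC death) from the exact per-cycle probabilities
that the deterministic engine applies to expected masses, so its summaries
converge to the engine's outputs as n grows.  It is never the primary
computation path.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .config import ModelConfig, StrategySchedule
from .engine import coerce_strategy
from .lifetables import LifeTable, discounted_residual_life_years, residual_life_expectancy
from .pathways import fit_positivity

__all__ = ["MicrosimSummary", "microsim_oracle"]

# susceptible sub-states
_FITWAIT, _HIATUS, _SURV, _WAIT, _UWAIT = 0, 1, 2, 3, 4
# person status
_SUS, _DX, _CURED, _DEAD_OTHER, _DEAD_CRC, _DEAD_PERF = 0, 1, 2, 3, 4, 5

_METRICS = (
    "cases", "crc_deaths", "life_years_lost", "life_years_lost_discounted",
    "fits", "colonoscopies", "therapeutic", "diagnostic",
    "bleeding", "perforation", "perforation_deaths",
)


@dataclass
class MicrosimSummary:
    """Batch-mean summaries scaled to the cohort size, with standard errors."""

    n: int
    batches: int
    cases: float = 0.0
    crc_deaths: float = 0.0
    life_years_lost: float = 0.0
    life_years_lost_discounted: float = 0.0
    fits: float = 0.0
    colonoscopies: float = 0.0
    therapeutic: float = 0.0
    diagnostic: float = 0.0
    bleeding: float = 0.0
    perforation: float = 0.0
    perforation_deaths: float = 0.0
    se: dict = None  # type: ignore[assignment]


def _simulate_batch(
    config: ModelConfig, strategy: StrategySchedule, table: LifeTable, n: int, rng: np.random.Generator
) -> dict[str, float]:
    eco = config.economics
    r = eco.discount_rate
    incidence_stop = eco.effective_incidence_stop_age
    stage_dist = np.asarray(config.stages.stage_distribution)
    if config.stages.screened_stage_distribution is not None and strategy.strategy_id != "none":
        stage_dist = np.asarray(config.stages.screened_stage_distribution)
    stage_cum = np.cumsum(stage_dist)
    stage_mort = np.asarray(config.stages.annual_stage_mortality)
    cure_years = config.stages.years_to_cure
    red_fit = config.efficacy.incidence_reduction_fit
    red_colo = (
        config.efficacy.incidence_reduction_ai_colonoscopy
        if strategy.uses_ai
        else config.efficacy.incidence_reduction_colonoscopy
    )
    comp = config.compliance
    kk = config.complications

    status = np.full(n, _SUS, dtype=np.int8)
    sub = np.full(n, _UWAIT if strategy.is_direct else _FITWAIT, dtype=np.int8)
    ctr = np.zeros(n, dtype=np.int16)
    fitneg = np.zeros(n, dtype=bool)
    stage = np.zeros(n, dtype=np.int8)
    clock = np.zeros(n, dtype=np.int16)

    totals = {m: 0.0 for m in _METRICS}

    def colonoscopy(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run colonoscopies on ``mask``; returns (to_surveillance, to_clean)."""
        m = int(mask.sum())
        totals["colonoscopies"] += m
        ther = mask & (rng.random(n) < kk.polypectomy_rate)
        totals["therapeutic"] += int(ther.sum())
        totals["diagnostic"] += m - int(ther.sum())
        totals["bleeding"] += int((mask & (rng.random(n) < kk.bleeding_rate)).sum())
        perf = mask & (rng.random(n) < kk.perforation_rate)
        totals["perforation"] += int(perf.sum())
        dead = perf & (rng.random(n) < kk.perforation_mortality)
        ndead = int(dead.sum())
        totals["perforation_deaths"] += ndead
        if ndead:
            status[dead] = _DEAD_PERF
        return ther & ~dead, mask & ~ther & ~dead

    for t in range(0, eco.horizon_age - eco.start_age + 1):
        age = eco.start_age + t
        qx = table.q_at(age)
        alive = status <= _CURED
        dies = alive & (rng.random(n) < qx)
        status[dies] = _DEAD_OTHER

        sus = status == _SUS
        if strategy.strategy_id != "none" and age < eco.screening_stop_age:
            prevalence = config.incidence.rate_at(age) if age < incidence_stop else 0.0
            positivity = fit_positivity(
                config.tests.fit_sensitivity, config.tests.fit_specificity, prevalence
            )
            if strategy.uses_fit:
                expired = sus & (sub == _HIATUS) & (ctr == 0)
                sub[expired] = _FITWAIT
                ctr[expired] = 0
                due = sus & (sub == _FITWAIT) & (ctr == 0)
                take = due & (rng.random(n) < comp.fit_compliance)
                totals["fits"] += int(take.sum())
                pos = take & (rng.random(n) < positivity)
                neg = take & ~pos
                ctr[neg] = strategy.fit_interval
                fitneg[neg] = True
                ctr[due & ~take] = 1
                attend = pos & (rng.random(n) < comp.colonoscopy_after_positive_compliance)
                ctr[pos & ~attend] = 1
                to_surv, to_clean = colonoscopy(attend)
                sub[to_surv] = _SURV
                ctr[to_surv] = strategy.surveillance_interval
                sub[to_clean] = _HIATUS
                ctr[to_clean] = strategy.post_normal_colonoscopy_hiatus
            else:
                due = sus & ((sub == _WAIT) | (sub == _UWAIT)) & (ctr == 0)
                comply = due & (rng.random(n) < comp.colonoscopy_primary_compliance)
                refuse = due & ~comply
                sub[refuse] = _UWAIT
                ctr[refuse] = strategy.post_normal_colonoscopy_hiatus
                to_surv, to_clean = colonoscopy(comply)
                sub[to_surv] = _SURV
                ctr[to_surv] = strategy.surveillance_interval
                sub[to_clean] = _WAIT
                ctr[to_clean] = strategy.post_normal_colonoscopy_hiatus

            sus = status == _SUS  # perforation deaths removed
            duev = sus & (sub == _SURV) & (ctr == 0)
            attendv = duev & (rng.random(n) < comp.colonoscopy_after_positive_compliance)
            dropout = duev & ~attendv  # off-schedule: protection lapses
            sub[dropout] = _FITWAIT if strategy.uses_fit else _UWAIT
            ctr[dropout] = 1
            to_surv, to_clean = colonoscopy(attendv)
            sub[to_surv] = _SURV
            ctr[to_surv] = strategy.surveillance_interval
            clean_dest = _HIATUS if strategy.uses_fit else _WAIT
            sub[to_clean] = clean_dest
            ctr[to_clean] = strategy.post_normal_colonoscopy_hiatus

        sus = status == _SUS

        if age < incidence_stop:
            h = config.incidence.rate_at(age)
            rate = np.full(n, h)
            if strategy.strategy_id != "none":
                colo_prot = (sub == _HIATUS) | (sub == _SURV) | (sub == _WAIT)
                rate[colo_prot] = h * (1.0 - red_colo)
                rate[fitneg] = h * (1.0 - red_fit)
            newdx = sus & (rng.random(n) < rate)
            k = int(newdx.sum())
            if k:
                totals["cases"] += k
                status[newdx] = _DX
                stage[newdx] = np.searchsorted(stage_cum, rng.random(k), side="right").astype(np.int8)
                clock[newdx] = 0

        dxm = status == _DX
        dies_crc = dxm & (rng.random(n) < stage_mort[np.clip(stage, 0, 3)])
        d = int(dies_crc.sum())
        if d:
            status[dies_crc] = _DEAD_CRC
            totals["crc_deaths"] += d
            totals["life_years_lost"] += d * residual_life_expectancy(table, age)
            totals["life_years_lost_discounted"] += d * discounted_residual_life_years(table, age, r, t)
        surv_dx = dxm & ~dies_crc
        clock[surv_dx] += 1
        cured_now = surv_dx & (clock >= cure_years)
        status[cured_now] = _CURED

        ticking = (status == _SUS) & (ctr > 0)
        ctr[ticking] -= 1
        fitneg[:] = False

    return totals


def microsim_oracle(
    config: ModelConfig,
    strategy: "StrategySchedule | str",
    table: LifeTable,
    n: int,
    seed: int,
    batches: int = 10,
) -> MicrosimSummary:
    """Simulate ``n`` individuals in ``batches`` independent batches.

    Returns batch-mean summaries scaled to the configured cohort size, with
    Monte-Carlo standard errors (std of batch means / sqrt(batches)).
    Reproducible: the same seed yields identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    strategy = coerce_strategy(strategy)
    rng = np.random.default_rng(seed)
    sizes = [n // batches] * batches
    sizes[-1] += n - sum(sizes)
    scale = config.economics.cohort_size
    per_batch: dict[str, list[float]] = {m: [] for m in _METRICS}
    for bn in sizes:
        totals = _simulate_batch(config, strategy, table, bn, rng)
        for m in _METRICS:
            per_batch[m].append(totals[m] / bn * scale)
    means = {m: float(np.mean(per_batch[m])) for m in _METRICS}
    ses = {
        m: float(np.std(per_batch[m], ddof=1) / np.sqrt(batches)) if batches > 1 else float("nan")
        for m in _METRICS
    }
    return MicrosimSummary(n=n, batches=batches, se=ses, **means)
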