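"""Screening-strategy logic: test scheduling, positivity, and procedure flow.

Two families of strategies are modelled.  FIT-based arms offer an annual
fecal immunochemical test; positives proceed to (conventional or AI-assisted)
colonoscopy, after which polyp-free participants pause screening for ten
years before resuming annual FIT, while participants with polyps removed
enter three-yearly surveillance colonoscopy until a polyp-free exam.  Direct
arms offer a primary colonoscopy, repeated every ten years when clean, with
the same three-yearly surveillance loop after polypectomy.

The state machines below push *expected masses* (fractions of the cohort)
through these schedules with one-year resolution; tunnel counters encode the
"k years until the next event" memory.  Each susceptible mass lives in
exactly one sub-state, and the machines conserve total mass to float
precision.  Protection against cancer incidence is classified by the last
procedure the mass actually received: none, FIT (this cycle's negative
testees), or colonoscopy (post-colonoscopy hiatus/surveillance/wait pools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ComplianceRates,
    ComplicationRates,
    EfficacyAssumptions,
    ModelConfig,
    StrategySchedule,
    TestPerformance,
)

__all__ = [
    "ProcedureCounts",
    "ComplicationCounts",
    "CycleEvents",
    "PathwayParams",
    "FitArmState",
    "DirectArmState",
    "make_screening_state",
    "fit_positivity",
    "effective_incidence_reduction",
    "expected_complications",
    "UNPROTECTED",
    "FIT_PROTECTED",
    "COLO_PROTECTED",
]

UNPROTECTED = "unprotected"
FIT_PROTECTED = "fit"
COLO_PROTECTED = "colonoscopy"


@dataclass
class ProcedureCounts:
    fit: float = 0.0
    colonoscopy_diagnostic: float = 0.0
    colonoscopy_therapeutic: float = 0.0

    @property
    def colonoscopy_total(self) -> float:
        return self.colonoscopy_diagnostic + self.colonoscopy_therapeutic


@dataclass
class ComplicationCounts:
    bleeding: float = 0.0
    perforation: float = 0.0
    perforation_death: float = 0.0


@dataclass
class CycleEvents:
    """Expected event masses produced by one screening cycle."""

    fits: float = 0.0
    colonoscopies: float = 0.0
    therapeutic: float = 0.0
    diagnostic: float = 0.0
    bleeding: float = 0.0
    perforation: float = 0.0
    perforation_death: float = 0.0


def fit_positivity(sens: float, spec: float, prevalence: float) -> float:
    """Probability of a positive FIT: true positives plus false positives."""
    for name, p in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0,1], got {p}")
    return sens * prevalence + (1.0 - spec) * (1.0 - prevalence)


def effective_incidence_reduction(
    strategy: StrategySchedule,
    efficacy: EfficacyAssumptions,
    compliance: ComplianceRates,
) -> float:
    """Headline programme-level incidence reduction for a strategy.

    The modality's efficacy is scaled by the uptake of its primary test:
    FIT compliance for FIT-based arms, primary colonoscopy compliance for
    direct arms.  ``none`` is 0 by contract.
    """
    if strategy.strategy_id == "none":
        return 0.0
    if strategy.uses_fit:
        return efficacy.incidence_reduction_fit * compliance.fit_compliance
    red = (
        efficacy.incidence_reduction_ai_colonoscopy
        if strategy.uses_ai
        else efficacy.incidence_reduction_colonoscopy
    )
    return red * compliance.colonoscopy_primary_compliance


def expected_complications(
    proc: ProcedureCounts,
    rates: ComplicationRates,
    perforation_mortality_basis: str = "per_perforation",
) -> ComplicationCounts:
    """Expected complication counts from colonoscopy volume.

    Bleeding and perforation rates apply per colonoscopy; perforation
    mortality applies per perforation event by default (switchable to a
    per-colonoscopy basis).
    """
    total = proc.colonoscopy_total
    perforation = rates.perforation_rate * total
    if perforation_mortality_basis == "per_perforation":
        deaths = rates.perforation_mortality * perforation
    elif perforation_mortality_basis == "per_colonoscopy":
        deaths = rates.perforation_mortality * total
    else:
        raise ValueError(f"unknown perforation mortality basis {perforation_mortality_basis!r}")
    return ComplicationCounts(
        bleeding=rates.bleeding_rate * total,
        perforation=perforation,
        perforation_death=deaths,
    )


@dataclass(frozen=True)
class PathwayParams:
    """Flattened per-strategy parameters for the state machines."""

    fit_compliance: float
    primary_compliance: float
    followup_compliance: float
    fit_sensitivity: float
    fit_specificity: float
    polypectomy_rate: float
    bleeding_rate: float
    perforation_rate: float
    perforation_mortality: float
    fit_interval: int
    hiatus_years: int
    surveillance_interval: int

    @classmethod
    def from_config(cls, config: ModelConfig, strategy: StrategySchedule) -> "PathwayParams":
        return cls(
            fit_compliance=config.compliance.fit_compliance,
            primary_compliance=config.compliance.colonoscopy_primary_compliance,
            followup_compliance=config.compliance.colonoscopy_after_positive_compliance,
            fit_sensitivity=config.tests.fit_sensitivity,
            fit_specificity=config.tests.fit_specificity,
            polypectomy_rate=config.complications.polypectomy_rate,
            bleeding_rate=config.complications.bleeding_rate,
            perforation_rate=config.complications.perforation_rate,
            perforation_mortality=config.complications.perforation_mortality,
            fit_interval=strategy.fit_interval,
            hiatus_years=strategy.post_normal_colonoscopy_hiatus,
            surveillance_interval=strategy.surveillance_interval,
        )


class _ArmStateBase:
    """Common plumbing: mass scaling, conservation, counter shifting."""

    def _arrays(self) -> list[np.ndarray]:  # pragma: no cover - abstract
        raise NotImplementedError

    def total(self) -> float:
        return float(sum(a.sum() for a in self._arrays()))

    def scale(self, factor: float) -> None:
        """Uniform attrition (e.g. other-cause survival) across sub-states."""
        for a in self._arrays():
            a *= factor

    @staticmethod
    def _shift(a: np.ndarray) -> None:
        # slot k -> slot k-1; mass already due (slot 0) stays due, so no mass
        # is lost on cycles where the event step did not run (e.g. past the
        # screening stop age)
        if len(a) > 1:
            a[0] += a[1]
            a[1:-1] = a[2:]
            a[-1] = 0.0

    def _colonoscopy_round(
        self, mass: float, p: PathwayParams, ev: CycleEvents
    ) -> tuple[float, float]:
        """Run ``mass`` colonoscopies; return (to_surveillance, to_clean).

        Counts procedures and complications; perforation deaths are removed
        from the output masses pro-rata to the polypectomy split.
        """
        if mass <= 0.0:
            return 0.0, 0.0
        ev.colonoscopies += mass
        ther = mass * p.polypectomy_rate
        diag = mass - ther
        ev.therapeutic += ther
        ev.diagnostic += diag
        ev.bleeding += mass * p.bleeding_rate
        perf = mass * p.perforation_rate
        ev.perforation += perf
        dead = perf * p.perforation_mortality
        ev.perforation_death += dead
        return ther - dead * p.polypectomy_rate, diag - dead * (1.0 - p.polypectomy_rate)


@dataclass
class FitArmState(_ArmStateBase):
    """Susceptible-pool state machine for FIT-first strategies."""

    params: PathwayParams
    fit_wait: np.ndarray = field(init=False)
    hiatus: np.ndarray = field(init=False)
    surv: np.ndarray = field(init=False)
    #: portion of fit_wait[1] that took a FIT (negative) this cycle —
    #: FIT-protected at the incidence step, plain pool mass afterwards
    _neg_this_cycle: float = field(init=False, default=0.0)

    def __init__(self, params: PathwayParams, initial_mass: float = 0.0):
        self.params = params
        self.fit_wait = np.zeros(params.fit_interval + 1)
        self.hiatus = np.zeros(params.hiatus_years + 1)
        self.surv = np.zeros(params.surveillance_interval + 1)
        self._neg_this_cycle = 0.0
        self.fit_wait[0] = initial_mass

    def _arrays(self) -> list[np.ndarray]:
        return [self.fit_wait, self.hiatus, self.surv]

    def advance(self, positivity: float) -> CycleEvents:
        p = self.params
        ev = CycleEvents()
        # expired hiatus returns to the annual FIT pool, due immediately
        self.fit_wait[0] += self.hiatus[0]
        self.hiatus[0] = 0.0

        # annual FIT offer
        due = self.fit_wait[0]
        takers = due * p.fit_compliance
        non_takers = due - takers
        ev.fits += takers
        positives = takers * positivity
        negatives = takers - positives
        attend = positives * p.followup_compliance
        skip_colo = positives - attend
        to_surv, to_clean = self._colonoscopy_round(attend, p, ev)

        # surveillance colonoscopy every `surveillance_interval` years until
        # clean; non-attendees drop off the colonoscopy-protected track and
        # are re-engaged through annual FIT (protection is conditional on
        # staying on schedule)
        visits = self.surv[0] * p.followup_compliance
        dropout = self.surv[0] - visits
        self.surv[0] = 0.0
        s_surv, s_clean = self._colonoscopy_round(visits, p, ev)

        self.fit_wait[0] = 0.0
        self.fit_wait[1] += non_takers + skip_colo + dropout
        self.fit_wait[p.fit_interval] += negatives
        self._neg_this_cycle = negatives
        self.surv[p.surveillance_interval] += to_surv + s_surv
        self.hiatus[p.hiatus_years] += to_clean + s_clean
        return ev

    def protection_masses(self) -> dict[str, float]:
        colo = float(self.hiatus.sum() + self.surv.sum())
        fitp = self._neg_this_cycle
        unprot = float(self.fit_wait.sum()) - fitp
        return {UNPROTECTED: unprot, FIT_PROTECTED: fitp, COLO_PROTECTED: colo}

    def remove_incident(self, removals: dict[str, float]) -> None:
        """Subtract incident-case mass pro-rata within each protection class."""
        masses = self.protection_masses()
        r = removals.get(FIT_PROTECTED, 0.0)
        if r > 0.0:
            self.fit_wait[self.params.fit_interval] -= r
            self._neg_this_cycle -= r
        r = removals.get(UNPROTECTED, 0.0)
        if r > 0.0 and masses[UNPROTECTED] > 0.0:
            w = self.fit_wait.copy()
            w[self.params.fit_interval] -= self._neg_this_cycle
            self.fit_wait -= r * w / w.sum()
        r = removals.get(COLO_PROTECTED, 0.0)
        if r > 0.0 and masses[COLO_PROTECTED] > 0.0:
            frac = r / masses[COLO_PROTECTED]
            self.hiatus *= 1.0 - frac
            self.surv *= 1.0 - frac

    def end_cycle(self) -> None:
        self._shift(self.fit_wait)
        self._shift(self.hiatus)
        self._shift(self.surv)
        self._neg_this_cycle = 0.0


@dataclass
class DirectArmState(_ArmStateBase):
    """Susceptible-pool state machine for primary-colonoscopy strategies."""

    params: PathwayParams
    wait: np.ndarray = field(init=False)  # post-colonoscopy, protected
    uwait: np.ndarray = field(init=False)  # declined/never screened, unprotected
    surv: np.ndarray = field(init=False)

    def __init__(self, params: PathwayParams, initial_mass: float = 0.0):
        self.params = params
        self.wait = np.zeros(params.hiatus_years + 1)
        self.uwait = np.zeros(params.hiatus_years + 1)
        self.surv = np.zeros(params.surveillance_interval + 1)
        self.uwait[0] = initial_mass  # never screened, due at first cycle

    def _arrays(self) -> list[np.ndarray]:
        return [self.wait, self.uwait, self.surv]

    def advance(self, positivity: float = 0.0) -> CycleEvents:
        p = self.params
        ev = CycleEvents()
        due = self.wait[0] + self.uwait[0]
        self.wait[0] = 0.0
        self.uwait[0] = 0.0
        compliers = due * p.primary_compliance
        refusers = due - compliers
        to_surv, to_clean = self._colonoscopy_round(compliers, p, ev)

        # surveillance non-attendees drop to the unscreened pool (offered a
        # primary colonoscopy again from the next cycle)
        visits = self.surv[0] * p.followup_compliance
        dropout = self.surv[0] - visits
        self.surv[0] = 0.0
        s_surv, s_clean = self._colonoscopy_round(visits, p, ev)

        self.surv[p.surveillance_interval] += to_surv + s_surv
        self.uwait[1] += dropout
        self.wait[p.hiatus_years] += to_clean + s_clean
        self.uwait[p.hiatus_years] += refusers
        return ev

    def protection_masses(self) -> dict[str, float]:
        return {
            UNPROTECTED: float(self.uwait.sum()),
            FIT_PROTECTED: 0.0,
            COLO_PROTECTED: float(self.wait.sum() + self.surv.sum()),
        }

    def remove_incident(self, removals: dict[str, float]) -> None:
        masses = self.protection_masses()
        r = removals.get(UNPROTECTED, 0.0)
        if r > 0.0 and masses[UNPROTECTED] > 0.0:
            self.uwait *= 1.0 - r / masses[UNPROTECTED]
        r = removals.get(COLO_PROTECTED, 0.0)
        if r > 0.0 and masses[COLO_PROTECTED] > 0.0:
            frac = r / masses[COLO_PROTECTED]
            self.wait *= 1.0 - frac
            self.surv *= 1.0 - frac

    def end_cycle(self) -> None:
        self._shift(self.wait)
        self._shift(self.uwait)
        self._shift(self.surv)


@dataclass
class NoScreeningState(_ArmStateBase):
    """Trivial single-pool state for the no-screening comparator."""

    mass: np.ndarray = field(init=False)

    def __init__(self, initial_mass: float = 0.0):
        self.mass = np.array([float(initial_mass)])

    def _arrays(self) -> list[np.ndarray]:
        return [self.mass]

    def advance(self, positivity: float = 0.0) -> CycleEvents:
        return CycleEvents()

    def protection_masses(self) -> dict[str, float]:
        return {UNPROTECTED: float(self.mass[0]), FIT_PROTECTED: 0.0, COLO_PROTECTED: 0.0}

    def remove_incident(self, removals: dict[str, float]) -> None:
        self.mass[0] -= removals.get(UNPROTECTED, 0.0)

    def end_cycle(self) -> None:
        pass


def make_screening_state(
    config: ModelConfig, strategy: StrategySchedule, initial_mass: float
):
    if strategy.strategy_id == "none":
        return NoScreeningState(initial_mass)
    params = PathwayParams.from_config(config, strategy)
    if strategy.uses_fit:
        return FitArmState(params, initial_mass)
    return DirectArmState(params, initial_mass)
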