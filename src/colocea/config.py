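"""Parameter set for the screening cost-effectiveness model.

Defines the validated parameter bundle (:class:`ModelConfig`) consumed by every
downstream stage: screening-test performance, compliance, colonoscopy
complication rates, programme efficacy (incidence-reduction fractions),
the age-specific CRC incidence schedule, stage distribution and stage-specific
annual mortality, unit costs, and economic settings.  The base case encodes a
Hong Kong average-risk cohort of 100,000 persons screened from age 50 to 75.

Rates are always fractions (0.73, never 73); costs are US dollars.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = [
    "TestPerformance",
    "ComplianceRates",
    "ComplicationRates",
    "EfficacyAssumptions",
    "IncidenceBand",
    "IncidenceSchedule",
    "StageModel",
    "CostTable",
    "EconomicSettings",
    "StrategySchedule",
    "ModelConfig",
    "Violation",
    "ConfigError",
    "basecase",
    "load_config",
    "validate",
    "serialize",
    "STRATEGY_IDS",
    "ALTERNATIVE_SCENARIOS",
]

STRATEGY_IDS = ("none", "fit_colo", "fit_ai", "colo", "ai_colo")


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class TestPerformance(_Frozen):
    """FIT operating characteristics at the 20 µg/g haemoglobin cutoff."""

    fit_sensitivity: float = 0.73
    fit_specificity: float = 0.919


class ComplianceRates(_Frozen):
    """Uptake probabilities per screening offer."""

    fit_compliance: float = 0.60
    colonoscopy_primary_compliance: float = 0.989
    colonoscopy_after_positive_compliance: float = 1.00


class ComplicationRates(_Frozen):
    """Colonoscopy complication probabilities.

    ``polypectomy_rate`` is the probability a screening/surveillance
    colonoscopy is therapeutic (polyps found and removed); bleeding and
    perforation are per-colonoscopy; ``perforation_mortality`` is per
    perforation event.
    """

    polypectomy_rate: float = 0.73
    bleeding_rate: float = 0.0098
    perforation_rate: float = 0.0008
    perforation_mortality: float = 0.000029


class EfficacyAssumptions(_Frozen):
    """Fractional CRC incidence reduction conferred by each modality."""

    incidence_reduction_fit: float = 0.21
    incidence_reduction_colonoscopy: float = 0.442
    incidence_reduction_ai_colonoscopy: float = 0.489


class IncidenceBand(_Frozen):
    age_start: int
    age_end: int  # half-open: [age_start, age_end)
    annual_rate: float  # cases per 100,000 person-years


class IncidenceSchedule(_Frozen):
    """Piecewise-constant age-specific annual CRC incidence."""

    bands: tuple[IncidenceBand, ...]

    def rate_at(self, age: int) -> float:
        """Annual incidence hazard (per person-year) at integer ``age``."""
        for b in self.bands:
            if b.age_start <= age < b.age_end:
                return b.annual_rate / 100_000.0
        raise ValueError(f"age {age} not covered by incidence schedule")


class StageModel(_Frozen):
    """Stage mix at diagnosis and stage-specific annual CRC mortality.

    ``years_to_cure``: prevalent cases surviving this many consecutive years
    post-diagnosis exit to the cured state (no further CRC mortality).
    ``screened_stage_distribution`` is a stage-shift hook for screened arms;
    it ships disabled (``None`` keeps one distribution for all arms).
    """

    stage_distribution: tuple[float, float, float, float]
    annual_stage_mortality: tuple[float, float, float, float]
    years_to_cure: int = 5
    screened_stage_distribution: Optional[tuple[float, float, float, float]] = None


class CostTable(_Frozen):
    """Unit costs in US dollars (AI and conventional colonoscopy share one)."""

    fit_kit: float = 19.0
    colonoscopy: float = 1259.0
    consultation: float = 96.0
    bleeding_episode: float = 3320.0
    histopathology: float = 142.0
    perforation_episode: float = 10790.0
    care_stage1: float = 17071.0
    care_stage2: float = 19755.0
    care_stage3: float = 26883.0
    care_stage4: float = 45115.0

    def care_for_stage(self, stage: int) -> float:
        return (self.care_stage1, self.care_stage2, self.care_stage3, self.care_stage4)[stage - 1]


class EconomicSettings(_Frozen):
    discount_rate: float = 0.03
    cohort_size: float = 100_000
    start_age: int = 50
    screening_stop_age: int = 75
    horizon_age: int = 100
    #: last age (exclusive) at which new CRC cases arise; defaults to the
    #: screening stop age — the convention under which the cohort's case
    #: count matches the follow-up window.  Raise towards horizon_age to
    #: accrue residual-lifetime incidence (the 75+ band).
    incidence_stop_age: Optional[int] = None

    @property
    def effective_incidence_stop_age(self) -> int:
        return self.screening_stop_age if self.incidence_stop_age is None else self.incidence_stop_age


class StrategySchedule(_Frozen):
    """Screening logic selector and interval settings for one strategy arm."""

    strategy_id: Literal["none", "fit_colo", "fit_ai", "colo", "ai_colo"]
    fit_interval: int = 1
    post_normal_colonoscopy_hiatus: int = 10
    surveillance_interval: int = 3

    @property
    def uses_fit(self) -> bool:
        return self.strategy_id in ("fit_colo", "fit_ai")

    @property
    def uses_ai(self) -> bool:
        return self.strategy_id in ("fit_ai", "ai_colo")

    @property
    def is_direct(self) -> bool:
        return self.strategy_id in ("colo", "ai_colo")


class ModelConfig(_Frozen):
    tests: TestPerformance
    compliance: ComplianceRates
    complications: ComplicationRates
    efficacy: EfficacyAssumptions
    incidence: IncidenceSchedule
    stages: StageModel
    costs: CostTable
    economics: EconomicSettings
    life_table_source: str = "synthetic:default"

    def with_overrides(self, **dotted: Any) -> "ModelConfig":
        """Return a copy with dotted-path fields replaced.

        ``cfg.with_overrides(**{"compliance.fit_compliance": 0.3})``
        """
        data = self.model_dump()
        for path, value in dotted.items():
            node = data
            parts = path.split(".")
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config section {p!r} in {path!r}")
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"unknown config field {path!r}")
            node[parts[-1]] = value
        return ModelConfig.model_validate(data)


@dataclass(frozen=True)
class Violation:
    """One validation failure: which field, what was seen, which rule broke."""

    field: str
    observed: Any
    rule: str
    severity: str = "error"  # or "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.field}={self.observed!r}: {self.rule}"


class ConfigError(ValueError):
    """Raised by load_config for files that do not produce a valid config."""


_BASE_STAGE_DIST_PRINTED = (0.113, 0.254, 0.324, 0.310)  # sums to 1.001


def _renormalized_stage_distribution() -> tuple[float, float, float, float]:
    s = sum(_BASE_STAGE_DIST_PRINTED)
    return tuple(x / s for x in _BASE_STAGE_DIST_PRINTED)  # type: ignore[return-value]


def basecase() -> ModelConfig:
    """The base-case parameter set for the Hong Kong screening cohort.

    The stage distribution as published sums to 100.1%; it is renormalized
    here (divided by its sum) to preserve the stage ratios.
    """
    return ModelConfig(
        tests=TestPerformance(),
        compliance=ComplianceRates(),
        complications=ComplicationRates(),
        efficacy=EfficacyAssumptions(),
        incidence=IncidenceSchedule(
            bands=(
                IncidenceBand(age_start=50, age_end=55, annual_rate=55.9),
                IncidenceBand(age_start=55, age_end=60, annual_rate=89.8),
                IncidenceBand(age_start=60, age_end=65, annual_rate=137.0),
                IncidenceBand(age_start=65, age_end=70, annual_rate=200.0),
                IncidenceBand(age_start=70, age_end=75, annual_rate=253.2),
                IncidenceBand(age_start=75, age_end=101, annual_rate=330.5),
            )
        ),
        stages=StageModel(
            stage_distribution=_renormalized_stage_distribution(),
            annual_stage_mortality=(0.01, 0.045, 0.087, 0.43),
        ),
        costs=CostTable(),
        economics=EconomicSettings(),
    )


#: Named alternative parameter scenarios (dotted-path overrides).
ALTERNATIVE_SCENARIOS: dict[str, dict[str, float]] = {
    # territory-wide programme estimate of colonoscopy efficacy quoted in the
    # source narrative; the tabulated 44.2%/48.9% remain the base case
    "colonoscopy_reduction_51.5": {
        "efficacy.incidence_reduction_colonoscopy": 0.515,
        "efficacy.incidence_reduction_ai_colonoscopy": 0.515,
    },
}


def _prob(field: str, value: float, out: list[Violation]) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(field, value, "must lie in [0, 1]"))


def validate(config: ModelConfig) -> list[Violation]:
    """Check every invariant; violations are returned as data, not raised."""
    v: list[Violation] = []
    t = config.tests
    _prob("tests.fit_sensitivity", t.fit_sensitivity, v)
    _prob("tests.fit_specificity", t.fit_specificity, v)
    c = config.compliance
    for name in ("fit_compliance", "colonoscopy_primary_compliance", "colonoscopy_after_positive_compliance"):
        _prob(f"compliance.{name}", getattr(c, name), v)
    k = config.complications
    for name in ("polypectomy_rate", "bleeding_rate", "perforation_rate", "perforation_mortality"):
        _prob(f"complications.{name}", getattr(k, name), v)
    if k.perforation_mortality > k.perforation_rate:
        v.append(
            Violation(
                "complications.perforation_mortality",
                k.perforation_mortality,
                "exceeds perforation_rate (context check)",
                severity="warning",
            )
        )
    e = config.efficacy
    for name in ("incidence_reduction_fit", "incidence_reduction_colonoscopy", "incidence_reduction_ai_colonoscopy"):
        _prob(f"efficacy.{name}", getattr(e, name), v)
    if e.incidence_reduction_ai_colonoscopy < e.incidence_reduction_colonoscopy:
        v.append(
            Violation(
                "efficacy.incidence_reduction_ai_colonoscopy",
                e.incidence_reduction_ai_colonoscopy,
                "below conventional-colonoscopy reduction",
                severity="warning",
            )
        )
    bands = config.incidence.bands
    if not bands:
        v.append(Violation("incidence.bands", (), "must be non-empty"))
    else:
        for i, b in enumerate(bands):
            if b.annual_rate < 0:
                v.append(Violation(f"incidence.bands[{i}].annual_rate", b.annual_rate, "must be >= 0"))
            if b.age_end <= b.age_start:
                v.append(Violation(f"incidence.bands[{i}]", (b.age_start, b.age_end), "empty or inverted band"))
        for i in range(1, len(bands)):
            if bands[i].age_start != bands[i - 1].age_end:
                v.append(
                    Violation(
                        f"incidence.bands[{i}].age_start",
                        bands[i].age_start,
                        f"gap/overlap: previous band ends at {bands[i - 1].age_end}",
                    )
                )
        eco = config.economics
        if bands[0].age_start > eco.start_age or bands[-1].age_end < eco.effective_incidence_stop_age:
            v.append(
                Violation(
                    "incidence.bands",
                    (bands[0].age_start, bands[-1].age_end),
                    f"must cover [{eco.start_age}, {eco.effective_incidence_stop_age})",
                )
            )
    s = config.stages
    total = sum(s.stage_distribution)
    if abs(total - 1.0) > 1e-9:
        v.append(Violation("stages.stage_distribution", s.stage_distribution, f"sums to {total:.6g}, expected 1"))
    for i, p in enumerate(s.stage_distribution):
        _prob(f"stages.stage_distribution[{i}]", p, v)
    for i, m in enumerate(s.annual_stage_mortality):
        _prob(f"stages.annual_stage_mortality[{i}]", m, v)
    if any(b < a for a, b in zip(s.annual_stage_mortality, s.annual_stage_mortality[1:])):
        v.append(
            Violation("stages.annual_stage_mortality", s.annual_stage_mortality, "must be non-decreasing in stage")
        )
    if s.years_to_cure < 1:
        v.append(Violation("stages.years_to_cure", s.years_to_cure, "must be >= 1"))
    costs = config.costs
    for name in (
        "fit_kit", "colonoscopy", "consultation", "bleeding_episode", "histopathology",
        "perforation_episode", "care_stage1", "care_stage2", "care_stage3", "care_stage4",
    ):
        if getattr(costs, name) < 0:
            v.append(Violation(f"costs.{name}", getattr(costs, name), "must be >= 0"))
    cares = [costs.care_stage1, costs.care_stage2, costs.care_stage3, costs.care_stage4]
    if any(b < a for a, b in zip(cares, cares[1:])):
        v.append(Violation("costs.care_stage1..4", tuple(cares), "must be non-decreasing in stage"))
    eco = config.economics
    if eco.discount_rate < 0:
        v.append(Violation("economics.discount_rate", eco.discount_rate, "must be >= 0"))
    if eco.cohort_size <= 0:
        v.append(Violation("economics.cohort_size", eco.cohort_size, "must be > 0"))
    if not (eco.start_age < eco.screening_stop_age <= eco.horizon_age):
        v.append(
            Violation(
                "economics",
                (eco.start_age, eco.screening_stop_age, eco.horizon_age),
                "must satisfy start_age < screening_stop_age <= horizon_age",
            )
        )
    return v


def serialize(config: ModelConfig) -> dict[str, Any]:
    """Plain-dict form suitable for YAML/JSON; round-trips via load."""
    return config.model_dump(mode="json")


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(value, dict) and isinstance(base[key], dict):
            out[key] = _deep_merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML override file on top of the base case.

    The file may specify any subset of fields (nested mapping mirroring the
    ModelConfig schema); unspecified fields keep their base-case values.
    Raises :class:`ConfigError` naming the offending key/field for schema or
    range violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping, got {type(raw).__name__}")
    base = serialize(basecase())
    merged = _deep_merge(base, raw)
    try:
        cfg = ModelConfig.model_validate(merged)
    except Exception as exc:  # pydantic structural error
        raise ConfigError(f"config schema violation in {path}: {exc}") from exc
    errors = [viol for viol in validate(cfg) if viol.severity == "error"]
    if errors:
        raise ConfigError("; ".join(f"{viol.field}={viol.observed!r} {viol.rule}" for viol in errors))
    return cfg


def config_digest(config: ModelConfig) -> str:
    """Stable content hash of a config (key order independent)."""
    import hashlib

    blob = json.dumps(serialize(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def export_manifest(config: ModelConfig) -> "pd.DataFrame":  # noqa: F821
    """Flat manifest of every scalar parameter (field path, value)."""
    import pandas as pd

    rows: list[tuple[str, Any]] = []

    def walk(node: Any, path: str) -> None:
        if isinstance(node, dict):
            for key, value in node.items():
                walk(value, f"{path}.{key}" if path else key)
        elif isinstance(node, (list, tuple)):
            for i, value in enumerate(node):
                walk(value, f"{path}[{i}]")
        else:
            rows.append((path, node))

    walk(serialize(config), "")
    return pd.DataFrame(rows, columns=["field", "value"])
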