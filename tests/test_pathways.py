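import numpy as np
import pytest

from colocea.config import StrategySchedule, basecase
from colocea.pathways import (
    COLO_PROTECTED,
    FIT_PROTECTED,
    UNPROTECTED,
    DirectArmState,
    FitArmState,
    PathwayParams,
    ProcedureCounts,
    effective_incidence_reduction,
    expected_complications,
    fit_positivity,
    make_screening_state,
)


class TestFitPositivity:
    def test_no_disease_limit_is_false_positive_rate(self):
        assert fit_positivity(0.73, 0.919, 0.0) == pytest.approx(1 - 0.919)

    def test_all_disease_limit_is_sensitivity(self):
        assert fit_positivity(0.73, 0.919, 1.0) == pytest.approx(0.73)

    def test_mixture(self):
        # 0.73*0.004 + 0.081*0.996 by hand
        assert fit_positivity(0.73, 0.919, 0.004) == pytest.approx(0.083596, abs=1e-9)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            fit_positivity(1.2, 0.9, 0.0)


class TestEffectiveIncidenceReduction:
    def test_direct_ai_product_rule(self, config):
        s = StrategySchedule(strategy_id="ai_colo")
        assert effective_incidence_reduction(s, config.efficacy, config.compliance) == pytest.approx(
            0.489 * 0.989
        )

    def test_zero_compliance_gives_zero(self, config):
        c = config.with_overrides(**{"compliance.colonoscopy_primary_compliance": 0.0})
        s = StrategySchedule(strategy_id="colo")
        assert effective_incidence_reduction(s, c.efficacy, c.compliance) == 0.0

    def test_fit_arm_full_compliance_is_modality_efficacy(self, config):
        c = config.with_overrides(**{"compliance.fit_compliance": 1.0})
        s = StrategySchedule(strategy_id="fit_colo")
        assert effective_incidence_reduction(s, c.efficacy, c.compliance) == pytest.approx(0.21)

    def test_no_screening_zero_by_contract(self, config):
        s = StrategySchedule(strategy_id="none")
        assert effective_incidence_reduction(s, config.efficacy, config.compliance) == 0.0


class TestExpectedComplications:
    def test_zero_volume(self, config):
        out = expected_complications(ProcedureCounts(), config.complications)
        assert (out.bleeding, out.perforation, out.perforation_death) == (0, 0, 0)

    def test_perforation_volume_arithmetic(self, config):
        proc = ProcedureCounts(colonoscopy_diagnostic=9891, colonoscopy_therapeutic=26744)
        out = expected_complications(proc, config.complications)
        assert out.perforation == pytest.approx(36635 * 0.0008)
        assert round(out.perforation) == 29

    def test_bleeding_scaling(self, config):
        proc = ProcedureCounts(colonoscopy_diagnostic=100)
        out = expected_complications(proc, config.complications)
        assert out.bleeding == pytest.approx(0.98)

    def test_per_colonoscopy_mortality_basis(self, config):
        proc = ProcedureCounts(colonoscopy_diagnostic=1000)
        a = expected_complications(proc, config.complications, "per_perforation")
        b = expected_complications(proc, config.complications, "per_colonoscopy")
        assert b.perforation_death == pytest.approx(a.perforation_death / 0.0008)


def _params(config, strategy_id="fit_colo", **over):
    cfg = config.with_overrides(**over) if over else config
    return PathwayParams.from_config(cfg, StrategySchedule(strategy_id=strategy_id))


class TestStateMachines:
    def test_zero_compliance_no_events(self, config):
        p = _params(
            config,
            **{
                "compliance.fit_compliance": 0.0,
                "compliance.colonoscopy_after_positive_compliance": 0.0,
            },
        )
        st = FitArmState(p, initial_mass=1.0)
        for _ in range(30):
            ev = st.advance(positivity=0.08)
            assert ev.fits == 0.0 and ev.colonoscopies == 0.0
            st.end_cycle()
        assert st.total() == pytest.approx(1.0)

    def test_zero_polypectomy_rate_all_diagnostic(self, config):
        p = _params(config, **{"complications.polypectomy_rate": 0.0})
        st = FitArmState(p, initial_mass=1.0)
        ther = surv_mass = 0.0
        for _ in range(30):
            ev = st.advance(positivity=0.08)
            ther += ev.therapeutic
            surv_mass += st.surv.sum()
            st.end_cycle()
        assert ther == 0.0 and surv_mass == 0.0

    def test_surveillance_visits_geometric_expectation(self, config):
        """Expected surveillance colonoscopies per entrant is 1/(1-p)."""
        p = _params(config)
        st = FitArmState(p, initial_mass=0.0)
        st.surv[0] = 1.0  # a unit mass entering surveillance, visit due now
        total = 0.0
        for _ in range(200):
            ev = st.advance(positivity=0.0)
            total += ev.colonoscopies
            st.end_cycle()
        assert total == pytest.approx(1.0 / (1.0 - 0.73), abs=1e-3)

    @pytest.mark.parametrize("strategy_id", ["fit_colo", "fit_ai", "colo", "ai_colo"])
    def test_mass_conserved_up_to_procedure_deaths(self, config, strategy_id):
        st = make_screening_state(config, StrategySchedule(strategy_id=strategy_id), 1000.0)
        lost = 0.0
        for _ in range(40):
            ev = st.advance(0.0836)
            lost += ev.perforation_death
            st.end_cycle()
        assert st.total() + lost == pytest.approx(1000.0, abs=1e-9)

    @pytest.mark.parametrize("strategy_id", ["fit_colo", "colo"])
    def test_protection_classes_partition_susceptible_mass(self, config, strategy_id):
        st = make_screening_state(config, StrategySchedule(strategy_id=strategy_id), 500.0)
        for _ in range(25):
            st.advance(0.0836)
            parts = st.protection_masses()
            assert sum(parts.values()) == pytest.approx(st.total(), abs=1e-9)
            # incident-case removal keeps classes and total consistent
            st.remove_incident({k: 0.001 * v for k, v in parts.items()})
            st.end_cycle()

    def test_direct_arm_refusers_unprotected(self, config):
        p = _params(config, "colo", **{"compliance.colonoscopy_primary_compliance": 0.0})
        st = DirectArmState(p, initial_mass=1.0)
        st.advance()
        parts = st.protection_masses()
        assert parts[UNPROTECTED] == pytest.approx(1.0)
        assert parts[COLO_PROTECTED] == 0.0

    def test_fit_negatives_fit_protected_this_cycle_only(self, config):
        p = _params(config, **{"compliance.fit_compliance": 1.0})
        st = FitArmState(p, initial_mass=1.0)
        st.advance(positivity=0.0)
        assert st.protection_masses()[FIT_PROTECTED] == pytest.approx(1.0)
        st.end_cycle()
        assert st.protection_masses()[FIT_PROTECTED] == 0.0
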