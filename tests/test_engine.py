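import numpy as np
import pytest

from colocea.config import basecase
from colocea.engine import annual_incidence, life_years_lost_accrual, run_cohort
from colocea.lifetables import LifeTable, residual_life_expectancy


def zero_mortality_table(max_age=100):
    qx = np.zeros(max_age + 1)
    qx[-1] = 1.0
    return LifeTable(start_age=0, qx=qx)


class TestAnnualIncidence:
    @pytest.mark.parametrize(
        "age,rate",
        [(52, 55.9e-5), (55, 89.8e-5), (74, 253.2e-5), (75, 330.5e-5)],
    )
    def test_band_lookup_half_open(self, config, age, rate):
        assert annual_incidence(age, config.incidence) == pytest.approx(rate)

    def test_uncovered_age_rejected(self, config):
        with pytest.raises(ValueError):
            annual_incidence(30, config.incidence)


class TestLifeYearsLostAccrual:
    def test_zero_deaths(self, life_table):
        assert life_years_lost_accrual(0.0, 60, life_table, 0.03) == (0.0, 0.0)

    def test_scales_with_deaths_and_discount_inequality(self, life_table):
        und, disc = life_years_lost_accrual(10.0, 60, life_table, 0.03, 10)
        assert und == pytest.approx(10 * residual_life_expectancy(life_table, 60))
        assert 0 < disc < und

    def test_zero_rate_identity(self, life_table):
        und, disc = life_years_lost_accrual(5.0, 70, life_table, 0.0)
        assert disc == pytest.approx(und)


class TestRunCohort:
    def test_no_disease_limit(self, config, life_table):
        """Zero incidence: no cases, no cancer life years lost, screening only."""
        cfg = config.with_overrides(
            **{"incidence.bands": [
                {"age_start": 50, "age_end": 101, "annual_rate": 0.0}
            ]}
        )
        tr = run_cohort(cfg, "fit_colo", life_table)
        assert tr.total_cases == 0.0
        assert tr.life_years_lost == 0.0
        assert tr.procedures().fit > 0

    def test_geometric_decay_closed_form(self, config):
        """No screening, no background mortality, one band: S(t+1)=S(t)(1-h)."""
        h = 200e-5
        cfg = config.with_overrides(
            **{
                "incidence.bands": [{"age_start": 50, "age_end": 101, "annual_rate": 2000.0 / 10}],
                "economics.incidence_stop_age": 100,
            }
        )
        tr = run_cohort(cfg, "none", zero_mortality_table())
        sus = tr.cycles["susceptible"].to_numpy()
        n0 = cfg.economics.cohort_size
        expected = n0 * (1 - h) ** np.arange(1, len(sus) + 1)
        # final cycle: the life table closes and the survivors die of other causes
        assert sus[:-1] == pytest.approx(expected[:-1], rel=1e-9)

    @pytest.mark.parametrize("strategy_id", ["none", "fit_colo", "fit_ai", "colo", "ai_colo"])
    def test_mass_conservation(self, config, life_table, strategy_id):
        tr = run_cohort(config, strategy_id, life_table)
        assert tr.mass_balance_error() < 1e-6

    def test_zero_uptake_equals_no_screening(self, config, life_table):
        """Screening nobody attends is the no-screening model on all disease outcomes."""
        cfg = config.with_overrides(
            **{
                "compliance.fit_compliance": 0.0,
                "compliance.colonoscopy_after_positive_compliance": 0.0,
            }
        )
        a = run_cohort(cfg, "fit_colo", life_table)
        b = run_cohort(cfg, "none", life_table)
        assert a.total_cases == pytest.approx(b.total_cases, rel=1e-12)
        assert a.life_years_lost_discounted == pytest.approx(
            b.life_years_lost_discounted, rel=1e-12
        )
        assert a.total_crc_deaths == pytest.approx(b.total_crc_deaths, rel=1e-12)

    def test_cases_monotone_in_efficacy(self, config, life_table):
        lo = run_cohort(config, "ai_colo", life_table).total_cases
        weaker = config.with_overrides(**{"efficacy.incidence_reduction_ai_colonoscopy": 0.2})
        hi = run_cohort(weaker, "ai_colo", life_table).total_cases
        assert lo < hi

    def test_short_life_table_rejected(self, config):
        short = LifeTable(start_age=0, qx=np.append(np.zeros(80), 1.0))
        with pytest.raises(ValueError, match="horizon"):
            run_cohort(config, "none", short)

    def test_diagnosed_exit_to_cure_after_five_years(self, config):
        """With zero stage mortality every diagnosed person reaches cure."""
        cfg = config.with_overrides(
            **{"stages.annual_stage_mortality": (0.0, 0.0, 0.0, 0.0)}
        )
        tr = run_cohort(cfg, "none", zero_mortality_table())
        assert tr.total_crc_deaths == 0.0
        final_cured = tr.cycles["cured"].iloc[-2]  # before the closing cycle
        prevalent = tr.cycles[[f"prevalent_stage{s}" for s in (1, 2, 3, 4)]].iloc[-2].sum()
        # everyone diagnosed at least 5 years ago has exited to cure
        recent = tr.cycles[[f"new_dx_stage{s}" for s in (1, 2, 3, 4)]].iloc[-6:-1].to_numpy().sum()
        assert prevalent == pytest.approx(recent, rel=1e-9)
        assert final_cured > 0

    def test_trace_tidy_export(self, config, life_table):
        tr = run_cohort(config, "fit_ai", life_table)
        tidy = tr.to_tidy()
        assert set(["t", "age", "measure", "value"]) == set(tidy.columns)
        assert (tidy["measure"] == "fit").sum() == len(tr.cycles)
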