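import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocea.lifetables import (
    DEFAULT_MAKEHAM,
    LifeTable,
    MakehamSpec,
    default_life_table,
    discounted_residual_life_years,
    read_life_table,
    residual_life_expectancy,
    synthesize_life_table,
    write_life_table,
)


def brute_force_expectancy(table: LifeTable, age: int, r: float = 0.0) -> float:
    """Independent cumulative-product oracle (plain Python loop)."""
    total, surv = 0.0, 1.0
    for t, a in enumerate(range(age, table.max_age + 1), start=1):
        surv *= 1.0 - table.q_at(a)
        total += surv / (1.0 + r) ** t
    return total


def constant_q_table(q: float, n: int = 120, start: int = 0) -> LifeTable:
    qx = np.full(n, q)
    qx[-1] = 1.0
    return LifeTable(start_age=start, qx=qx)


class TestSynthesize:
    def test_zero_hazard_gives_zero_qx(self):
        t = synthesize_life_table(MakehamSpec(a=0.0, b=0.5, c=0.0, max_age=80))
        assert np.all(t.qx[:-1] == 0.0) and t.qx[-1] == 1.0

    def test_constant_hazard_ln2_gives_half(self):
        t = synthesize_life_table(MakehamSpec(a=0.0, b=0.0, c=math.log(2), max_age=60))
        assert t.qx[:-1] == pytest.approx(0.5)

    def test_default_spec_high_longevity(self):
        t = default_life_table()
        e50 = residual_life_expectancy(t, 50)
        assert 30.0 <= e50 <= 37.0

    def test_reproducible(self):
        a = synthesize_life_table(DEFAULT_MAKEHAM)
        b = synthesize_life_table(DEFAULT_MAKEHAM)
        assert a == b

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            MakehamSpec(a=-1e-5)


class TestResidualLifeExpectancy:
    def test_certain_death_gives_zero(self):
        t = constant_q_table(1.0, n=30)
        assert residual_life_expectancy(t, 0) == 0.0

    def test_constant_hazard_geometric_closed_form(self):
        # ex = (1-q)/q for constant q; at q=0.5 the truncation error is 2^-119
        t = constant_q_table(0.5)
        assert residual_life_expectancy(t, 0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        t = default_life_table()
        assert residual_life_expectancy(t, 50) == pytest.approx(
            brute_force_expectancy(t, 50), abs=1e-9
        )

    def test_strictly_decreasing_in_age_for_increasing_hazard(self):
        t = default_life_table()
        ex = [residual_life_expectancy(t, a) for a in range(30, 100)]
        assert all(b < a for a, b in zip(ex, ex[1:]))

    def test_age_outside_table_rejected(self):
        t = constant_q_table(0.5, n=10, start=50)
        with pytest.raises(ValueError):
            residual_life_expectancy(t, 30)


class TestDiscountedResidualLifeYears:
    def test_reduces_to_undiscounted_at_zero_rate(self):
        t = default_life_table()
        assert discounted_residual_life_years(t, 50, 0.0) == pytest.approx(
            residual_life_expectancy(t, 50)
        )

    def test_certain_death_zero_for_any_rate(self):
        t = constant_q_table(1.0, n=30)
        assert discounted_residual_life_years(t, 0, 0.07) == 0.0

    def test_constant_hazard_discounted_geometric(self):
        # sum (0.5/1.03)^t = (0.5/1.03)/(1 - 0.5/1.03) ~ 0.943396
        t = constant_q_table(0.5)
        x = 0.5 / 1.03
        assert discounted_residual_life_years(t, 0, 0.03) == pytest.approx(
            x / (1 - x), abs=1e-12
        )

    def test_offset_anchors_discounting_at_model_start(self):
        t = default_life_table()
        base = discounted_residual_life_years(t, 60, 0.03, years_from_model_start=0)
        shifted = discounted_residual_life_years(t, 60, 0.03, years_from_model_start=10)
        assert shifted == pytest.approx(base * 1.03**-10)

    @settings(derandomize=True, max_examples=30)
    @given(age=st.integers(min_value=0, max_value=99), r=st.floats(0.0, 0.2))
    def test_discounting_never_increases_life_years(self, age, r):
        t = default_life_table()
        disc = discounted_residual_life_years(t, age, r)
        undisc = residual_life_expectancy(t, age)
        assert disc <= undisc + 1e-12
        if r == 0.0:
            assert disc == pytest.approx(undisc)


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path):
        t = default_life_table()
        p = tmp_path / "lt.csv"
        write_life_table(t, p)
        assert read_life_table(p) == t

    def test_out_of_range_qx_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("age,qx\n0,0.1\n1,1.5\n2,1.0\n")
        with pytest.raises(ValueError, match="qx"):
            read_life_table(p)

    def test_missing_age_rejected(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("age,qx\n62,0.1\n64,1.0\n")
        with pytest.raises(ValueError, match="contiguous"):
            read_life_table(p)

    def test_closure_required(self):
        with pytest.raises(ValueError, match="close"):
            LifeTable(start_age=0, qx=np.array([0.1, 0.2]))
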