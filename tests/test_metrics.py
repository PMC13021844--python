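import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pharmits as ph
from pharmits import studycalendar as cal
from pharmits.errors import (
    InsufficientHistoryError,
    MissingDataError,
    UndefinedMetricError,
)
from pharmits.metrics import derive_incident_counts


def _series(ddd, pop=100_000, counts=None):
    days = np.array([cal.days_in_month(i) for i in range(1, 61)])
    return ph.MonthlySeries.from_arrays(
        "t", "all", "all", np.asarray(ddd, float), np.full(60, pop), days, counts
    )


class TestDddTid:
    def test_hand_computed_single_month(self):
        # March 2018 has 31 days: 93000 / (31 * 100000) * 1000 = 30
        ddd = np.zeros(60)
        ddd[2] = 93_000.0
        v = ph.compute_dddtid(_series(ddd), 3)
        assert v.v == pytest.approx(30.0, abs=1e-12)
        assert v.person_days == 31 * 100_000

    def test_zero_numerator(self):
        assert ph.compute_dddtid(_series(np.zeros(60)), (2020, 2)).v == 0.0

    @given(scale=st.integers(min_value=1, max_value=50))
    def test_scale_invariance(self, scale):
        """v is invariant under joint scaling of DDD and population."""
        ddd = np.linspace(10_000, 90_000, 60)
        base = ph.compute_dddtid(_series(ddd), (2021, 3)).v
        scaled = _series(ddd * scale, pop=100_000 * scale)
        assert ph.compute_dddtid(scaled, (2021, 3)).v == pytest.approx(base, rel=1e-9)

    def test_quarter_additivity(self):
        """A quarter's v combines its months' numerators and person-days."""
        rng = np.random.default_rng(1)
        ddd = rng.uniform(10_000, 90_000, 60)
        s = _series(ddd)
        q = ph.compute_dddtid(s, (2019, 3))
        months = cal.months_of_quarter(2019, 3)
        num = sum(ph.compute_dddtid(s, m).numerator_ddd for m in months)
        pdays = sum(ph.compute_dddtid(s, m).person_days for m in months)
        assert q.v == pytest.approx(num / pdays * 1000.0, rel=1e-12)

    def test_monthly_vector_matches_per_month_calls(self):
        ddd = np.linspace(10_000, 90_000, 60)
        s = _series(ddd)
        vec = ph.monthly_dddtid(s)
        assert vec.loc[7] == pytest.approx(ph.compute_dddtid(s, 7).v)


class TestIncidence:
    def test_definitional_single_month(self):
        counts = np.zeros(60)
        counts[0] = 50
        s = _series(np.zeros(60), counts=counts)
        assert ph.compute_incidence(s, 1).incidence == pytest.approx(50.0)

    def test_zero_counts(self):
        s = _series(np.zeros(60), counts=np.zeros(60))
        assert ph.compute_incidence(s, (2019, 1)).incidence == 0.0

    def test_quarter_pools_counts_over_population(self):
        # (10+20+30) / (3*50000) * 1e5 = 40
        counts = np.zeros(60)
        counts[[0, 1, 2]] = [10, 20, 30]
        s = _series(np.zeros(60), pop=50_000, counts=counts)
        assert ph.compute_incidence(s, (2018, 1)).incidence == pytest.approx(40.0)

    def test_absent_counts_raise(self):
        with pytest.raises(MissingDataError, match="absent"):
            ph.compute_incidence(_series(np.zeros(60)), 1)


class TestRelativeChange:
    BASE = {(y, q): 100.0 * (1.0 + 0.1 * (y - 2019)) for y in range(2018, 2023) for q in range(1, 5)}

    def test_2019_is_zero_for_every_quarter(self):
        for q in range(1, 5):
            assert ph.relative_change(self.BASE, q, 2019).delta_pct == 0.0

    @pytest.mark.parametrize("factor,expected", [(1.5, 50.0), (0.61, -39.0), (1.0, 0.0)])
    def test_ratio_arithmetic(self, factor, expected):
        table = {(2019, 2): 80.0, (2020, 2): 80.0 * factor}
        assert ph.relative_change(table, 2, 2020).delta_pct == pytest.approx(expected)

    def test_zero_base_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ph.relative_change({(2019, 1): 0.0, (2020, 1): 5.0}, 1, 2020)


def _events(rows):
    return pd.DataFrame(rows, columns=["person_id", "dispensing_date", "atc_code"])


class TestWashout:
    def test_dispensing_13_months_earlier_is_incident(self):
        ev = _events(
            [(1, "2018-01-10", "N06AB06"), (1, "2019-02-05", "N06AB06")]
        )
        counts = derive_incident_counts(ev, months=[14], history_start=(2018, 1))
        assert counts.incident_count.sum() == 1

    def test_dispensing_previous_month_is_not_incident(self):
        ev = _events(
            [(1, "2019-01-10", "N06AB06"), (1, "2019-02-05", "N06AB06")]
        )
        counts = derive_incident_counts(ev, months=[14], history_start=(2018, 1))
        assert counts.incident_count.sum() == 0

    def test_multiple_dispensings_in_incident_month_count_once(self):
        ev = _events(
            [(1, "2019-02-05", "N06AB06"), (1, "2019-02-20", "N06AX16")]
        )
        counts = derive_incident_counts(ev, months=[14], history_start=(2018, 1))
        assert counts.incident_count.sum() == 1

    def test_non_n06a_codes_ignored(self):
        ev = _events([(1, "2019-02-05", "C07AB02")])
        counts = derive_incident_counts(ev, months=[14], history_start=(2018, 1))
        assert counts.incident_count.sum() == 0

    def test_insufficient_lookback_raises(self):
        ev = _events([(1, "2018-06-10", "N06AB06")])
        with pytest.raises(InsufficientHistoryError):
            derive_incident_counts(ev, months=[6], history_start=(2018, 1))

    def test_matches_brute_force_on_random_tables(self):
        """Vectorized washout equals an explicit per-person, per-month scan."""
        rng = np.random.default_rng(2024)
        base = 2018 * 12 + 1
        for _ in range(20):
            rows = []
            for pid in range(20):
                months = rng.choice(
                    np.arange(2017 * 12 + 1, 2017 * 12 + 31),
                    size=rng.integers(1, 6),
                    replace=False,
                )
                for am in months:
                    y, m = (am - 1) // 12, am - ((am - 1) // 12) * 12
                    rows.append((pid, f"{y}-{m:02d}-10", "N06AB06"))
            ev = _events(rows)
            requested = list(range(1, 7))
            got = derive_incident_counts(ev, months=requested, history_start=(2017, 1))
            got = dict(zip(got.month_index, got.incident_count))
            ev["_am"] = pd.to_datetime(ev.dispensing_date).dt.year * 12 + pd.to_datetime(
                ev.dispensing_date
            ).dt.month
            for m in requested:
                am = base + m - 1
                expected = 0
                for pid, grp in ev.groupby("person_id"):
                    months_set = set(grp["_am"])
                    if am in months_set and not any(
                        a in months_set for a in range(am - 12, am)
                    ):
                        expected += 1
                assert got[m] == expected
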