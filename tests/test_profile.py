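"""Concentration-table aggregations: MDL, group sums, RC, majors, consistency."""

import numpy as np
import pandas as pd
import pytest

from aromaquant.profile import (apply_mdl, consistency_counts, group_sums,
                                relative_composition, select_major,
                                validate_concentration_table)


def make_table(rows):
    return pd.DataFrame(rows, columns=["compound", "group", "day",
                                       "conc_ppb", "conc_ugm3", "bdl"])


@pytest.fixture
def small_table():
    return make_table([
        ("a", "ester", 0, 10.0, 36.0, False),
        ("a", "ester", 1, 0.02, 0.07, True),
        ("b", "ester", 0, 5.0, 22.0, False),
        ("b", "ester", 1, 4.0, 17.0, False),
        ("c", "alcohol", 0, 0.01, 0.03, True),
        ("c", "alcohol", 1, 8.0, 24.0, False),
    ])


class TestApplyMdl:
    def test_sub_mdl_entries_carry_the_mdl(self):
        t = make_table([("x", "ester", 0, 0.0, 0.0, False)])
        out = apply_mdl(t, {"x": 0.02}, mw={"x": 98.0})
        assert bool(out.loc[0, "bdl"])
        assert out.loc[0, "conc_ppb"] == pytest.approx(0.02)
        assert out.loc[0, "conc_ugm3"] == pytest.approx(0.02 * 98.0 / 24.5)

    def test_detected_entries_untouched(self):
        t = make_table([("x", "ester", 0, 5.0, 20.0, False)])
        out = apply_mdl(t, {"x": 0.02})
        assert not bool(out.loc[0, "bdl"])
        assert out.loc[0, "conc_ppb"] == 5.0

    def test_missing_mdl_is_an_error(self):
        t = make_table([("x", "ester", 0, 5.0, 20.0, False)])
        with pytest.raises(ValueError, match="no MDL"):
            apply_mdl(t, {})


class TestGroupSums:
    def test_detection_counts_exclude_bdl(self, small_table):
        out = group_sums(small_table).set_index(["group", "day"])
        assert out.loc[("ester", 0), "n_detected"] == 2
        assert out.loc[("ester", 1), "n_detected"] == 1
        assert out.loc[("alcohol", 0), "n_detected"] == 0

    def test_bdl_placeholders_excluded_by_default(self, small_table):
        out = group_sums(small_table).set_index(["group", "day"])
        assert out.loc[("ester", 1), "sum_ugm3"] == pytest.approx(17.0)
        withbdl = group_sums(small_table, include_bdl=True).set_index(["group", "day"])
        assert withbdl.loc[("ester", 1), "sum_ugm3"] == pytest.approx(17.07)

    def test_group_sums_conserve_total(self, strawberry_conc):
        out = group_sums(strawberry_conc)
        det = strawberry_conc[~strawberry_conc["bdl"]]
        for day, total in det.groupby("day")["conc_ugm3"].sum().items():
            assert out.loc[out["day"] == day, "sum_ugm3"].sum() == pytest.approx(total)


class TestRelativeComposition:
    def test_single_compound_is_its_own_total(self):
        t = make_table([("x", "ester", 0, 5.0, 20.0, False)])
        rc = relative_composition(t, {0: 20.0})
        assert rc.loc[0, "rc_percent"] == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        t = make_table([("x", "ester", 0, 5.0, 20.0, False)])
        with pytest.raises(ValueError):
            relative_composition(t, {0: 0.0})

    def test_rc_sums_below_100_for_partial_tables(self, strawberry_conc, daily_totals):
        rc = relative_composition(strawberry_conc, daily_totals)
        per_day = rc.groupby("day")["rc_percent"].sum()
        assert (per_day <= 100.0 + 1e-9).all()
        assert (per_day > 99.0).all()  # the majors carry ~all the mass


class TestSelectMajor:
    def test_cutoff_boundary(self):
        rc = pd.DataFrame(dict(compound=["lo", "hi"], group=["etc"] * 2,
                               day=[0, 0], conc_ugm3=[1, 1],
                               rc_percent=[0.04, 0.06]))
        out = select_major(rc, cutoff=0.05)
        assert out["compound"].tolist() == ["hi"]

    def test_single_qualifying_day_suffices(self):
        rc = pd.DataFrame(dict(compound=["x"] * 3, group=["etc"] * 3,
                               day=[0, 1, 3], conc_ugm3=[1] * 3,
                               rc_percent=[0.01, 0.06, 0.01]))
        out = select_major(rc)
        assert out.loc[0, "qualifying_days"] == (1,)

    def test_constructed_147_compound_profile_yields_53(self):
        """A profile built so exactly 53 of 147 compounds pass the filter."""
        rows = []
        for i in range(147):
            rc_val = 0.06 if i < 53 else 0.04
            rows.append(dict(compound=f"c{i}", group="etc", day=0,
                             conc_ugm3=1.0, rc_percent=rc_val))
        assert len(select_major(pd.DataFrame(rows))) == 53

    def test_monotone_in_cutoff(self, strawberry_conc, daily_totals):
        rc = relative_composition(strawberry_conc, daily_totals)
        sizes = [len(select_major(rc, cutoff=c)) for c in (0.01, 0.05, 0.5, 5.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestConsistencyCounts:
    def test_identical_sets_fully_consistent(self):
        t = make_table([("a", "ester", d, 1.0, 4.0, False) for d in (0, 1)]
                       + [("b", "ester", d, 1.0, 4.0, False) for d in (0, 1)])
        out = consistency_counts(t).set_index(["group", "day"])
        assert out.loc[("ester", 1), "n_consistent"] == 2

    def test_disjoint_sets_give_zero(self):
        t = make_table([("a", "ester", 0, 1.0, 4.0, False),
                        ("a", "ester", 1, 0.01, 0.04, True),
                        ("b", "ester", 0, 0.01, 0.04, True),
                        ("b", "ester", 1, 1.0, 4.0, False)])
        out = consistency_counts(t).set_index(["group", "day"])
        assert out.loc[("ester", 1), "n_consistent"] == 0

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(5)
        days = [0, 1, 3, 6, 9]
        names = [f"c{i}" for i in range(40)]
        rows = []
        detected = {}
        for d in days:
            det = set(rng.choice(names, size=rng.integers(5, 30), replace=False))
            detected[d] = det
            for n in names:
                rows.append((n, "ester", d, 1.0, 4.0, n not in det))
        out = consistency_counts(make_table(rows)).set_index(["group", "day"])
        for prev, day in zip(days, days[1:]):
            expect = len(detected[day] & detected[prev])
            assert out.loc[("ester", day), "n_consistent"] == expect


def test_duplicate_compound_day_rejected():
    t = make_table([("a", "ester", 0, 1.0, 4.0, False)] * 2)
    with pytest.raises(ValueError, match="duplicate"):
        validate_concentration_table(t)
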