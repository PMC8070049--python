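"""Tests for cohort reading and the exclusion cascade."""

import numpy as np
import pandas as pd
import pytest

import cogspan as cs
from cogspan.cohort import CohortSchemaError


def _tiny_frame(n=3):
    df = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "age": np.linspace(20, 40, n),
        "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
    })
    for c in cs.TEST_COLUMNS:
        df[c] = np.linspace(-1, 1, n)
    df["sleep_hours"] = 7.0
    df["caffeine_units"] = 2.0
    df["anxiety"] = 1
    df["education"] = 2
    df["exercise"] = 1
    df["tech_savvy"] = "yes"
    return df


class TestReadCohort:
    def test_roundtrip_well_formed_file(self, tmp_path):
        df = _tiny_frame()
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        table = cs.read_cohort(path)
        assert table.n == 3
        assert list(table.data.participant_id) == ["P0", "P1", "P2"]

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "c.tsv"
        _tiny_frame().to_csv(path, sep="\t", index=False)
        assert cs.read_cohort(path).n == 3

    def test_missing_sex_column_is_schema_error(self, tmp_path):
        df = _tiny_frame().drop(columns=["sex"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="sex"):
            cs.read_cohort(path)

    def test_third_sex_level_rejected(self, tmp_path):
        df = _tiny_frame()
        df.loc[0, "sex"] = "other"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="sex"):
            cs.read_cohort(path)

    def test_unparseable_score_reports_line_number(self, tmp_path):
        df = _tiny_frame()
        df["digit_span"] = df["digit_span"].astype(object)
        df.loc[1, "digit_span"] = "oops"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="line 3"):
            cs.read_cohort(path)

    def test_duplicate_id_rejected(self, tmp_path):
        df = _tiny_frame()
        df.loc[2, "participant_id"] = "P0"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="duplicate"):
            cs.read_cohort(path)


class TestFilterComplete:
    def test_identity_when_no_missing(self, small_cohort):
        out, rep = cs.filter_complete(small_cohort)
        assert rep.n_removed == 0 and out.n == small_cohort.n

    def test_forced_count(self):
        df = _tiny_frame(10)
        df["participant_id"] = [f"Q{i}" for i in range(10)]
        df.loc[2, "digit_span"] = np.nan
        df["anxiety"] = df["anxiety"].astype(float)
        df.loc[7, "anxiety"] = np.nan
        t = cs.CohortTable(df)
        out, rep = cs.filter_complete(t)
        assert (rep.n_before, rep.n_removed, rep.n_after) == (10, 2, 8)
        assert rep.details["missing_per_column"] == {
            "digit_span": 1, "anxiety": 1}


class TestTwoPassOutlierFilter:
    def test_masking_example_52_to_50(self):
        """One 100 hides a 12 behind an inflated SD; the second pass
        catches it after recalculation."""
        values = [0.0] * 50 + [100.0, 12.0]
        df = _tiny_frame(52)
        df["participant_id"] = [f"R{i}" for i in range(52)]
        df["sex"] = ["female", "male"] * 26
        for c in cs.TEST_COLUMNS:
            df[c] = 0.0
        df["monkey_ladder"] = values
        t = cs.CohortTable(df)
        with pytest.warns(UserWarning, match="zero variance"):
            out, rep = cs.filter_outliers_two_pass(t)
        assert rep.details["pass1"]["n_removed"] == 1
        assert rep.details["pass2"]["n_removed"] == 1
        assert out.n == 50
        assert not out.data.monkey_ladder.gt(0).any()

    def test_all_equal_scores_no_removals(self):
        df = _tiny_frame(6)
        df["participant_id"] = [f"S{i}" for i in range(6)]
        for c in cs.TEST_COLUMNS:
            df[c] = 1.5
        with pytest.warns(UserWarning, match="zero variance"):
            out, rep = cs.filter_outliers_two_pass(cs.CohortTable(df))
        assert rep.n_removed == 0 and out.n == 6

    def test_gaussian_tail_removal_fractions(self):
        rng = np.random.default_rng(12345)
        n = 100_000
        df = _tiny_frame(2)
        df = pd.DataFrame({c: [0.0] * n for c in df.columns})
        df["participant_id"] = [f"G{i}" for i in range(n)]
        df["sex"] = ["female", "male"] * (n // 2)
        df["age"] = 30.0
        df["tech_savvy"] = "yes"
        df["monkey_ladder"] = rng.normal(0, 1, n)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            _, rep = cs.filter_outliers_two_pass(cs.CohortTable(df))
        assert rep.details["pass1"]["n_removed"] <= n * 1e-4
        # ~2*Phi(-4)*n = 6.3 expected removals in pass 2
        assert 1 <= rep.details["pass2"]["n_removed"] <= 18

    def test_rerun_after_removals_can_remove_more(self):
        """The screen is not idempotent when masking is present."""
        values = [0.0] * 50 + [100.0, 12.0]
        df = _tiny_frame(52)
        df["participant_id"] = [f"T{i}" for i in range(52)]
        for c in cs.TEST_COLUMNS:
            df[c] = np.linspace(-1, 1, 52)
        df["monkey_ladder"] = values
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            once, rep1 = cs.filter_outliers_two_pass(cs.CohortTable(df))
            twice, rep2 = cs.filter_outliers_two_pass(once)
        assert rep1.n_removed >= 1
        assert rep2.n_removed >= 0  # masking permits further removals

    def test_threshold_ordering_enforced(self, small_cohort):
        with pytest.raises(ValueError, match="k1 > k2"):
            cs.filter_outliers_two_pass(small_cohort, k1=4, k2=6)


class TestFilterAge:
    def test_closed_interval_boundaries(self):
        df = _tiny_frame(4)
        df["participant_id"] = list("abcd")
        df["age"] = [11, 12, 69, 70]
        out, rep = cs.filter_age(cs.CohortTable(df))
        assert sorted(out.data.age) == [12, 69]
        assert rep.n_removed == 2

    def test_identity_inside_window(self, small_cohort):
        out, rep = cs.filter_age(small_cohort)
        assert rep.n_removed == 0

    def test_empty_result_allowed(self):
        df = _tiny_frame(3)
        df["age"] = [5, 6, 7]
        out, rep = cs.filter_age(cs.CohortTable(df))
        assert out.n == 0 and rep.n_after == 0


def test_cascade_report_counts_chain(small_cohort):
    t1, r1 = cs.filter_complete(small_cohort)
    t2, r2 = cs.filter_outliers_two_pass(t1)
    t3, r3 = cs.filter_age(t2)
    assert r1.n_after == r2.n_before
    assert r2.n_after == r3.n_before
    assert r3.n_after == t3.n
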