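"""Container invariants and lossless delimited-text round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tickrate import (
    BetaMatrix, ClockModel, ClockScores, CpGSet, SampleTable,
    align_samples, read_beta_matrix, read_clock_model, read_cpg_set,
    write_beta_matrix, write_clock_model, write_cpg_set,
    read_sample_table, write_sample_table,
)
from tickrate.datamodel import check_aligned


class TestBetaMatrix:
    def test_basic_parse_shape(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("cpg_id\tA\tB\ncg1\t0.1\t0.2\ncg2\t0.5\t0.9\ncg3\t0.3\t0.4\n")
        bm = read_beta_matrix(p)
        assert bm.shape == (3, 2)
        assert bm.cpg_ids == ["cg1", "cg2", "cg3"]

    def test_out_of_range_value_rejected_with_coordinates(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("cpg_id\tA\ncg1\t0.5\ncg2\t1.2\n")
        with pytest.raises(ValueError, match="cg2.*A|A.*cg2"):
            read_beta_matrix(p)

    def test_duplicate_ids_rejected_by_name(self):
        with pytest.raises(ValueError, match="cg1"):
            BetaMatrix(["cg1", "cg1"], ["A"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="sample ids"):
            BetaMatrix(["cg1", "cg2"], ["A", "A"], np.zeros((2, 2)))

    def test_missing_distinguished_from_zero(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("cpg_id\tA\tB\ncg1\tNA\t0.0\n")
        bm = read_beta_matrix(p)
        assert np.isnan(bm.values[0, 0]) and bm.values[0, 1] == 0.0

    @pytest.mark.parametrize("dialect,ext", [("tsv", "tsv"), ("csv", "csv")])
    def test_roundtrip_bitwise(self, tmp_path, dialect, ext):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 1, (50, 10))
        values[rng.random((50, 10)) < 0.05] = np.nan
        bm = BetaMatrix([f"cg{i}" for i in range(50)],
                        [f"S{j}" for j in range(10)], values)
        p = tmp_path / f"b.{ext}"
        write_beta_matrix(bm, p, dialect)
        back = read_beta_matrix(p, dialect)
        assert back.cpg_ids == bm.cpg_ids and back.sample_ids == bm.sample_ids
        assert np.array_equal(back.values, bm.values, equal_nan=True)


class TestSampleTable:
    def _frame(self, **overrides):
        base = dict(sample_id=["a", "b"], age=[30.0, 40.0], ec=[0.5, 0.6],
                    fib=[0.1, 0.05], ic=[0.4, 0.35], group=["control", "case"])
        base.update(overrides)
        return pd.DataFrame(base)

    def test_valid_table(self, tmp_path):
        t = SampleTable(self._frame())
        p = tmp_path / "s.tsv"
        write_sample_table(t, p)
        back = read_sample_table(p)
        assert back.sample_ids == t.sample_ids
        assert np.array_equal(back.age, t.age)

    def test_fraction_sum_rejected(self):
        with pytest.raises(ValueError, match="ec \\+ fib \\+ ic"):
            SampleTable(self._frame(ec=[0.8, 0.6]))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            SampleTable(self._frame(age=[-1.0, 40.0]))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SampleTable(self._frame(group=["control", "treated"]))


class TestAlignment:
    def test_align_reorders_by_id(self, tiny_beta, tiny_samples):
        shuffled = tiny_beta.select_samples(["S3", "S1", "S0", "S4", "S2"])
        aligned, _ = align_samples(shuffled, tiny_samples)
        assert aligned.sample_ids == tiny_samples.sample_ids
        assert np.array_equal(aligned.values, tiny_beta.values)

    def test_mismatched_order_rejected(self, tiny_beta, tiny_samples):
        shuffled = tiny_beta.select_samples(["S3", "S1", "S0", "S4", "S2"])
        with pytest.raises(ValueError, match="align_samples"):
            check_aligned(shuffled, tiny_samples)

    def test_disjoint_sample_sets_rejected(self, tiny_beta, tiny_samples):
        renamed = BetaMatrix(tiny_beta.cpg_ids, [f"X{j}" for j in range(5)],
                             tiny_beta.values)
        with pytest.raises(ValueError, match="sample sets differ"):
            align_samples(renamed, tiny_samples)


class TestClockModelIO:
    def test_general_roundtrip_exact(self, tmp_path):
        m = ClockModel("general", ["cg1", "cg2"], [10.0, -5.0], [], 30.0,
                       meta={"penalty": "lasso"})
        p = tmp_path / "clock.tsv"
        write_clock_model(m, p)
        back = read_clock_model(p)
        assert back.kind == "general" and back.cpgs == m.cpgs
        assert np.array_equal(back.w, m.w) and back.intercept == m.intercept
        assert back.meta == m.meta

    def test_interaction_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        m = ClockModel("epithelial", [f"cg{i}" for i in range(7)],
                       rng.normal(size=7), rng.normal(size=7), rng.normal())
        p = tmp_path / "clock.tsv"
        write_clock_model(m, p)
        back = read_clock_model(p)
        assert np.array_equal(back.w, m.w)
        assert np.array_equal(back.w_ic, m.w_ic)
        assert back.intercept == m.intercept

    def test_missing_intercept_errors(self, tmp_path):
        p = tmp_path / "clock.tsv"
        p.write_text("#kind=general\ncpg\tweight\ncg1\t1.0\n")
        with pytest.raises(ValueError, match="intercept"):
            read_clock_model(p)

    def test_interaction_column_invalid_for_general(self, tmp_path):
        p = tmp_path / "clock.tsv"
        p.write_text("#kind=general\n#intercept=3\n"
                     "cpg\tweight\tinteraction_weight\ncg1\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="interaction"):
            read_clock_model(p)

    def test_general_model_refuses_interaction_weights(self):
        with pytest.raises(ValueError, match="general"):
            ClockModel("general", ["cg1"], [1.0], [2.0], 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False,
                              width=64), min_size=1, max_size=20),
           st.floats(allow_nan=False, allow_infinity=False, width=64))
    def test_roundtrip_property_full_precision(self, tmp_path_factory, w, intercept):
        tmp = tmp_path_factory.mktemp("clock")
        cpgs = [f"cg{i}" for i in range(len(w))]
        m = ClockModel("immune", cpgs, np.array(w), np.array(w)[::-1], intercept)
        p = tmp / "c.tsv"
        write_clock_model(m, p)
        back = read_clock_model(p)
        assert np.array_equal(back.w, m.w) and np.array_equal(back.w_ic, m.w_ic)
        assert back.intercept == m.intercept


class TestCpGSet:
    def test_roundtrip_and_name_header(self, tmp_path):
        s = CpGSet("pcgt", frozenset(["cg3", "cg1", "cg2"]))
        p = tmp_path / "set.txt"
        write_cpg_set(s, p)
        back = read_cpg_set(p)
        assert back.name == "pcgt" and back.members == s.members

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CpGSet("x", frozenset())


class TestClockScores:
    def test_relative_age_identity_enforced(self):
        frame = pd.DataFrame({
            "sample_id": ["a"], "age": [50.0], "general_age": [52.0],
            "epithelial_age": [49.0], "immune_age": [54.0],
            "age_accel": [2.0], "rea": [-3.0], "ria": [2.0],
        })
        ClockScores(frame)  # consistent
        bad = frame.assign(rea=[1.0])
        with pytest.raises(ValueError, match="rea"):
            ClockScores(bad)
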