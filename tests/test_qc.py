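"""Quality-filter chain, KNN imputation and exclusion lists."""

import numpy as np
import pandas as pd
import pytest

from tickrate import (
    BetaMatrix, CpGSet, DetectionMatrix, QcConfig, apply_exclusions,
    filter_cohort, flag_failed, impute_failed,
)
from tickrate.synthetic import FailSpec, generate_qc_artifacts


def _det(beta, p):
    return DetectionMatrix(list(beta.cpg_ids), list(beta.sample_ids), p)


class TestFlagFailed:
    def test_threshold_is_strict(self, tiny_beta):
        p = np.full(tiny_beta.shape, 0.0001)
        p[0, 0] = 0.01   # exactly at threshold: not failed
        p[1, 1] = 0.011  # above: failed
        mask = flag_failed(_det(tiny_beta, p), QcConfig())
        assert not mask[0, 0] and mask[1, 1]
        assert mask.sum() == 1

    def test_all_zero_detection_gives_no_failures(self, tiny_beta):
        mask = flag_failed(_det(tiny_beta, np.zeros(tiny_beta.shape)))
        assert not mask.any()

    def test_matches_elementwise_comparison_oracle(self, tiny_beta):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.05, tiny_beta.shape)
        cfg = QcConfig(p_fail=0.02)
        mask = flag_failed(_det(tiny_beta, p), cfg)
        # brute-force cell-by-cell oracle
        expect = np.array([[pv > 0.02 for pv in row] for row in p])
        assert np.array_equal(mask, expect)


class TestFilterCohort:
    def test_constructed_sample_and_probe_drops(self, tiny_beta):
        # S1 fails 2/10 probes (20% > 10%) -> dropped;
        # cg0 then fails in 1 of remaining 4 samples (25% > 10%) -> dropped
        p = np.full(tiny_beta.shape, 0.0001)
        p[0, 1] = p[1, 1] = 0.5       # S1: two failed probes
        p[0, 2] = 0.5                 # cg0 also fails in S2
        beta, det, report = filter_cohort(tiny_beta, _det(tiny_beta, p))
        assert report.dropped_samples_failure == ["S1"]
        assert report.dropped_probes == ["cg0"]
        assert beta.shape == (9, 4)

    def test_low_intensity_sample_dropped_first(self, tiny_beta):
        p = np.full(tiny_beta.shape, 0.0001)
        inten = pd.DataFrame({"median_methylated": [10.5] * 5,
                              "median_unmethylated": [10.5] * 5},
                             index=tiny_beta.sample_ids)
        inten.loc["S2", "median_methylated"] = 9.3
        beta, det, report = filter_cohort(tiny_beta, _det(tiny_beta, p), inten)
        assert report.dropped_samples_intensity == ["S2"]
        assert "S2" not in beta.sample_ids

    def test_intensity_threshold_is_strict_less_than(self, tiny_beta):
        p = np.full(tiny_beta.shape, 0.0001)
        inten = pd.DataFrame({"median_methylated": [9.5] * 5,
                              "median_unmethylated": [9.5] * 5},
                             index=tiny_beta.sample_ids)
        beta, _, report = filter_cohort(tiny_beta, _det(tiny_beta, p), inten)
        assert report.dropped_samples_intensity == []
        assert beta.shape == tiny_beta.shape

    def test_clean_input_passes_through(self, tiny_beta):
        p = np.zeros(tiny_beta.shape)
        beta, det, report = filter_cohort(tiny_beta, _det(tiny_beta, p))
        assert beta.cpg_ids == tiny_beta.cpg_ids
        assert beta.sample_ids == tiny_beta.sample_ids
        assert np.array_equal(beta.values, tiny_beta.values)

    def test_filtering_is_idempotent(self, tiny_beta):
        rng = np.random.default_rng(4)
        p = np.where(rng.random(tiny_beta.shape) < 0.1, 0.5, 0.0001)
        b1, d1, _ = filter_cohort(tiny_beta, _det(tiny_beta, p))
        b2, d2, r2 = filter_cohort(b1, d1)
        assert b2.cpg_ids == b1.cpg_ids and b2.sample_ids == b1.sample_ids
        assert np.array_equal(b2.values, b1.values)
        assert not r2.dropped_samples_failure and not r2.dropped_probes

    def test_all_removed_is_an_error(self, tiny_beta):
        p = np.full(tiny_beta.shape, 0.5)
        with pytest.raises(ValueError, match="all samples removed"):
            filter_cohort(tiny_beta, _det(tiny_beta, p))


class TestImputeFailed:
    def test_identical_neighbours_give_shared_value(self):
        values = np.vstack([np.full(4, 0.3)] * 3 + [np.full(4, 0.8)])
        beta = BetaMatrix([f"cg{i}" for i in range(4)],
                          [f"S{j}" for j in range(4)], values)
        mask = np.zeros((4, 4), bool)
        mask[0, 2] = True
        out = impute_failed(beta, mask, QcConfig(knn_k=2))
        assert out.values[0, 2] == pytest.approx(0.3)

    def test_no_missing_is_bitwise_identity(self, tiny_beta):
        out = impute_failed(tiny_beta, np.zeros(tiny_beta.shape, bool))
        assert np.array_equal(out.values, tiny_beta.values)

    def test_matches_exhaustive_knn_oracle(self):
        # 4-probe toy: impute cg0@S1 from the 2 nearest rows by brute force
        values = np.array([
            [0.10, 0.20, 0.30],
            [0.11, 0.22, 0.29],   # near cg0
            [0.12, 0.19, 0.33],   # near cg0
            [0.90, 0.85, 0.80],   # far
        ])
        beta = BetaMatrix(["cg0", "cg1", "cg2", "cg3"], ["S0", "S1", "S2"], values)
        mask = np.zeros((4, 3), bool)
        mask[0, 1] = True
        # oracle: Euclidean over observed columns of cg0 (S0, S2)
        d = [np.sqrt((values[j, 0] - 0.10) ** 2 + (values[j, 2] - 0.30) ** 2)
             for j in (1, 2, 3)]
        nearest = [(1, 2, 3)[i] for i in np.argsort(d)[:2]]
        expect = np.mean([values[j, 1] for j in nearest])
        out = impute_failed(beta, mask, QcConfig(knn_k=2))
        assert out.values[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_observed_entries_untouched_and_in_range(self, tiny_beta):
        rng = np.random.default_rng(9)
        mask = rng.random(tiny_beta.shape) < 0.1
        out = impute_failed(tiny_beta, mask, QcConfig(knn_k=3))
        assert np.array_equal(out.values[~mask], tiny_beta.values[~mask])
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_fully_missing_probe_is_an_error(self, tiny_beta):
        mask = np.zeros(tiny_beta.shape, bool)
        mask[2, :] = True
        with pytest.raises(ValueError, match="cg2"):
            impute_failed(tiny_beta, mask)


class TestApplyExclusions:
    def test_set_difference(self, tiny_beta):
        out, counts = apply_exclusions(
            tiny_beta, CpGSet("snp", frozenset(["cg1", "cg5", "cg7"])))
        assert out.shape == (7, 5)
        assert counts == {"snp": 3}

    def test_no_lists_is_identity(self, tiny_beta):
        out, counts = apply_exclusions(tiny_beta)
        assert out.cpg_ids == tiny_beta.cpg_ids and counts == {}

    def test_overlapping_lists_counted_per_list_removed_once(self, tiny_beta):
        a = CpGSet("a", frozenset(["cg1", "cg2"]))
        b = CpGSet("b", frozenset(["cg2", "cg3", "cg999"]))
        out, counts = apply_exclusions(tiny_beta, a, b)
        # union oracle: {cg1, cg2, cg3} removed once each
        assert out.shape == (7, 5)
        assert counts == {"a": 2, "b": 2}  # cg999 absent from matrix


class TestQcArtifacts:
    def test_empty_fail_spec_filter_is_identity(self, tiny_beta):
        det, inten = generate_qc_artifacts(tiny_beta, FailSpec())
        beta, _, report = filter_cohort(tiny_beta, det, inten)
        assert np.array_equal(beta.values, tiny_beta.values)

    def test_designed_sample_removal_by_failure_rule(self, tiny_beta):
        spec = FailSpec(fail_cells=[("S0", "cg0"), ("S0", "cg1")])
        det, inten = generate_qc_artifacts(tiny_beta, spec)
        _, _, report = filter_cohort(tiny_beta, det, inten)
        assert report.dropped_samples_failure == ["S0"]

    def test_designed_intensity_removal(self, tiny_beta):
        det, inten = generate_qc_artifacts(
            tiny_beta, FailSpec(low_intensity_samples=["S3"]))
        _, _, report = filter_cohort(tiny_beta, det, inten)
        assert report.dropped_samples_intensity == ["S3"]

    def test_unknown_ids_rejected(self, tiny_beta):
        with pytest.raises(KeyError, match="nope"):
            generate_qc_artifacts(tiny_beta, FailSpec(fail_cells=[("nope", "cg0")]))
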