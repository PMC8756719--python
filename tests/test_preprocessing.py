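"""QC pipeline: depth filter, normalization, IQR outliers, filters, split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dnmap.preprocessing import (
    ExpressionMatrix,
    SampleOntology,
    drop_small_classes,
    filter_features,
    filter_low_depth,
    remove_outliers_iqr,
    run_qc_pipeline,
    sample_summary,
    stratified_split,
    total_count_normalize,
)


def make_matrix(values, normalized=False, prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        sample_ids=tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        feature_names=tuple(f"m{j}" for j in range(values.shape[1])),
        normalized=normalized,
    )


class TestExpressionMatrix:
    def test_rejects_invalid_values(self):
        with pytest.raises(ValueError, match="finite"):
            make_matrix([[1.0, np.nan]])
        with pytest.raises(ValueError, match="non-negative"):
            make_matrix([[1.0, -2.0]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(np.ones((2, 2)), ("a", "a"), ("f1", "f2"))
        with pytest.raises(ValueError, match="duplicate feature"):
            ExpressionMatrix(np.ones((2, 2)), ("a", "b"), ("f1", "f1"))

    def test_normalized_flag_requires_common_row_sum(self):
        with pytest.raises(ValueError, match="common sum"):
            make_matrix([[1, 2], [3, 5]], normalized=True)

    def test_tsv_round_trip(self, tmp_path):
        m = make_matrix([[1, 2, 3], [4, 5, 6]])
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        back = ExpressionMatrix.read_tsv(path)
        assert back.sample_ids == m.sample_ids
        assert back.feature_names == m.feature_names
        np.testing.assert_array_equal(back.values, m.values)


class TestFilterLowDepth:
    def test_hand_counted_toy(self):
        m = make_matrix(np.diag([2e6, 9e5, 1e6, 0, 3e6]))
        out = filter_low_depth(m, min_reads=1e6)
        assert out.sample_ids == ("s0", "s2", "s4")
        assert out.feature_names == m.feature_names

    def test_boundary_is_inclusive(self):
        m = make_matrix(np.full((3, 4), 250.0))
        out = filter_low_depth(m, min_reads=1000.0)
        assert out.sample_ids == m.sample_ids

    def test_all_removed_is_an_error(self):
        m = make_matrix([[1.0, 1.0]])
        with pytest.raises(ValueError, match="all samples removed"):
            filter_low_depth(m, min_reads=10)

    def test_refuses_normalized_input(self):
        m = make_matrix([[1, 1], [1, 1]], normalized=True)
        with pytest.raises(ValueError, match="raw"):
            filter_low_depth(m)


class TestNormalize:
    def test_uniform_row(self):
        out = total_count_normalize(make_matrix([[1, 1, 1, 1]]))
        np.testing.assert_allclose(out.values, [[250000] * 4])
        assert out.normalized

    def test_hand_computed_fractions(self):
        out = total_count_normalize(make_matrix([[10, 30, 60]]), scale=100)
        np.testing.assert_allclose(out.values, [[10, 30, 60]])

    def test_zero_sum_row_names_sample(self):
        m = make_matrix([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            total_count_normalize(m)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1e6), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        ),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_row_sums_equal_scale_and_scale_invariance(self, rows, c):
        m = make_matrix(rows)
        out = total_count_normalize(m)
        np.testing.assert_allclose(out.row_sums(), 1e6, rtol=1e-6)
        scaled = total_count_normalize(make_matrix(np.asarray(rows) * c))
        np.testing.assert_allclose(scaled.values, out.values, rtol=1e-9)


class TestIQROutliers:
    @staticmethod
    def concentration_matrix(weights):
        # each row sums to 100; mass concentration controls the log2 summary
        rows = []
        for w in weights:
            row = np.full(10, (100.0 - w) / 9)
            row[0] = w
            rows.append(row)
        return make_matrix(rows, normalized=True)

    def test_identical_summaries_remove_nothing(self):
        m = self.concentration_matrix([50, 50, 50, 50, 50])
        out, removed = remove_outliers_iqr(m)
        assert removed == ()
        assert out.sample_ids == m.sample_ids

    def test_matches_independent_fence_computation(self):
        m = self.concentration_matrix([10, 20, 30, 40, 99.9])
        summary = np.log2(m.values + 1).mean(axis=1)
        q1, q3 = np.quantile(summary, [0.25, 0.75])
        fence = (q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1))
        expected = tuple(
            s for s, v in zip(m.sample_ids, summary) if v < fence[0] or v > fence[1]
        )
        assert expected  # the highly concentrated sample must be flagged
        out, removed = remove_outliers_iqr(m)
        assert removed == expected

    def test_idempotent_on_retained_set(self):
        m = self.concentration_matrix([10, 20, 30, 40, 99.9])
        once, removed1 = remove_outliers_iqr(m)
        twice, removed2 = remove_outliers_iqr(once)
        assert removed1 and removed2 == ()
        assert twice.sample_ids == once.sample_ids

    def test_too_few_samples(self):
        m = self.concentration_matrix([10, 20, 30])
        with pytest.raises(ValueError, match="4 samples"):
            remove_outliers_iqr(m)

    def test_unknown_statistic(self):
        m = self.concentration_matrix([10, 20, 30, 40])
        with pytest.raises(ValueError, match="statistic"):
            remove_outliers_iqr(m, statistic="mode")


class TestFilterFeatures:
    def test_zero_threshold_is_identity(self):
        m = make_matrix([[0, 1], [0, 2]], normalized=False)
        m = total_count_normalize(m)
        assert filter_features(m, 0).feature_names == m.feature_names

    def test_all_zero_feature_always_removed(self):
        m = total_count_normalize(make_matrix([[0, 1, 1], [0, 2, 2]]))
        out = filter_features(m, min_fraction_expressed=0.01)
        assert out.feature_names == ("m1", "m2")

    def test_presence_fraction_threshold(self):
        values = np.ones((4, 2))
        values[1:, 0] = 0  # feature m0 present in 1/4 samples
        m = total_count_normalize(make_matrix(values))
        out = filter_features(m, min_fraction_expressed=0.5)
        assert out.feature_names == ("m1",)


def make_ontology(class_sizes):
    ids, tissues, status = [], [], []
    for k, ((tissue, neo), n) in enumerate(class_sizes.items()):
        for i in range(n):
            ids.append(f"{tissue}{'+' if neo else '-'}{i}")
            tissues.append(tissue)
            status.append(neo)
    return SampleOntology(tuple(ids), tuple(tissues), tuple(status))


class TestDropSmallClasses:
    def test_hand_counted_classes(self):
        ont = make_ontology({("a", True): 12, ("b", True): 9, ("c", False): 10})
        m = make_matrix(np.ones((31, 3)) / 3, normalized=True, prefix="")
        m = ExpressionMatrix(m.values, ont.sample_ids, m.feature_names, normalized=True)
        out_m, out_ont = drop_small_classes(m, ont, min_n=10)
        assert out_m.n_samples == 22
        assert set(out_ont.tissue) == {"a", "c"}

    def test_min_one_is_identity(self):
        ont = make_ontology({("a", True): 2, ("b", False): 1})
        m = ExpressionMatrix(np.ones((3, 2)) / 2, ont.sample_ids, ("m0", "m1"), normalized=True)
        out_m, _ = drop_small_classes(m, ont, min_n=1)
        assert out_m.sample_ids == m.sample_ids


class TestStratifiedSplit:
    def test_exact_fractions(self):
        ont = make_ontology({("a", True): 10})
        split = stratified_split(ont, test_frac=0.4, val_frac=0.0, seed=0)
        assert len(split.test_ids) == 4 and len(split.train_ids) == 6

    def test_deterministic_and_count_stable(self):
        ont = make_ontology({("a", True): 11, ("b", False): 7, ("b", True): 25})
        s1 = stratified_split(ont, seed=3)
        s2 = stratified_split(ont, seed=3)
        assert s1 == s2
        s3 = stratified_split(ont, seed=4)
        assert s3 != s1
        assert len(s3.test_ids) == len(s1.test_ids)
        assert len(s3.val_ids) == len(s1.val_ids)

    def test_singleton_class_is_an_error(self):
        ont = make_ontology({("a", True): 1, ("b", True): 5})
        with pytest.raises(ValueError, match="drop_small_classes"):
            stratified_split(ont)

    @given(
        st.lists(st.integers(2, 23), min_size=1, max_size=6),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_and_per_class_rounding(self, sizes, seed):
        ont = make_ontology({(f"t{k}", True): n for k, n in enumerate(sizes)})
        split = stratified_split(ont, test_frac=0.4, val_frac=0.2, seed=seed)
        all_ids = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
        assert all_ids == set(ont.sample_ids)
        assert len(split.train_ids) + len(split.val_ids) + len(split.test_ids) == len(ont)
        class_of = ont.class_of()
        for cls, n in ont.class_counts().items():
            n_test = sum(1 for s in split.test_ids if class_of[s] == cls)
            assert abs(n_test - 0.4 * n) < 1 or n_test in (1, n - 1)
            assert 1 <= n_test <= n - 1  # both sides represented


class TestPipeline:
    def test_planted_failures_reported(self):
        from dnmap.synthetic import SynthConfig, generate_cohort

        cfg = SynthConfig(seed=1, n_lowdepth=3, n_outliers=2, net_like_tissues=(),
                          net_signature_size=0)
        raw, truth = generate_cohort(cfg)
        matrix, ont, report = run_qc_pipeline(raw, truth.ontology)
        assert set(report.low_depth_ids) == set(truth.planted_lowdepth_ids)
        assert set(report.outlier_ids) == set(truth.planted_outlier_ids)
        np.testing.assert_allclose(matrix.row_sums(), 1e6, rtol=1e-6)

    def test_missing_ontology_entry(self):
        m = make_matrix(np.ones((2, 3)) * 1e6)
        ont = SampleOntology(("s0",), ("a",), (True,))
        with pytest.raises(ValueError, match="missing from ontology"):
            run_qc_pipeline(m, ont)
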