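"""Missing-value filtering, KNN imputation, scaling, fusion, class labels."""

import numpy as np
import pytest

from metabotype import (
    Autoscaler,
    autoscale,
    block_scale,
    filter_missing,
    knn_impute,
    make_class_labels,
)
from tests.conftest import toy_block, toy_phenotypes


def block_with_missing(n=12, p=19, missing=()):
    rng = np.random.default_rng(0)
    vals = rng.normal(10, 2, (n, p))
    for i, j in missing:
        vals[i, j] = np.nan
    return toy_block(vals)


class TestFilterMissing:
    def test_one_third_rule_on_samples(self):
        # 7/19 = 0.368 > 1/3 dropped; 6/19 = 0.316 <= 1/3 kept
        block = block_with_missing(
            missing=[(0, j) for j in range(7)] + [(1, j) for j in range(6)]
        )
        out, report = filter_missing(block)
        assert report.dropped_samples == ["S0"]
        assert "S1" in out.data.index

    def test_variables_filtered_after_samples(self):
        # column 0 is missing in 5 of 9 rows, but 4 of those rows are
        # themselves dropped (>1/3 missing); recomputed on survivors the
        # column falls back under the threshold and is kept
        n, p = 9, 3
        missing = [(i, j) for i in range(4) for j in range(2)]  # rows 0-3: 2/3 missing
        missing += [(4, 0)]  # row 4 only misses column 0
        block = block_with_missing(n=n, p=p, missing=missing)
        out, report = filter_missing(block)
        assert len(report.dropped_samples) == 4
        assert report.dropped_features == []
        assert out.data.shape == (5, 3)

    def test_fully_observed_is_identity_and_idempotent(self):
        block = block_with_missing()
        out, report = filter_missing(block)
        assert out.data.equals(block.data)
        again, rep2 = filter_missing(out)
        assert again.data.equals(out.data)
        assert rep2.dropped_samples == [] and rep2.dropped_features == []

    def test_empty_result_raises(self):
        block = block_with_missing(n=3, p=3, missing=[(i, j) for i in range(3) for j in range(2)])
        with pytest.raises(ValueError):
            filter_missing(block)


class TestKNNImpute:
    def test_no_missing_is_identity(self):
        block = block_with_missing()
        out = knn_impute(block, k=3)
        assert np.allclose(out.values, block.values)

    def test_constant_feature_imputes_the_constant(self):
        vals = np.random.default_rng(1).normal(size=(6, 3))
        vals[:, 2] = 7.0
        vals[0, 2] = np.nan
        out = knn_impute(toy_block(vals), k=3)
        assert out.values[0, 2] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self):
        """One missing cell in a 5x3 block vs an independent hand computation."""
        vals = np.array(
            [
                [1.0, 2.0, np.nan],
                [1.1, 2.1, 3.0],
                [0.9, 1.9, 3.2],
                [5.0, 6.0, 9.0],
                [5.2, 6.1, 9.5],
            ]
        )
        k = 2
        out = knn_impute(toy_block(vals), k=k)

        # oracle: autoscale on observed values, Euclidean over mutually
        # observed features, inverse-distance-weighted mean of the k nearest
        # donors observing the target feature
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
        z = (vals - mu) / sd
        dists = []
        for c in range(1, 5):
            shared = [j for j in range(3) if not np.isnan(vals[0, j]) and not np.isnan(vals[c, j])]
            d = np.sqrt(sum((z[0, j] - z[c, j]) ** 2 for j in shared))
            dists.append((d, c))
        dists.sort()
        nn = dists[:k]
        w = [1.0 / (d + 1e-12) for d, _ in nn]
        expected = sum(wi * vals[c, 2] for wi, (_, c) in zip(w, nn)) / sum(w)
        assert out.values[0, 2] == pytest.approx(expected, abs=1e-10)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 6))
        mask = rng.random((30, 6)) < 0.15
        mask[:, 0] = False  # keep one anchor column
        vals_missing = vals.copy()
        vals_missing[mask] = np.nan
        out = knn_impute(toy_block(vals_missing), k=5)
        assert np.allclose(out.values[~mask], vals[~mask])
        assert not np.isnan(out.values).any()


class TestAutoscale:
    def test_scaled_columns_standardized(self, cohort_500):
        _, _, blocks = cohort_500
        scaled, _, scaler = autoscale(blocks["clinical"])
        assert np.abs(scaled.values.mean(axis=0)).max() < 1e-10
        assert np.abs(scaled.values.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_flagged_and_zeroed(self):
        vals = np.random.default_rng(0).normal(size=(10, 3))
        vals[:, 1] = 4.2
        scaled, _, scaler = autoscale(toy_block(vals))
        assert scaler.zero_sd_flags_.tolist() == [False, True, False]
        assert np.allclose(scaled.values[:, 1], 0.0)

    def test_params_transfer_to_companion_block(self):
        rng = np.random.default_rng(5)
        train = toy_block(rng.normal(2, 3, (20, 4)))
        other = toy_block(rng.normal(2, 3, (8, 4)), ids=[f"T{i}" for i in range(8)])
        scaled_train, [scaled_other], scaler = autoscale(train, [other])
        # companion uses train parameters, not its own
        assert np.allclose(
            scaled_other.values, (other.values - scaler.means_) / scaler.sds_
        )
        # applying params to an identical copy reproduces the scaled train
        copy_scaled, _, _ = autoscale(train)
        assert np.allclose(copy_scaled.values, scaled_train.values)


class TestBlockScale:
    def test_each_block_total_variance_one(self):
        rng = np.random.default_rng(2)
        a = toy_block(rng.normal(5, 2, (40, 19)), name="clin")
        b = toy_block(rng.lognormal(1, 1, (40, 126)), name="gcms")
        mb = block_scale([a, b])
        X = mb.values.to_numpy()
        for name, sl in mb.block_slices.items():
            total_var = X[:, sl].var(axis=0, ddof=1).sum()
            assert total_var == pytest.approx(1.0, abs=1e-8)

    def test_three_block_toy_matches_oracle(self):
        rng = np.random.default_rng(7)
        sizes = (2, 3, 4)
        blocks = [
            toy_block(rng.normal(size=(6, p)), name=f"b{p}") for p in sizes
        ]
        mb = block_scale(blocks)
        # oracle: per-feature standardize then divide by sqrt(p), per block
        expected = []
        for blk in blocks:
            v = blk.values
            z = (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)
            expected.append(z / np.sqrt(blk.n_features))
        assert np.allclose(mb.values.to_numpy(), np.hstack(expected), atol=1e-12)

    def test_misalignment_reported(self):
        a = toy_block(np.zeros((3, 2)) + np.arange(3)[:, None], ids=["A", "B", "C"])
        b = toy_block(np.ones((3, 2)) * np.arange(3)[:, None], ids=["A", "B", "D"])
        with pytest.raises(ValueError, match="misalignment"):
            block_scale([a, b])

    def test_single_block_rejected(self):
        a = toy_block(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            block_scale([a])


class TestClassLabels:
    def test_age_boundaries(self):
        phenos = toy_phenotypes(
            age=[49.0, 50.0, 65.0, 66.0],
            sex=["male", "female", "male", "female"],
            bmi=[22.0, 22.0, 35.0, 35.0],
        )
        labels = make_class_labels(phenos, "age")
        assert labels.retained_mask.tolist() == [True, False, False, True]
        assert labels.labels.tolist() == ["young", "old"]

    def test_bmi_boundaries(self):
        phenos = toy_phenotypes(
            bmi=[25.0, 25.1, 30.0, 30.1],
            sex=["male", "female", "male", "female"],
            age=[30.0, 30.0, 70.0, 70.0],
        )
        labels = make_class_labels(phenos, "bmi")
        assert labels.retained_mask.tolist() == [True, False, False, True]
        assert labels.labels.tolist() == ["lean", "obese"]

    def test_sex_retains_everyone(self, cohort_500):
        _, phenos, _ = cohort_500
        labels = make_class_labels(phenos, "sex")
        assert labels.retained_mask.all()
        assert set(labels.labels) == {"male", "female"}

    def test_partition_property(self, cohort_500):
        _, phenos, _ = cohort_500
        for trait in ("age", "bmi"):
            labels = make_class_labels(phenos, trait)
            n_a = (labels.labels == labels.class_names[0]).sum()
            n_b = (labels.labels == labels.class_names[1]).sum()
            assert n_a + n_b == labels.retained_mask.sum()
            assert n_a > 0 and n_b > 0

    def test_degenerate_class_raises(self):
        phenos = toy_phenotypes(
            age=[30.0, 35.0, 40.0], sex=["male"] * 3, bmi=[22.0, 23.0, 24.0]
        )
        with pytest.raises(ValueError, match="degenerate"):
            make_class_labels(phenos, "age")

    def test_unknown_trait(self, cohort_500):
        _, phenos, _ = cohort_500
        with pytest.raises(ValueError):
            make_class_labels(phenos, "height")
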