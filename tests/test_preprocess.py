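import numpy as np
import pandas as pd
import pytest

from mirdecoy.cohort import CohortConfig, generate_cohort
from mirdecoy.preprocess import (
    batch_adjust,
    delta_ct,
    group_compare,
    lentiviral_titer,
    pca_qc,
    quantile_normalize,
    relative_quantity,
)
from mirdecoy.sequence_io import ExpressionMatrix, SampleMetadata


def matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def meta(samples, genotypes, treatments, batches):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "genotype": genotypes,
                "treatment": treatments,
                "batch": batches,
            }
        )
    )


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = matrix([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_two_by_two_rank_means(self):
        m = matrix([[1, 2], [3, 4]])  # columns [1,3] and [2,4]
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, np.array([[1.5, 1.5], [3.5, 3.5]]))

    def test_columns_share_distribution(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.normal(size=(50, 6)))
        out = quantile_normalize(m).values
        for c in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, c]))

    def test_idempotent_on_continuous_data(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(8, 1.5, size=(40, 4))
        once = quantile_normalize(matrix(arr)).values
        twice = quantile_normalize(quantile_normalize(matrix(arr))).values
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_within_column_ties_share_averaged_value(self):
        m = matrix([[1, 3], [1, 4], [2, 5]])  # column 0 has a tie at rank 1-2
        out = quantile_normalize(m).values
        assert out[0, 0] == out[1, 0] == pytest.approx((2.0 + 2.5) / 2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(matrix([[1.0], [2.0]]))


class TestBatchAdjust:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.base = rng.normal(8, 1, size=(30, 8))
        self.samples = [f"s{j}" for j in range(8)]
        self.meta = meta(
            self.samples,
            ["EU", "TS"] * 4,
            ["control", "sponge"] * 4,
            ["A"] * 4 + ["B"] * 4,
        )

    def test_constructed_shift_removed(self):
        arr = self.base.copy()
        arr[:, 4:] += 2.0  # batch B shifted
        out = batch_adjust(matrix(arr, samples=self.samples), self.meta).values
        per_gene_diff = out[:, :4].mean(axis=1) - out[:, 4:].mean(axis=1)
        assert np.abs(per_gene_diff).max() < 1e-9

    def test_pooled_gene_mean_preserved(self):
        arr = self.base.copy()
        arr[:, 4:] += 2.0
        out = batch_adjust(matrix(arr, samples=self.samples), self.meta).values
        np.testing.assert_allclose(out.mean(axis=1), arr.mean(axis=1), atol=1e-9)

    def test_within_batch_rank_order_preserved(self):
        arr = self.base.copy()
        arr[:, 4:] += 2.0
        out = batch_adjust(matrix(arr, samples=self.samples), self.meta).values
        for g in range(arr.shape[0]):
            for cols in (slice(0, 4), slice(4, 8)):
                assert (np.argsort(arr[g, cols]) == np.argsort(out[g, cols])).all()

    def test_single_batch_identity_with_flag(self):
        m = meta(self.samples, ["EU", "TS"] * 4, ["control", "sponge"] * 4, ["A"] * 8)
        x = matrix(self.base, samples=self.samples)
        out = batch_adjust(x, m, allow_single_batch=True)
        np.testing.assert_allclose(out.values, x.values)
        with pytest.raises(ValueError, match="2 batches"):
            batch_adjust(x, m)

    def test_confounded_batch_warns_but_proceeds(self):
        m = meta(
            self.samples,
            ["EU"] * 4 + ["TS"] * 4,
            ["control", "sponge"] * 4,
            ["A"] * 4 + ["B"] * 4,
        )
        with pytest.warns(UserWarning, match="confounded"):
            batch_adjust(matrix(self.base, samples=self.samples), m)


class TestQPCRQuantities:
    def test_delta_ct_examples(self):
        assert delta_ct(25, 20) == 5
        assert delta_ct(20, 20) == 0
        with pytest.raises(ValueError, match="outside"):
            delta_ct(50, 20)

    def test_rq_calibrator_is_one(self):
        dct = pd.Series({"a": 5.0, "b": 7.0, "c": 6.0})
        rq = relative_quantity(dct, ["a", "b"])
        # sample with dCt equal to the calibrator mean (6.0) has RQ 1
        assert rq["c"] == pytest.approx(1.0)
        assert rq.loc[["a", "b"]].prod() == pytest.approx(1.0)  # 2^1 * 2^-1

    def test_rq_doubling_rules(self):
        dct = pd.Series({"cal": 10.0, "up": 8.0, "down": 11.0})
        rq = relative_quantity(dct, ["cal"])
        assert rq["down"] == pytest.approx(0.5)  # ddCt = +1
        assert rq["up"] == pytest.approx(4.0)  # ddCt = -2

    def test_rq_shift_invariance(self):
        dct = pd.Series({"a": 5.0, "b": 6.5, "c": 9.0})
        rq1 = relative_quantity(dct, ["a"])
        rq2 = relative_quantity(dct + 3.0, ["a"])
        np.testing.assert_allclose(rq1 / rq1["b"], rq2 / rq2["b"])

    def test_empty_calibrator_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            relative_quantity(pd.Series({"a": 1.0}), [])


class TestGroupCompare:
    def test_null_distributions_not_significant(self):
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            values = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
            groups = pd.Series(["x"] * 6 + ["y"] * 6, index=values.index)
            _, p = group_compare(values, groups)
            assert p > 0.05

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 6), rng.normal(10, 1, 6)]),
            index=[f"s{i}" for i in range(12)],
        )
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=values.index)
        _, p = group_compare(values, groups)
        assert p < 0.01

    def test_small_group_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValueError, match="2 samples"):
            group_compare(values, groups)


class TestTiter:
    def test_printed_formula(self):
        assert lentiviral_titer(6.6e-7, 1000) == pytest.approx(6.02e11)

    def test_linear_in_concentration(self):
        assert lentiviral_titer(2e-7, 500) == pytest.approx(2 * lentiviral_titer(1e-7, 500))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lentiviral_titer(1e-7, 0)


class TestPCAQC:
    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(20, 3))
        arr = np.column_stack([arr, arr[:, 0]])
        m = matrix(arr)
        md = meta(m.sample_ids, ["EU", "EU", "TS", "EU"],
                  ["control", "sponge", "control", "control"], ["A", "A", "B", "B"])
        rep = pca_qc(m, md)
        np.testing.assert_allclose(rep.scores.iloc[0], rep.scores.iloc[3], atol=1e-8)

    def test_constant_matrix_flagged(self):
        m = matrix(np.full((10, 4), 3.0))
        md = meta(m.sample_ids, ["EU", "EU", "TS", "TS"],
                  ["control", "sponge", "control", "sponge"], ["A", "A", "B", "B"])
        rep = pca_qc(m, md)
        assert rep.degenerate and rep.variance_fractions == (0.0, 0.0)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_genotype_separates_before_treatment(self, seed):
        # dosage effect >> sponge effect: genotype centroids split on PC1-2
        data = generate_cohort(CohortConfig(seed=seed))
        adjusted = batch_adjust(data.expression, data.metadata)
        rep = pca_qc(adjusted, data.metadata)
        assert rep.genotype_separates_first
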