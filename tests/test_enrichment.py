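import numpy as np
import pandas as pd
import pytest

from mirdecoy.cohort import CohortConfig, generate_cohort
from mirdecoy.enrichment import (
    bin_pairs,
    direction_concordance,
    gsea_es,
    gsea_permutation_p,
    normalization_fractions,
)
from mirdecoy.sequence_io import GeneLocus


def brute_running_sum(metric: pd.Series, gene_set, p=1.0):
    """Independent recomputation of the weighted KS running sum."""
    ordered = sorted(metric.items(), key=lambda kv: (-kv[1], kv[0]))
    hits = [g for g, _ in ordered if g in gene_set]
    denom_hit = sum(abs(v) ** p for g, v in ordered if g in gene_set)
    n_miss = len(ordered) - len(hits)
    running, best = 0.0, 0.0
    for g, v in ordered:
        if g in gene_set:
            running += (abs(v) ** p / denom_hit) if denom_hit > 0 else 1.0 / len(hits)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_gene_singleton_set(self):
        metric = pd.Series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        res = gsea_es(metric, {"g1"})
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g1"]

    def test_set_equals_universe(self):
        metric = pd.Series({"a": 2.0, "b": 1.0})
        assert gsea_es(metric, {"a", "b"}).es == pytest.approx(1.0)

    def test_reversed_ranking_negates_singleton_es(self):
        metric = pd.Series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        res_fwd = gsea_es(metric, {"g1"})
        res_rev = gsea_es(-metric, {"g1"})
        assert res_rev.es == pytest.approx(-res_fwd.es)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea_es(pd.Series({"a": 1.0}), {"zzz"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_running_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        metric = pd.Series(rng.normal(size=n), index=[f"g{k}" for k in range(n)])
        members = set(rng.choice(metric.index, size=int(rng.integers(1, n)), replace=False))
        res = gsea_es(metric, members)
        assert res.es == pytest.approx(brute_running_sum(metric, members), abs=1e-12)


class TestPermutationP:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        metric = pd.Series(rng.normal(size=60), index=[f"g{k}" for k in range(60)])
        members = set(metric.index[:10])
        a = gsea_permutation_p(metric, members, nperm=100, seed=5)
        b = gsea_permutation_p(metric, members, nperm=100, seed=5)
        assert a.p_perm == b.p_perm

    def test_strong_signal_hits_floor(self):
        # top decile of a strongly structured metric
        metric = pd.Series(
            np.linspace(5, -5, 100), index=[f"g{k:03d}" for k in range(100)]
        )
        members = set(metric.index[:10])
        res = gsea_permutation_p(metric, members, nperm=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_null_calibration(self):
        # permutation p is approximately uniform under a random set
        rng = np.random.default_rng(7)
        hits = 0
        trials = 100
        for _ in range(trials):
            metric = pd.Series(rng.normal(size=60), index=[f"g{k}" for k in range(60)])
            members = set(rng.choice(metric.index, size=8, replace=False))
            res = gsea_permutation_p(metric, members, nperm=100, seed=rng.integers(2**31))
            hits += res.p_perm < 0.05
        assert hits / trials <= 0.08

    def test_nperm_floor(self):
        with pytest.raises(ValueError, match="nperm"):
            gsea_permutation_p(pd.Series({"a": 1.0, "b": 0.5}), {"a"}, nperm=10)


class TestBinPairs:
    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["mirna", "gene", "r"])

    def test_three_genes_one_bin(self):
        loci = [GeneLocus(f"g{k}", "chr1", 10_000 + k, 20_000 + k) for k in range(3)]
        pairs = self.pairs([("m", f"g{k}", -0.5) for k in range(3)])
        bins, unlocated = bin_pairs(pairs, loci)
        assert unlocated == 0
        assert len(bins) == 1 and bins.loc[0, "n_pairs"] == 3

    def test_half_open_bin_boundary(self):
        loci = [
            GeneLocus("a", "chr1", 999_999, 1_000_500),
            GeneLocus("b", "chr1", 1_000_000, 1_000_500),
        ]
        pairs = self.pairs([("m", "a", -0.4), ("m", "b", -0.4)])
        bins, _ = bin_pairs(pairs, loci)
        assert sorted(bins["start"]) == [0, 1_000_000]

    def test_pair_conservation(self):
        rng = np.random.default_rng(0)
        loci = [
            GeneLocus(f"g{k}", f"chr{rng.integers(1, 4)}", int(rng.integers(0, 5_000_000)), 6_000_000)
            for k in range(20)
        ]
        pairs = self.pairs([("m", f"g{k}", -0.5) for k in range(25)])  # 5 without loci
        bins, unlocated = bin_pairs(pairs, loci)
        assert bins["n_pairs"].sum() + unlocated == 25


class TestConcordance:
    def test_equal_profiles(self):
        fc = pd.Series({"a": 1.0, "b": -2.0})
        assert direction_concordance(fc, fc).fraction_same_direction == 1.0

    def test_negated_profiles(self):
        fc = pd.Series({"a": 1.0, "b": -2.0})
        assert direction_concordance(fc, -fc).fraction_same_direction == 0.0

    def test_independent_signs_near_half(self):
        rng = np.random.default_rng(3)
        idx = [f"g{k}" for k in range(10_000)]
        a = pd.Series(rng.choice([-1.0, 1.0], size=10_000), index=idx)
        b = pd.Series(rng.choice([-1.0, 1.0], size=10_000), index=idx)
        res = direction_concordance(a, b)
        assert res.fraction_same_direction == pytest.approx(0.5, abs=0.02)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        idx = [f"g{k}" for k in range(50)]
        a = pd.Series(rng.normal(size=50), index=idx)
        b = pd.Series(rng.normal(size=50), index=idx)
        assert (
            direction_concordance(a, b).fraction_same_direction
            == direction_concordance(b, a).fraction_same_direction
        )

    def test_no_common_genes_rejected(self):
        with pytest.raises(ValueError, match="common"):
            direction_concordance(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestNormalizationFractions:
    def test_full_silencing_normalizes_everything(self):
        tri = pd.Series({"a": -1.0, "b": -0.8})
        silenced = pd.Series({"a": 0.0, "b": 0.0})
        res = normalization_fractions(tri, silenced, ["a", "b"])
        assert res.fraction_down == 1.0 and res.fraction_normalized == 1.0

    def test_no_change_upon_silencing(self):
        tri = pd.Series({"a": -1.0, "b": -0.8})
        res = normalization_fractions(tri, tri, ["a", "b"])
        assert res.fraction_normalized == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_synthetic_restoration(self, seed):
        """Sponge treatment of the trisomic cohort restores target expression:
        targets are down in TS-control vs EU and normalized in TS-sponge."""
        data = generate_cohort(CohortConfig(seed=seed))
        expr = data.expression.data
        meta = data.metadata.data.set_index("sample_id")
        eu = expr.loc[:, meta["genotype"] == "EU"].mean(axis=1)
        ts_ctrl = expr.loc[:, (meta["genotype"] == "TS") & (meta["treatment"] == "control")].mean(axis=1)
        ts_sponge = expr.loc[:, (meta["genotype"] == "TS") & (meta["treatment"] == "sponge")].mean(axis=1)
        candidates = data.truth.target_genes("mmu-miR-155") + data.truth.target_genes("mmu-miR-802")
        res = normalization_fractions(ts_ctrl - eu, ts_sponge - eu, candidates)
        assert res.fraction_down >= 0.9
        assert res.fraction_normalized >= 0.9
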