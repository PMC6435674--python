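"""Pearson screen, Monte-Carlo overlap, eigengenes and permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nwdose import (
    AnalysisConfig,
    adjust_overlaps,
    build_eigengene,
    build_lab_design,
    eigengene_assoc,
    monte_carlo_overlap,
    normalize_unit_interval,
    pearson_fdr,
    simulate_lab_counts,
    simulate_phenotypes,
    size_factors,
)

from conftest import make_counts


class TestPearsonFdr:
    def test_gene_equal_to_phenotype_is_perfect(self, rng):
        y = rng.normal(size=12)
        expr = pd.DataFrame([y, rng.normal(size=12)],
                            index=["hit", "noise"],
                            columns=[f"s{i}" for i in range(12)])
        pheno = pd.Series(y, index=expr.columns)
        out = pearson_fdr(expr, pheno)
        assert np.isclose(out.loc["hit", "r"], 1.0)
        assert out.loc["hit", "raw_p"] < 1e-10
        assert out.loc["hit", "significant"]

    def test_null_genes_rarely_pass_fdr(self, rng):
        expr = pd.DataFrame(rng.normal(size=(1000, 20)),
                            columns=[f"s{i}" for i in range(20)])
        pheno = pd.Series(rng.normal(size=20), index=expr.columns)
        out = pearson_fdr(expr, pheno)
        assert out["significant"].mean() < 0.01

    def test_matches_scipy_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 15)),
                            columns=[f"s{i}" for i in range(15)])
        pheno = pd.Series(rng.normal(size=15), index=expr.columns)
        out = pearson_fdr(expr, pheno)
        for gene in expr.index:
            r_ref, p_ref = stats.pearsonr(expr.loc[gene], pheno)
            assert abs(out.loc[gene, "r"] - r_ref) < 1e-12
            assert abs(out.loc[gene, "raw_p"] - p_ref) < 1e-9

    def test_constant_gene_flagged_not_significant(self, rng):
        expr = pd.DataFrame([np.full(10, 3.0), rng.normal(size=10)],
                            index=["flat", "ok"],
                            columns=[f"s{i}" for i in range(10)])
        pheno = pd.Series(rng.normal(size=10), index=expr.columns)
        out = pearson_fdr(expr, pheno)
        assert not out.loc["flat", "significant"]
        assert out.loc["flat", "reason"] == "constant gene"
        assert np.isnan(out.loc["flat", "r"])


class TestMonteCarloOverlap:
    BG = [f"g{i}" for i in range(2000)]

    def test_identical_sets_hit_floor_p(self):
        genes = self.BG[:20]
        res = monte_carlo_overlap(genes, genes, self.BG, n_perm=500, seed=1)
        assert res.observed == 20
        assert res.p == 1 / 501

    def test_disjoint_small_sets_not_significant(self):
        res = monte_carlo_overlap(self.BG[:5], self.BG[5:10], self.BG,
                                  n_perm=500, seed=1)
        assert res.observed == 0
        assert res.p == 1.0

    def test_reproducible_for_fixed_seed(self):
        a, b = self.BG[:50], self.BG[30:110]
        r1 = monte_carlo_overlap(a, b, self.BG, n_perm=300, seed=9)
        r2 = monte_carlo_overlap(a, b, self.BG, n_perm=300, seed=9)
        assert r1.p == r2.p

    def test_gene_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            monte_carlo_overlap(["absent"], self.BG[:5], self.BG)

    def test_matches_hypergeometric_oracle(self, rng):
        """Overlap of a uniform draw follows the hypergeometric law, so the
        Monte-Carlo tail must agree with the closed form within MC error."""
        n_perm = 400
        checked = 0
        for _ in range(20):
            n_bg = int(rng.integers(200, 800))
            bg = [f"g{i}" for i in range(n_bg)]
            n_a = int(rng.integers(10, 60))
            n_b = int(rng.integers(10, 80))
            shared = int(rng.integers(0, min(n_a, n_b)))
            set_a = bg[:n_a]
            set_b = bg[n_a - shared:n_a - shared + n_b]
            res = monte_carlo_overlap(set_a, set_b, bg, n_perm=n_perm,
                                      seed=int(rng.integers(2 ** 31)))
            p_exact = stats.hypergeom.sf(res.observed - 1, n_bg, n_b, n_a)
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_perm)
            assert abs(res.p - p_exact) <= 3 * se + 2 / n_perm
            checked += 1
        assert checked == 20

    def test_bh_adjustment_across_pairs(self):
        results = [monte_carlo_overlap(self.BG[:20], self.BG[:20], self.BG,
                                       n_perm=200, seed=s) for s in range(3)]
        adjust_overlaps(results)
        assert all(r.adj_p >= r.p for r in results)


class TestEigengene:
    def test_single_gene_scores_match_centered_profile(self, rng):
        values = rng.integers(10, 300, size=(1, 8))
        counts = make_counts(values)
        factors = pd.Series(np.ones(8), index=counts.sample_ids)
        eig = build_eigengene(counts, factors)
        profile = np.log2(values[0] + 1.0)
        profile -= profile.mean()
        scores = eig.scores.to_numpy()
        cos = abs(scores @ profile) / (np.linalg.norm(scores)
                                       * np.linalg.norm(profile))
        assert np.isclose(cos, 1.0)
        assert np.isclose(eig.variance_proportion, 1.0)

    def test_perfectly_correlated_genes_have_full_variance(self):
        base = np.array([10, 20, 40, 80, 160, 320])
        counts = make_counts(np.vstack([base, base]))
        factors = pd.Series(np.ones(6), index=counts.sample_ids)
        eig = build_eigengene(counts, factors)
        assert np.isclose(eig.variance_proportion, 1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.integers(0, 500, size=(50, 20))
        counts = make_counts(values)
        factors = pd.Series(np.ones(20), index=counts.sample_ids)
        eig = build_eigengene(counts, factors)
        # brute force: eigendecomposition of the gene-gene covariance, then
        # project samples onto the leading eigenvector
        X = np.log2(values + 1.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T
        w, v = np.linalg.eigh(cov)
        scores_ref = v[:, -1] @ Xc
        scores = eig.scores.to_numpy()
        if np.dot(scores, scores_ref) < 0:
            scores_ref = -scores_ref
        assert np.allclose(scores, scores_ref, atol=1e-8)
        assert np.isclose(eig.variance_proportion, w[-1] / w.sum(), atol=1e-10)

    def test_single_sample_rejected(self):
        counts = make_counts([[5], [7]])
        with pytest.raises(ValueError, match="2 samples"):
            build_eigengene(counts, pd.Series([1.0], index=counts.sample_ids))


class TestEigengeneAssociation:
    # mixed background: random null gene sets then express a blend of dose
    # patterns, so the permutation null is not dominated by any one class
    @pytest.fixture(scope="class")
    def background(self):
        design = build_lab_design()
        counts, truths = simulate_lab_counts(
            design, 300,
            {"N": 0.16, "W": 0.16, "NdivW": 0.16, "NxW": 0.16, "null": 0.36},
            seed=77)
        nxw = [t.gene_id for t in truths if t.true_class == "NxW"]
        return design, counts, nxw

    def test_phenotype_equal_to_scores_hits_floor(self, background):
        _, counts, nxw = background
        factors = size_factors(counts)
        eig = build_eigengene(counts.subset_genes(nxw), factors)
        assoc = eigengene_assoc(eig, eig.scores, counts, n_perm=200, seed=4,
                                factors=factors)
        assert np.isclose(assoc.abs_r, 1.0)
        assert assoc.p == 1 / 201

    def test_sign_flip_invariance(self, background):
        design, counts, nxw = background
        factors = size_factors(counts)
        eig = build_eigengene(counts.subset_genes(nxw), factors)
        pheno = np.log2(simulate_phenotypes(
            design, {"intercept": 1.0, "NxW": 0.5}, seed=3).trait("shoot_biomass"))
        a = eigengene_assoc(eig, pheno, counts, n_perm=100, seed=5, factors=factors)
        eig.scores = -eig.scores
        b = eigengene_assoc(eig, pheno, counts, n_perm=100, seed=5, factors=factors)
        assert a.abs_r == b.abs_r and a.p == b.p

    def test_constant_phenotype_flagged(self, background):
        _, counts, nxw = background
        factors = size_factors(counts)
        eig = build_eigengene(counts.subset_genes(nxw), factors)
        pheno = pd.Series(1.0, index=eig.scores.index)
        assoc = eigengene_assoc(eig, pheno, counts, n_perm=50, seed=1,
                                factors=factors)
        assert not assoc.significant
        assert assoc.reason == "constant phenotype"

    def test_driving_gene_set_detected(self, background):
        design, counts, nxw = background
        factors = size_factors(counts)
        eig = build_eigengene(counts.subset_genes(nxw), factors)
        pheno = np.log2(simulate_phenotypes(
            design, {"intercept": 1.0, "NxW": 0.5}, noise_sd=0.1,
            seed=13).trait("shoot_biomass"))
        assoc = eigengene_assoc(eig, pheno, counts, n_perm=300, seed=2,
                                factors=factors)
        assert assoc.significant and assoc.abs_r > 0.8


class TestNormalizeUnitInterval:
    def test_simple_example(self):
        expr = pd.DataFrame([[2.0, 4.0, 6.0]], index=["g"])
        out, flags = normalize_unit_interval(expr)
        assert np.allclose(out.loc["g"], [0.0, 0.5, 1.0])
        assert not flags["g"]

    def test_maximum_maps_to_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 8)))
        out, _ = normalize_unit_interval(expr)
        assert np.allclose(out.max(axis=1), 1.0)
        assert np.allclose(out.min(axis=1), 0.0)

    def test_affine_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 6)))
        out1, _ = normalize_unit_interval(expr)
        out2, _ = normalize_unit_interval(3.5 * expr + 11.0)
        assert np.allclose(out1, out2)

    def test_constant_gene_zeroed_and_flagged(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                            index=["flat", "ok"])
        out, flags = normalize_unit_interval(expr)
        assert np.allclose(out.loc["flat"], 0.0)
        assert flags["flat"] and not flags["ok"]
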