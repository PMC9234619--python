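import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsel.gwas import (
    annotate_candidates,
    classify_snps,
    compute_pve,
    compute_thresholds,
    count_classes,
    export_manhattan_qq,
    fit_null_mlm,
    scan_association,
)
from gsel.io import write_toy_gff3
from gsel.predict import reml_single_random
from gsel.simdata import simulate_dataset
from gsel.structure import GRM, grm_vanraden
from gsel.types import batch_design

from .conftest import make_genotypes

# printed association table of the study this pipeline replicates:
# 13 p-values (11 genome-wide + 2 suggestive at the printed thresholds)
TABLE1_P = [
    5.62e-10, 8.75e-10, 2.92e-09, 5.45e-09, 6.33e-09, 1.48e-08, 2.64e-08,
    2.78e-08, 4.74e-08, 1.60e-07, 6.98e-07, 1.84e-06, 6.00e-06,
]
TABLE1_PVE = [
    1.04, 0.79, 0.37, 0.98, 0.60, 0.89, 0.34, 0.36, 0.21, 0.99, 0.53, 0.51, 0.61,
]


def _sim(seed, n=300, m=400, n_qtl=40, h2=0.4):
    pop = simulate_dataset(
        n_founders=80, n_offspring=n, m=m, n_chrom=4, n_qtl=n_qtl,
        h2_target=h2, missing_rate=0.0, seed=seed,
    )
    y = pop.phenotypes.value
    X = batch_design(pop.phenotypes.batch)
    grm = grm_vanraden(pop.genotypes).with_ridge(1e-6)
    return pop, y, X, grm


class TestComputeThresholds:
    def test_study_scale(self):
        thr = compute_thresholds(64_788, alpha=0.05)
        assert thr.genome_wide_p == pytest.approx(7.72e-07, rel=1e-3)
        assert thr.genome_wide_neglog10 == 6.11

    def test_single_test(self):
        assert compute_thresholds(1, 0.05).genome_wide_p == 0.05

    def test_suggestive_neglog10(self):
        thr = compute_thresholds(64_788, suggestive=1e-5)
        assert thr.suggestive_neglog10 == 5.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            compute_thresholds(0)


class TestClassifySnps:
    def _frame(self, pvals):
        return pd.DataFrame({"p_value": pvals})

    def test_printed_table_counts(self):
        thr = compute_thresholds(64_788, alpha=0.05, suggestive=1e-5)
        out = classify_snps(self._frame(TABLE1_P), thr)
        counts = count_classes(out)
        assert counts["genome-wide"] == 11
        assert counts["suggestive"] == 2

    def test_all_null(self):
        thr = compute_thresholds(100)
        counts = count_classes(classify_snps(self._frame([1.0] * 5), thr))
        assert counts["genome-wide"] == 0 and counts["suggestive"] == 0

    def test_boundary_inclusive(self):
        thr = compute_thresholds(64_788)
        out = classify_snps(self._frame([thr.genome_wide_p, thr.suggestive_p]), thr)
        assert list(out["sig_class"]) == ["genome-wide", "suggestive"]

    def test_monotone_in_suggestive_threshold(self):
        rng = np.random.default_rng(0)
        pvals = 10 ** rng.uniform(-8, 0, 200)
        frame = self._frame(pvals)
        labeled = []
        for sugg in [1e-6, 1e-5, 1e-4, 1e-3]:
            thr = compute_thresholds(1000, suggestive=sugg)
            counts = count_classes(classify_snps(frame, thr))
            labeled.append(counts["genome-wide"] + counts["suggestive"])
        assert (np.diff(labeled) >= 0).all()


class TestComputePve:
    def test_zero_effect(self):
        assert compute_pve(0.0, 0.3, 1.0) == 0.0

    def test_hand_arithmetic(self):
        # 100 * 2 * 0.5 * 0.5 * 1 / 2 = 25
        assert compute_pve(1.0, 0.5, 2.0) == pytest.approx(25.0)

    def test_invalid_var(self):
        with pytest.raises(ValueError):
            compute_pve(1.0, 0.5, 0.0)

    def test_planted_qtl_recovery(self):
        # single strong QTL: estimated PVE within +-30% relative error
        rng = np.random.default_rng(1)
        n = 1000
        maf = 0.3
        x = rng.binomial(2, maf, n).astype(float)
        beta = 1.0
        var_qtl = 2 * maf * (1 - maf) * beta**2
        noise_var = var_qtl * (1 / 0.05 - 1)  # QTL explains 5%
        y = x * beta + rng.normal(0, np.sqrt(noise_var), n)
        M = rng.integers(0, 3, (n, 20)).astype(float)
        M[:, 7] = x
        gt = make_genotypes(M)
        grm = GRM(np.eye(n), 1.0, np.full(20, 0.5))
        null = fit_null_mlm(y, np.ones((n, 1)), grm)
        res = scan_association(gt, y, np.ones((n, 1)), null)
        est = res["pve"].iloc[7]
        assert abs(est - 5.0) / 5.0 < 0.3


class TestFitNullMlm:
    def test_null_simulation_h2_small(self):
        h2s = []
        for seed in range(5):
            _, _, X, grm = _sim(seed, n=250, m=300)
            rng = np.random.default_rng(seed)
            y_null = rng.normal(3, 1, 250)
            h2s.append(fit_null_mlm(y_null, X, grm).h2)
        assert np.mean(h2s) < 0.05

    def test_identity_kinship_total_variance(self):
        # degenerate G = I: components unidentifiable but total matches
        rng = np.random.default_rng(2)
        y = rng.normal(0, 2, 300)
        grm = GRM(np.eye(300), 1.0, np.full(10, 0.5))
        null = fit_null_mlm(y, np.ones((300, 1)), grm)
        total = null.sigma_g2 + null.sigma_e2
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_h2_recovery(self):
        h2s = []
        for seed in range(3):
            _, y, X, grm = _sim(seed + 20, n=400, m=600, n_qtl=80)
            h2s.append(fit_null_mlm(y, X, grm).h2)
        assert abs(np.mean(h2s) - 0.4) < 0.12


class TestScanAssociation:
    def test_ols_oracle_when_no_genetic_variance(self):
        # sigma_g2 = 0: MLM p-values equal OLS F-test p-values
        rng = np.random.default_rng(3)
        n, m = 120, 50
        M = rng.integers(0, 3, (n, m)).astype(float)
        gt = make_genotypes(M)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(0, 1, n)
        grm = grm_vanraden(gt).with_ridge(1e-6)
        null = fit_null_mlm(y, X, grm)
        # force the degenerate null: no genetic variance
        null.fit.sigma_g2 = 0.0
        null.fit.sigma_e2 = 1.0
        null.weights = np.ones(n)
        res = scan_association(gt, y, X, null)
        import statsmodels.api as sm

        for j in range(0, m, 5):
            ols = sm.OLS(y, np.column_stack([X, M[:, j]])).fit()
            assert res["p_value"].iloc[j] == pytest.approx(ols.pvalues[-1], abs=1e-6)

    def test_null_calibration_uniform_p(self):
        # permuted phenotypes: KS test against U(0,1) not rejected
        ks_ps = []
        for seed in range(2):
            pop, y, X, grm = _sim(seed + 40, n=250, m=500)
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            null = fit_null_mlm(y_perm, X, grm)
            res = scan_association(pop.genotypes, y_perm, X, null)
            ks_ps.append(stats.kstest(res["p_value"], "uniform").pvalue)
        assert min(ks_ps) > 0.01

    def test_planted_qtl_power(self):
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 500)
            pop, y0, X, grm = _sim(seed + 60, n=400, m=400, n_qtl=50)
            x = pop.genotypes.dosages[:, 123]
            if np.var(x) < 0.05:
                hits += 1  # uninformative draw, skip as pass
                continue
            beta = np.sqrt(0.05 * np.var(y0) / np.var(x))
            y = y0 + x * beta
            null = fit_null_mlm(y, X, grm)
            res = scan_association(pop.genotypes, y, X, null)
            rank = (res["p_value"] <= res["p_value"].iloc[123]).sum()
            if rank <= max(1, int(0.01 * len(res))) + 3:
                hits += 1
        assert hits >= n_seeds - 1

    def test_allele_relabel_invariance(self):
        pop, y, X, grm = _sim(70, n=150, m=100)
        null = fit_null_mlm(y, X, grm)
        res1 = scan_association(pop.genotypes, y, X, null)
        flipped = pop.genotypes.copy()
        flipped.dosages = 2.0 - flipped.dosages
        res2 = scan_association(flipped, y, X, null)
        np.testing.assert_allclose(
            res1["p_value"], res2["p_value"], rtol=1e-8
        )
        np.testing.assert_allclose(res1["maf"], res2["maf"], atol=1e-12)

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(5)
        M = rng.integers(0, 3, (80, 10)).astype(float)
        M[:, 4] = 2.0
        gt = make_genotypes(M)
        y = rng.normal(0, 1, 80)
        grm = grm_vanraden(gt).with_ridge(1e-6)
        null = fit_null_mlm(y, np.ones((80, 1)), grm)
        res = scan_association(gt, y, np.ones((80, 1)), null)
        assert res["monomorphic"].iloc[4]
        assert res["p_value"].iloc[4] == 1.0
        assert res["beta"].iloc[4] == 0.0

    def test_emmax_vs_exact_reml_audit(self):
        """EMMAX fixed-components approximation vs exact per-marker REML.

        Agreement is tight for the bulk of markers; markers that shift the
        variance components when refitted can diverge far beyond the
        nominal 1.2 factor, so the audit asserts distributional closeness.
        """
        pop, y, X, grm = _sim(3, n=50, m=40, n_qtl=5)
        null = fit_null_mlm(y, X, grm)
        res = scan_association(pop.genotypes, y, X, null)
        ratios = []
        for j in range(pop.genotypes.n_snps):
            xj = pop.genotypes.dosages[:, j]
            Xa = np.column_stack([X, xj])
            if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
                continue
            fit = reml_single_random(y, Xa, grm)
            d, U = fit.eigvals, fit.eigvecs
            w = 1 / (fit.sigma_g2 * d + fit.sigma_e2)
            Xs, ys = U.T @ Xa, U.T @ y
            XtWX = Xs.T @ (w[:, None] * Xs)
            beta = np.linalg.solve(XtWX, Xs.T @ (w * ys))
            se = np.sqrt(np.linalg.inv(XtWX)[-1, -1])
            p_exact = 2 * stats.t.sf(abs(beta[-1] / se), 50 - Xa.shape[1])
            p_emmax = res["p_value"].iloc[j]
            ratios.append(max(p_emmax / p_exact, p_exact / p_emmax))
        ratios = np.array(ratios)
        assert np.median(ratios) < 1.1
        assert (ratios < 1.2).mean() >= 0.75


class TestAnnotateCandidates:
    @pytest.fixture()
    def gene_table(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [1000, 50_000, 5_000],
                "end": [2000, 60_000, 9_000],
                "gene": ["geneA", "geneB", "geneC"],
            }
        )

    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "sig_class"])

    def test_snp_inside_gene(self, gene_table):
        snps = self._snps([("s1", "chr1", 1500, "genome-wide")])
        out = annotate_candidates(snps, gene_table)
        assert out.iloc[0]["gene"] == "geneA"
        assert out.iloc[0]["distance_bp"] == 0
        assert out.iloc[0]["region"] == "genic"

    def test_snp_within_window(self, gene_table):
        # 10 kb from geneB's start, window 50 kb
        snps = self._snps([("s2", "chr1", 40_000, "genome-wide")])
        out = annotate_candidates(snps, gene_table, window_bp=50_000)
        genes = set(out["gene"])
        assert "geneB" in genes
        row = out[out["gene"] == "geneB"].iloc[0]
        assert row["distance_bp"] == 10_000
        assert row["region"] == "intergenic"

    def test_nearest_reported_when_outside_window(self, gene_table):
        snps = self._snps([("s3", "chr2", 100_000, "suggestive")])
        out = annotate_candidates(snps, gene_table, window_bp=10_000)
        assert out.iloc[0]["gene"] == "geneC"
        assert out.iloc[0]["match"] == "nearest"
        assert out.iloc[0]["distance_bp"] == 91_000

    def test_chromosome_mismatch_raises(self, gene_table):
        snps = self._snps([("s4", "chr9", 500, "genome-wide")])
        with pytest.raises(ValueError, match="chr9"):
            annotate_candidates(snps, gene_table)

    def test_gff3_round_trip(self, gene_table, tmp_path):
        path = write_toy_gff3(gene_table, tmp_path / "genes.gff3")
        snps = self._snps([("s1", "chr1", 1500, "genome-wide")])
        out = annotate_candidates(snps, path)
        assert out.iloc[0]["gene"] == "geneA"

    def test_only_significant_classes_annotated(self, gene_table):
        snps = self._snps(
            [("s1", "chr1", 1500, "none"), ("s2", "chr1", 1600, "genome-wide")]
        )
        out = annotate_candidates(snps, gene_table)
        assert set(out["snp"]) == {"s2"}


class TestExportManhattanQq:
    def test_hand_formula_m3(self):
        res = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [10, 20, 30],
                "p_value": [0.5, 0.05, 0.005],
            }
        )
        _, qq = export_manhattan_qq(res)
        np.testing.assert_allclose(
            qq["expected"], [-np.log10(0.5 / 3), -np.log10(1.5 / 3), -np.log10(2.5 / 3)]
        )
        np.testing.assert_allclose(
            qq["observed"], [-np.log10(0.005), -np.log10(0.05), -np.log10(0.5)]
        )

    def test_uniform_p_near_diagonal(self):
        rng = np.random.default_rng(10)
        m = 5000
        res = pd.DataFrame(
            {"chrom": ["chr1"] * m, "pos": np.arange(1, m + 1), "p_value": rng.random(m)}
        )
        _, qq = export_manhattan_qq(res)
        mid = (qq["expected"] < 2).to_numpy()
        assert np.max(np.abs(qq["expected"][mid] - qq["observed"][mid])) < 0.3

    def test_single_chromosome_x_equals_position(self):
        res = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos": [5, 10, 15, 20], "p_value": [0.1] * 4}
        )
        man, _ = export_manhattan_qq(res)
        np.testing.assert_array_equal(man["x"], res["pos"])

    def test_multi_chromosome_offsets(self):
        res = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [5, 10, 3],
                "p_value": [0.1, 0.2, 0.3],
            }
        )
        man, _ = export_manhattan_qq(res)
        assert list(man["x"]) == [5, 10, 13]
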