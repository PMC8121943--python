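"""Tissue specificity, SNP annotation, LD-corrected regression, eQTL QQ."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tgca import (
    InsufficientVariationError,
    MixtureFit,
    MixtureParams,
    SnpAnnotation,
    TGCAResult,
    TissueExpression,
    annotate_snps,
    bed_to_intervals,
    eqtl_chisq_qq,
    eqtl_lead_variants,
    export_for_sldsc,
    ld_corrected_regression,
    method_agreement,
    specificity_scores,
    top_specific_genes,
)


def _expr(tpm, genes=None, tissues=None):
    tpm = np.asarray(tpm, dtype=float)
    n, t = tpm.shape
    return TissueExpression(
        genes=np.array(genes or [f"g{i}" for i in range(n)], dtype=object),
        tissues=np.array(tissues or [f"t{j}" for j in range(t)], dtype=object),
        tpm=tpm,
    )


def _result(snp, theta, se, converged=True, chrom="1", pos=1):
    p = MixtureParams(0.1, 0.8, 0.1, -1.0, 1.0, 1.0, 1.0)
    z = theta / se if se and np.isfinite(se) else np.nan
    pval = stats.chi2.sf(z**2, 1) if np.isfinite(z) else np.nan
    return TGCAResult(snp, theta, se, z, pval,
                      MixtureFit(p, -1.0, 5, converged), chrom=chrom, pos=pos)


class TestSpecificity:
    def test_single_tissue_gene(self):
        t = specificity_scores(_expr([[0, 0, 7, 0]]))
        np.testing.assert_allclose(t.specificity[0], [0, 0, 1, 0])

    def test_uniform_gene(self):
        t = specificity_scores(_expr([np.ones(48)]))
        np.testing.assert_allclose(t.specificity[0], 1 / 48)

    def test_zero_gene_excluded(self):
        t = specificity_scores(_expr([[0, 0], [1, 1]]))
        assert np.isnan(t.specificity[0]).all()
        sel = top_specific_genes(t, "t0", fraction=1.0)
        assert list(sel) == ["g1"]

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            specificity_scores(_expr([[-1.0, 2.0]]))

    def test_rows_sum_to_one(self, rng):
        t = specificity_scores(_expr(rng.uniform(0.1, 5.0, size=(30, 8))))
        np.testing.assert_allclose(t.specificity.sum(axis=1), 1.0, atol=1e-12)


class TestTopGenes:
    def test_count_contract(self, rng):
        t = _expr(rng.uniform(0.1, 5.0, size=(1000, 5)))
        assert len(top_specific_genes(t, "t2", fraction=0.10)) == 100

    def test_fraction_one_returns_all_valid(self, rng):
        t = _expr(rng.uniform(0.1, 5.0, size=(20, 3)))
        assert len(top_specific_genes(t, "t0", fraction=1.0)) == 20

    def test_tie_broken_by_gene_identifier(self):
        t = _expr([[1, 1], [1, 1], [4, 1]], genes=["gB", "gA", "gC"])
        sel = top_specific_genes(t, "t0", fraction=0.5)  # ceil(1.5) = 2 genes
        # gC is most specific; gA beats gB on the id tie-break
        assert list(sel) == ["gC", "gA"]

    def test_unknown_tissue_rejected(self):
        t = _expr([[1, 2]])
        with pytest.raises(ValueError, match="tissue"):
            top_specific_genes(t, "no-such-tissue")


class TestAnnotateSnps:
    GENES = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "start": [100, 500, 100],
            "end": [200, 600, 200],
            "gene_id": ["gA", "gB", "gC"],
        }
    )

    def test_inclusive_boundaries(self):
        A = annotate_snps(["1", "1", "1"], [100, 200, 201], self.GENES, ["gA"])
        np.testing.assert_array_equal(A, [1, 1, 0])

    def test_window_extension(self):
        A = annotate_snps(["1"], [95_000], pd.DataFrame(
            {"chrom": ["1"], "start": [100_000], "end": [110_000],
             "gene_id": ["g"]}), ["g"], window_bp=10_000)
        assert A[0] == 1

    def test_chromosome_must_match(self):
        A = annotate_snps(["2", "1"], [150, 150], self.GENES, ["gA", "gC"])
        np.testing.assert_array_equal(A, [1, 1])

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame(
            {"chrom": ["1"], "start": [200], "end": [100], "gene_id": ["g"]}
        )
        with pytest.raises(ValueError, match="interval"):
            annotate_snps(["1"], [150], bad, ["g"])

    def test_agrees_with_bruteforce_oracle(self, rng):
        n_genes, n_snps = 40, 1000
        starts = rng.integers(1, 10**6, n_genes)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], n_genes),
                "start": starts,
                "end": starts + rng.integers(100, 50_000, n_genes),
                "gene_id": [f"g{i}" for i in range(n_genes)],
            }
        )
        chrom = rng.choice(["1", "2"], n_snps)
        pos = rng.integers(1, 1_100_000, n_snps)
        gene_set = [f"g{i}" for i in range(0, n_genes, 3)]
        A = annotate_snps(chrom, pos, genes, gene_set)
        sel = genes[genes.gene_id.isin(gene_set)]
        for i in range(n_snps):
            hit = bool(
                ((sel.chrom == chrom[i]) & (sel.start <= pos[i])
                 & (pos[i] <= sel.end)).any()
            )
            assert bool(A[i]) == hit

    def test_bed_conversion(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t99\t200\tgA\n")
        onebased = bed_to_intervals(path, zero_based=True)
        assert onebased.loc[0, "start"] == 100
        assert onebased.loc[0, "end"] == 200


class TestLdCorrectedRegression:
    def test_exact_linear_recovery(self, rng):
        n = 5000
        ld = rng.uniform(1, 50, n)
        A = (rng.random(n) < 0.2).astype(float)
        theta = 0.1 + 0.05 * ld + 0.5 * A
        fit = ld_corrected_regression(theta, SnpAnnotation(A=A, ld_score=ld))
        assert fit.gamma_median == pytest.approx(0.5, abs=1e-8)
        np.testing.assert_allclose(fit.gamma_all, 0.5, atol=1e-8)
        np.testing.assert_allclose(fit.delta, 0.05, atol=1e-8)

    def test_null_annotation_gives_gamma_near_zero(self, rng):
        n = 10_000
        ld = rng.uniform(1, 50, n)
        A = (rng.random(n) < 0.1).astype(float)
        theta = 0.1 + 0.02 * ld + rng.normal(0, 0.3, n)
        fit = ld_corrected_regression(theta, SnpAnnotation(A=A, ld_score=ld))
        assert abs(fit.gamma_median) < 2 * fit.gamma_all.std()

    def test_constant_annotation_rejected(self, rng):
        n = 2000
        with pytest.raises(InsufficientVariationError):
            ld_corrected_regression(
                rng.normal(size=n),
                SnpAnnotation(A=np.zeros(n), ld_score=np.ones(n)),
            )

    def test_subsets_interleave_positionally(self, rng):
        # gamma differs between odd and even positions; with 2 interleaved
        # subsets the two estimates recover the two planted values separately
        n = 400
        ld = np.zeros(n)
        A = np.tile([1.0, 0.0, 0.0, 1.0], n // 4)  # varies within each parity
        theta = np.where(np.arange(n) % 2 == 0, 1.0 * A, 2.0 * A)
        fit = ld_corrected_regression(theta, SnpAnnotation(A=A, ld_score=ld),
                                      n_subsets=2)
        assert sorted(np.round(fit.gamma_all, 6).tolist()) == [1.0, 2.0]

    def test_median_of_subset_estimates(self, rng):
        n = 3000
        ld = rng.uniform(1, 10, n)
        A = (rng.random(n) < 0.3).astype(float)
        theta = 0.3 * A + rng.normal(0, 0.1, n)
        fit = ld_corrected_regression(theta, SnpAnnotation(A=A, ld_score=ld),
                                      n_subsets=20)
        assert fit.gamma_median == pytest.approx(np.median(fit.gamma_all))


class TestMethodAgreement:
    def test_identical_rankings(self):
        a = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        rho, p = method_agreement(a, a * 10)
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        a = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        b = pd.Series([5, 4, 3, 2, 1], index=list("abcde"))
        rho, _ = method_agreement(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_tissues_rejected(self):
        a = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            method_agreement(a, a)

    def test_mismatched_tissue_sets_rejected(self):
        a = pd.Series(range(5), index=list("abcde"))
        b = pd.Series(range(5), index=list("abcdf"))
        with pytest.raises(ValueError):
            method_agreement(a, b)

    def test_kendall_available(self):
        a = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        rho, _ = method_agreement(a, a, method="kendall")
        assert rho == pytest.approx(1.0)


class TestEqtlLeads:
    TABLE = pd.DataFrame(
        {
            "gene": ["g1", "g1", "g1", "g2", "g2"],
            "snp": ["s1", "s2", "s3", "s4", "s5"],
            "pos": [10, 20, 30, 40, 50],
            "p": [0.2, 0.001, 0.5, 0.9, 0.3],
        }
    )

    def test_argmin_per_gene(self):
        leads = eqtl_lead_variants(self.TABLE, ["s1", "s2", "s3", "s4", "s5"])
        assert dict(zip(leads.gene, leads.snp)) == {"g1": "s2", "g2": "s5"}

    def test_restriction_before_argmin(self):
        leads = eqtl_lead_variants(self.TABLE, ["s1", "s3", "s4", "s5"])
        assert dict(zip(leads.gene, leads.snp))["g1"] == "s1"

    def test_p_tie_broken_by_position(self):
        t = pd.DataFrame(
            {"gene": ["g", "g"], "snp": ["sB", "sA"], "pos": [200, 100],
             "p": [0.01, 0.01]}
        )
        leads = eqtl_lead_variants(t, ["sA", "sB"])
        assert leads.snp.iloc[0] == "sA"

    def test_gene_without_tested_snps_skipped(self):
        leads = eqtl_lead_variants(self.TABLE, ["s4"])
        assert set(leads.gene) == {"g2"}

    def test_duplicate_gene_snp_keeps_smallest_p(self):
        t = pd.DataFrame(
            {"gene": ["g", "g"], "snp": ["s", "s"], "pos": [5, 5],
             "p": [0.5, 0.001]}
        )
        leads = eqtl_lead_variants(t, ["s"])
        assert leads.p.iloc[0] == 0.001


class TestChisqQQ:
    def test_squaring(self):
        results = [_result("s0", 1.0, 0.5)]
        qq = eqtl_chisq_qq(results, ["s0"])
        assert qq.chisq_observed.iloc[0] == pytest.approx(4.0)

    def test_null_matches_chi2_distribution(self, rng):
        results = [
            _result(f"s{i}", abs(rng.normal()) * 0.2, 0.2) for i in range(1000)
        ]
        qq = eqtl_chisq_qq(results, [f"s{i}" for i in range(1000)])
        slope = np.polyfit(qq.chisq_expected, qq.chisq_observed, 1)[0]
        assert 0.9 < slope < 1.1

    def test_planted_signal_lifts_upper_tail(self, rng):
        null = [_result(f"n{i}", abs(rng.normal()) * 0.2, 0.2) for i in range(500)]
        strong = [_result(f"h{i}", 2.0 + 0.1 * i, 0.2) for i in range(20)]
        qq = eqtl_chisq_qq(null + strong, [r.snp_id for r in null + strong])
        top = qq.tail(20)
        assert (top.chisq_observed > top.chisq_expected).all()

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            eqtl_chisq_qq([_result("s0", 1.0, 0.5)], ["other"])


class TestExportSldsc:
    def test_format_and_round_trip(self, tmp_path):
        results = [_result(f"s{i}", 0.5 + i / 7, 0.1) for i in range(100)]
        path = tmp_path / "ldsc_in.tsv"
        n = export_for_sldsc(results, path, n_eff=361_194)
        assert n == 100
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["SNP", "Z", "N", "A1", "A2"]
        for r, z in zip(results, df["Z"]):
            assert z == pytest.approx(r.z_theta, rel=1e-5)

    def test_rows_without_se_excluded(self, tmp_path):
        results = [_result("a", 1.0, 0.1), _result("b", 1.0, np.nan)]
        path = tmp_path / "out.tsv"
        assert export_for_sldsc(results, path) == 1
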