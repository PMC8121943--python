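"""Tissue-specificity scoring and enrichment of theta signals.

Downstream of the per-SNP theta estimates, three analyses connect the total
genetic contribution to tissue biology:

* an LD-corrected regression of theta-hat on a binary tissue annotation,
  theta_j = alpha + delta * ldscore_j + gamma * A_j + eps_j, estimated on
  100 interleaved positional subsets (SNPs j, j+100, j+200, ...) so that LD
  between neighbouring SNPs is pruned; the median of the per-subset gamma
  estimates is reported;
* a rank-based (Spearman) agreement between two per-tissue score vectors,
  used to triangulate enrichment methods;
* a chi-square(1) QQ comparison of (theta/se)^2 at cis-eQTL lead variants of
  tissue-specific genes.

Gene expression input is a gene x tissue TPM matrix; specificity of a gene
in a tissue is its TPM divided by the gene's summed TPM over all tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

N_SUBSETS = 100
TOP_FRACTION = 0.10


class InsufficientVariationError(ValueError):
    """Too few subsets with both annotation levels to estimate gamma."""


@dataclass
class TissueExpression:
    """Gene x tissue TPM matrix with derived specificity proportions."""

    genes: np.ndarray
    tissues: np.ndarray
    tpm: np.ndarray
    specificity: Optional[np.ndarray] = None

    @classmethod
    def from_tsv(cls, path) -> "TissueExpression":
        """First column gene id, remaining columns per-tissue TPM."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            genes=df.iloc[:, 0].to_numpy(dtype=object),
            tissues=df.columns[1:].to_numpy(dtype=object),
            tpm=df.iloc[:, 1:].to_numpy(dtype=float),
        )


@dataclass
class SnpAnnotation:
    """Binary annotation vector and LD scores for a SNP list."""

    A: np.ndarray
    ld_score: np.ndarray
    tissue: str = ""


@dataclass
class EnrichmentFit:
    """Median-of-subsets gamma with the per-subset estimates."""

    gamma_median: float
    gamma_all: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    tissue: str = ""
    domain: str = ""
    n_subsets_used: int = 0


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------


def specificity_scores(t: TissueExpression) -> TissueExpression:
    """Row-normalise TPM to per-gene tissue proportions in [0, 1].

    Genes with zero total expression get NaN specificity and are excluded
    from downstream top-decile selection.
    """
    if np.any(t.tpm < 0):
        raise ValueError("TPM values must be non-negative")
    total = t.tpm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(total > 0, t.tpm / total, np.nan)
    n_zero = int((total.ravel() == 0).sum())
    if n_zero:
        logger.info("specificity_scores: %d all-zero genes excluded", n_zero)
    t.specificity = spec
    return t


def top_specific_genes(
    t: TissueExpression, tissue: str, fraction: float = TOP_FRACTION
) -> np.ndarray:
    """The ceil(fraction * n_valid) most tissue-specific genes, ranked by
    specificity in ``tissue``; ties at the cut resolved by gene identifier."""
    if t.specificity is None:
        specificity_scores(t)
    hits = np.nonzero(t.tissues == tissue)[0]
    if hits.size != 1:
        raise ValueError(f"unknown tissue {tissue!r}")
    col = t.specificity[:, hits[0]]
    valid = np.isfinite(col)
    order = sorted(
        np.nonzero(valid)[0], key=lambda i: (-col[i], str(t.genes[i]))
    )
    n_top = int(np.ceil(fraction * valid.sum()))
    return np.array([t.genes[i] for i in order[:n_top]], dtype=object)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_snps(
    chrom: Sequence,
    pos: Sequence[int],
    gene_table: pd.DataFrame,
    gene_set: Sequence,
    window_bp: int = 0,
) -> np.ndarray:
    """Binary indicator per SNP: inside any gene of ``gene_set`` (intervals
    1-based inclusive) extended by ``window_bp`` on both sides.

    ``gene_table`` columns: chrom, start, end, gene_id.
    """
    gset = set(map(str, gene_set))
    sel = gene_table[gene_table["gene_id"].astype(str).isin(gset)]
    if (sel["end"] < sel["start"]).any():
        raise ValueError("malformed gene interval: end < start")
    trees: dict[str, IntervalTree] = {}
    for _, row in sel.iterrows():
        lo = int(row["start"]) - window_bp
        hi = int(row["end"]) + window_bp
        # IntervalTree is half-open; +1 makes [lo, hi] inclusive
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(lo, hi + 1)
    A = np.zeros(len(pos), dtype=int)
    for i, (c, p) in enumerate(zip(chrom, pos)):
        tree = trees.get(str(c))
        if tree is not None and tree.overlaps_point(int(p)):
            A[i] = 1
    return A


def bed_to_intervals(path, zero_based: bool = False) -> pd.DataFrame:
    """Read a BED-like gene-interval table (chrom, start, end, gene_id).

    The native convention is 1-based inclusive; ``zero_based=True`` accepts
    0-based half-open BED and converts.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        comment="#",
    )
    if zero_based:
        df["start"] = df["start"] + 1
    return df


# ---------------------------------------------------------------------------
# LD-corrected regression (interleaved subsets)
# ---------------------------------------------------------------------------


def ld_corrected_regression(
    theta_hat: np.ndarray,
    ann: SnpAnnotation,
    n_subsets: int = N_SUBSETS,
    tissue: str = "",
    domain: str = "",
) -> EnrichmentFit:
    """OLS of theta-hat on (1, ldscore, A) within each interleaved subset.

    ``theta_hat`` must be ordered by genomic position: subset s contains
    SNPs s, s + n_subsets, s + 2*n_subsets, ..., so that neighbouring (LD-
    correlated) SNPs land in different subsets. Subsets where A is constant
    are excluded from the median.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    A = np.asarray(ann.A, dtype=float)
    ld = np.asarray(ann.ld_score, dtype=float)
    if not (len(theta_hat) == len(A) == len(ld)):
        raise ValueError("theta_hat, A and ld_score must have equal length")
    if A.min() == A.max():
        raise InsufficientVariationError("annotation is constant over all SNPs")
    gammas, alphas, deltas = [], [], []
    for s in range(n_subsets):
        idx = np.arange(s, len(theta_hat), n_subsets)
        if len(idx) < 4 or A[idx].min() == A[idx].max():
            continue
        X = sm.add_constant(np.column_stack([ld[idx], A[idx]]))
        res = sm.OLS(theta_hat[idx], X).fit()
        alphas.append(res.params[0])
        deltas.append(res.params[1])
        gammas.append(res.params[2])
    needed = min(10, n_subsets)
    if len(gammas) < needed:
        raise InsufficientVariationError(
            f"only {len(gammas)} subsets with annotation variation "
            f"(need >= {needed})"
        )
    gammas = np.array(gammas)
    return EnrichmentFit(
        gamma_median=float(np.median(gammas)),
        gamma_all=gammas,
        alpha=np.array(alphas),
        delta=np.array(deltas),
        tissue=tissue,
        domain=domain,
        n_subsets_used=len(gammas),
    )


def method_agreement(
    scores_a: pd.Series, scores_b: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Rank correlation across tissues between two enrichment methods.

    Returns (rho, two-sided p). Ties receive average ranks. Kendall's tau is
    available behind the ``method`` flag.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("the two score vectors must cover the same tissues")
    if len(scores_a) < 5:
        raise ValueError("need at least 5 tissues")
    b = scores_b.reindex(scores_a.index)
    if method == "spearman":
        rho, p = stats.spearmanr(scores_a.to_numpy(), b.to_numpy())
    elif method == "kendall":
        rho, p = stats.kendalltau(scores_a.to_numpy(), b.to_numpy())
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# cis-eQTL lead variants and chi-square QQ
# ---------------------------------------------------------------------------


def eqtl_lead_variants(
    eqtl_table: pd.DataFrame, tested_snps: Sequence
) -> pd.DataFrame:
    """One lead (smallest-p) cis-SNP per gene, restricted to SNPs that were
    also tested by the theta analysis.

    ``eqtl_table`` columns: gene, snp, pos, p (duplicate (gene, snp) rows keep
    the smallest p; ties at the minimum resolved by smaller position).
    """
    tested = set(map(str, tested_snps))
    df = eqtl_table.copy()
    df["snp"] = df["snp"].astype(str)
    df = df[df["snp"].isin(tested)]
    skipped = set(eqtl_table["gene"]) - set(df["gene"])
    if skipped:
        logger.info("eqtl_lead_variants: %d genes with no tested cis-SNP skipped",
                    len(skipped))
    if df.empty:
        return df.assign(lead=True).iloc[0:0]
    df = (
        df.sort_values(["gene", "p", "pos"], kind="mergesort")
        .drop_duplicates(["gene", "snp"], keep="first")
        .drop_duplicates("gene", keep="first")
        .reset_index(drop=True)
    )
    return df


def eqtl_chisq_qq(results, lead_snps: Sequence) -> pd.DataFrame:
    """Observed (theta/se)^2 at the lead SNPs against chi-square(1) quantiles.

    Returns a table of (snp, chisq_observed, chisq_expected) with observed
    values sorted ascending and expected quantiles at (i - 0.5)/n.
    """
    lead = set(map(str, lead_snps))
    sel = [
        r for r in results
        if r.snp_id in lead and r.fit.converged and np.isfinite(r.se_theta)
        and r.se_theta > 0
    ]
    if not sel:
        raise ValueError("no lead SNPs with converged fits and standard errors")
    obs = np.array([(r.theta / r.se_theta) ** 2 for r in sel])
    order = np.argsort(obs)
    n = len(obs)
    expected = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
    return pd.DataFrame(
        {
            "snp": [sel[i].snp_id for i in order],
            "chisq_observed": obs[order],
            "chisq_expected": expected,
        }
    )


# ---------------------------------------------------------------------------
# S-LDSC export
# ---------------------------------------------------------------------------


def export_for_sldsc(results, path, n_eff: Optional[int] = None) -> int:
    """Write a munge-compatible association table (SNP, Z, N, A1, A2) of the
    theta Z-scores for the external S-LDSC toolchain. Rows without a usable
    standard error are excluded (and counted in the log). Returns the number
    of rows written."""
    rows = []
    n_skipped = 0
    for r in results:
        if not np.isfinite(r.z_theta):
            n_skipped += 1
            continue
        rows.append(
            {
                "SNP": r.snp_id,
                "Z": r.z_theta,
                "N": n_eff if n_eff is not None else 0,
                "A1": "A",
                "A2": "G",
            }
        )
    if n_skipped:
        logger.info("export_for_sldsc: %d rows without SE excluded", n_skipped)
    pd.DataFrame(rows, columns=["SNP", "Z", "N", "A1", "A2"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return len(rows)
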