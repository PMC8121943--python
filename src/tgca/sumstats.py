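"""Reading, validation, QC and standardisation of multi-phenotype GWAS
summary statistics.

Conventions: genomic coordinates are 1-based; files are tab-separated with a
header; alleles are matched order-insensitively across phenotype files, and
the Z-score sign is flipped when the effect allele is swapped relative to the
first file (sign consistency matters because theta separates positive and
negative effect components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default column-name mapping for input summary tables
DEFAULT_COLUMNS = {
    "variant": "variant",
    "chr": "chr",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "beta": "beta",
    "se": "se",
    "z": "z",
    "pval": "pval",
    "n": "n",
    "n_cases": "n_cases",
    "maf": "minor_AF",
}

MIN_NONMISSING = 50_000
MIN_CASES = 1_000
KS_ALPHA = 0.1
MIN_MAF = 0.005


class SumstatsFormatError(ValueError):
    """A required column is missing or malformed in an input file."""


class EmptyInputError(ValueError):
    """No variants (or no phenotypes) survive intersection or filtering."""


@dataclass(frozen=True)
class PhenotypeMeta:
    """Per-phenotype metadata: identity, trait type and sample sizes."""

    phenotype_id: str
    trait_type: str  # "binary", "continuous" or "ordinal"
    n_total: int
    n_cases: Optional[int] = None
    domain_label: Optional[str] = None

    def __post_init__(self):
        if self.trait_type not in ("binary", "continuous", "ordinal"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.trait_type == "binary":
            if self.n_cases is None or not (0 <= self.n_cases <= self.n_total):
                raise ValueError("binary traits need 0 <= n_cases <= n_total")


@dataclass
class SummaryStatSet:
    """SNP x phenotype matrix of GWAS Z-scores with per-SNP metadata."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    Z: np.ndarray
    P: np.ndarray
    pheno: list[PhenotypeMeta]
    standardized: bool = False

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        if self.Z.shape != self.P.shape:
            raise ValueError("Z and P must have identical shape")
        if self.Z.shape != (len(self.snp_ids), len(self.pheno)):
            raise ValueError("Z shape must be (n_snps, n_phenotypes)")
        if len(set(map(str, self.snp_ids))) != len(self.snp_ids):
            raise ValueError("duplicated snp_ids")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_pheno(self) -> int:
        return len(self.pheno)

    @property
    def sample_sizes(self) -> np.ndarray:
        """Effective per-phenotype sample size: case count for binary traits."""
        return np.array(
            [m.n_cases if m.trait_type == "binary" else m.n_total for m in self.pheno],
            dtype=float,
        )

    def subset_snps(self, idx) -> "SummaryStatSet":
        idx = np.asarray(idx)
        return SummaryStatSet(
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            maf=self.maf[idx],
            Z=self.Z[idx],
            P=self.P[idx],
            pheno=list(self.pheno),
            standardized=self.standardized,
        )

    def subset_phenotypes(self, idx) -> "SummaryStatSet":
        idx = np.asarray(idx)
        return SummaryStatSet(
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            maf=self.maf.copy(),
            Z=self.Z[:, idx],
            P=self.P[:, idx],
            pheno=[self.pheno[int(i)] for i in idx],
            standardized=self.standardized,
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_one(path, cols: dict) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={cols["variant"]: str})
    for key in ("variant", "chr", "pos", "pval", "n", "maf"):
        if cols[key] not in df.columns:
            raise SumstatsFormatError(
                f"{path}: required column {cols[key]!r} (for {key!r}) is missing"
            )
    have_z = cols["z"] in df.columns
    have_beta = cols["beta"] in df.columns and cols["se"] in df.columns
    if not have_z and not have_beta:
        raise SumstatsFormatError(
            f"{path}: need either a {cols['z']!r} column or "
            f"{cols['beta']!r}+{cols['se']!r} columns"
        )
    out = pd.DataFrame(
        {
            "variant": df[cols["variant"]].astype(str),
            "chr": df[cols["chr"]].astype(str),
            "pos": df[cols["pos"]].astype(int),
            "pval": df[cols["pval"]].astype(float),
            "maf": df[cols["maf"]].astype(float),
        }
    )
    if have_z:
        out["z"] = df[cols["z"]].astype(float)
    else:
        out["z"] = df[cols["beta"]].astype(float) / df[cols["se"]].astype(float)
    for key in ("ref", "alt"):
        if cols[key] in df.columns:
            out[key] = df[cols[key]].astype(str)
    return out


def read_sumstats(
    paths: Sequence,
    pheno: Sequence[PhenotypeMeta],
    format_spec: Optional[dict] = None,
) -> SummaryStatSet:
    """Read one summary table per phenotype and align them on the variant
    intersection.

    Alleles (when present) are matched order-insensitively against the first
    file; variants whose effect allele is swapped get their Z sign flipped,
    and variants with incompatible allele pairs are dropped with a log entry.
    """
    if len(paths) != len(pheno):
        raise ValueError("one path per phenotype required")
    cols = dict(DEFAULT_COLUMNS)
    if format_spec:
        cols.update(format_spec)
    tables = [_read_one(p, cols) for p in paths]

    common = tables[0]["variant"]
    for t in tables[1:]:
        common = common[common.isin(set(t["variant"]))]
    common = pd.Index(common)  # preserves first-file row order
    if len(common) == 0:
        raise EmptyInputError("zero variants shared across all input files")

    ref = tables[0].drop_duplicates("variant").set_index("variant").loc[common]
    has_alleles = "ref" in ref.columns and "alt" in ref.columns
    Z = np.empty((len(common), len(tables)))
    P = np.empty_like(Z)
    keep = np.ones(len(common), dtype=bool)
    for j, t in enumerate(tables):
        tt = t.drop_duplicates("variant").set_index("variant").loc[common]
        z = tt["z"].to_numpy()
        if has_alleles and "ref" in tt.columns and "alt" in tt.columns:
            same = (tt["ref"].to_numpy() == ref["ref"].to_numpy()) & (
                tt["alt"].to_numpy() == ref["alt"].to_numpy()
            )
            swapped = (tt["ref"].to_numpy() == ref["alt"].to_numpy()) & (
                tt["alt"].to_numpy() == ref["ref"].to_numpy()
            )
            z = np.where(swapped, -z, z)
            bad = ~(same | swapped)
            if bad.any():
                logger.warning(
                    "%s: dropping %d variants with incompatible alleles",
                    paths[j], int(bad.sum()),
                )
                keep &= ~bad
        Z[:, j] = z
        P[:, j] = tt["pval"].to_numpy()
    if not keep.all():
        common = common[keep]
        Z, P, ref = Z[keep], P[keep], ref[keep]
    if len(common) == 0:
        raise EmptyInputError("no variants left after allele harmonisation")
    return SummaryStatSet(
        snp_ids=common.to_numpy(dtype=object),
        chrom=ref["chr"].to_numpy(dtype=object),
        pos=ref["pos"].to_numpy(dtype=int),
        maf=ref["maf"].to_numpy(dtype=float),
        Z=Z,
        P=P,
        pheno=list(pheno),
    )


# ---------------------------------------------------------------------------
# phenotype and SNP QC
# ---------------------------------------------------------------------------


def qc_phenotypes(
    pheno: Sequence[PhenotypeMeta],
    min_nonmissing: int = MIN_NONMISSING,
    min_cases: int = MIN_CASES,
) -> np.ndarray:
    """Indices of phenotypes surviving the sample-size filters.

    Continuous/ordinal traits with fewer than ``min_nonmissing`` non-missing
    samples and binary traits with fewer than ``min_cases`` cases are dropped
    (strict inequalities). Correlation pruning happens later, in phenocorr.
    """
    kept = []
    for i, m in enumerate(pheno):
        if m.trait_type == "binary":
            if m.n_cases is not None and m.n_cases < min_cases:
                continue
        else:
            if m.n_total < min_nonmissing:
                continue
        kept.append(i)
    if not kept:
        raise EmptyInputError("no phenotypes survive the sample-size filters")
    logger.info("qc_phenotypes: kept %d / %d phenotypes", len(kept), len(pheno))
    return np.array(kept, dtype=int)


def standardize_zscores(s: SummaryStatSet) -> SummaryStatSet:
    """Re-weight the Z columns by the square roots of the sample sizes.

    Column j is multiplied by w_j = (1/k) * sum_i sqrt(N_i) / sqrt(N_j), which
    equalises study-size-driven power differences across phenotypes before
    mixture modelling. Refuses to standardise twice.
    """
    if s.standardized:
        raise ValueError("SummaryStatSet is already standardised")
    n = s.sample_sizes
    if np.any(n <= 0):
        raise ValueError("all per-phenotype sample sizes must be positive")
    w = np.mean(np.sqrt(n)) / np.sqrt(n)
    out = SummaryStatSet(
        snp_ids=s.snp_ids.copy(),
        chrom=s.chrom.copy(),
        pos=s.pos.copy(),
        maf=s.maf.copy(),
        Z=s.Z * w[None, :],
        P=s.P.copy(),
        pheno=list(s.pheno),
        standardized=True,
    )
    return out


def sample_size_weights(n: np.ndarray, renormalize: bool = False) -> np.ndarray:
    """w_j = mean_i(sqrt(N_i)) / sqrt(N_j); optionally rescaled so the weights
    average exactly 1 (off by default — the printed formula only satisfies
    that constraint approximately)."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    w = np.mean(np.sqrt(n)) / np.sqrt(n)
    if renormalize:
        w = w / w.mean()
    return w


def qc_snps_ks(s: SummaryStatSet, alpha: float = KS_ALPHA) -> np.ndarray:
    """Retain SNPs whose p-values across phenotypes deviate from Uniform(0,1).

    A one-sample two-sided Kolmogorov-Smirnov test is applied per SNP to its
    k GWAS p-values; SNPs with KS p-value < ``alpha`` are retained (a SNP with
    no signal anywhere has uniform p-values and carries no information for the
    mixture). Exact KS distribution for k <= 1000, asymptotic above.
    """
    if s.n_pheno < 2:
        raise ValueError("KS screen needs at least 2 phenotypes")
    method = "exact" if s.n_pheno <= 1000 else "asymp"
    kept = []
    n_missing = 0
    for i in range(s.n_snps):
        p_row = s.P[i]
        if not np.all(np.isfinite(p_row)):
            n_missing += 1
            continue
        ks_p = stats.kstest(p_row, stats.uniform.cdf, method=method).pvalue
        if ks_p < alpha:
            kept.append(i)
    if n_missing:
        logger.warning("qc_snps_ks: %d SNPs excluded for missing p-values", n_missing)
    logger.info("qc_snps_ks: retained %d / %d SNPs", len(kept), s.n_snps)
    return np.array(kept, dtype=int)


def apply_maf_filter(s: SummaryStatSet, min_maf: float = MIN_MAF) -> np.ndarray:
    """Indices of SNPs with MAF strictly greater than ``min_maf``."""
    idx = np.nonzero(s.maf > min_maf)[0]
    logger.info("apply_maf_filter: retained %d / %d SNPs", len(idx), s.n_snps)
    return idx


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

_TGCA_COLUMNS = [
    "snp", "chrom", "pos", "theta", "se_theta", "z_theta", "p_theta",
    "pi_neg", "pi_null", "pi_pos", "mu_neg", "mu_pos", "sigma2_1", "sigma2_2",
    "converged", "n_iter",
]


def write_tgca_table(results, path) -> None:
    """Write per-SNP TGCA results as a tab-separated table (10 significant
    digits; lossless round-trip through :func:`read_tgca_table`).

    Non-converged fits keep their row with ``converged`` False and empty
    inference columns.
    """
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        p = r.fit.params
        ok = r.fit.converged
        rows.append(
            {
                "snp": r.snp_id,
                "chrom": r.chrom if r.chrom is not None else "",
                "pos": r.pos if r.pos is not None else -1,
                "theta": r.theta if ok else np.nan,
                "se_theta": r.se_theta if ok else np.nan,
                "z_theta": r.z_theta if ok else np.nan,
                "p_theta": r.p_theta if ok else np.nan,
                "pi_neg": p.pi_neg,
                "pi_null": p.pi_null,
                "pi_pos": p.pi_pos,
                "mu_neg": p.mu_neg,
                "mu_pos": p.mu_pos,
                "sigma2_1": p.sigma2_1,
                "sigma2_2": p.sigma2_2,
                "converged": ok,
                "n_iter": r.fit.n_iter,
            }
        )
    df = pd.DataFrame(rows, columns=_TGCA_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tgca_table(path) -> pd.DataFrame:
    """Companion reader for :func:`write_tgca_table`."""
    return pd.read_csv(path, sep="\t")
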