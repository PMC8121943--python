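"""Phenotypic test-statistic correlation and eigen-regularised decorrelation.

The correlation matrix R between the GWAS test statistics of the phenotypes
is estimated as the Pearson correlation of the Z-score columns restricted to
very-low-MAF variants (MAF < 5e-4): such variants carry essentially no
genetic signal, so the correlation of their test statistics reflects
phenotypic correlation plus sample overlap. Near-duplicate phenotypes
(|r| > 0.9) are pruned. Decorrelation maps each SNP's Z-vector through
R^(-1/2) restricted to the leading eigenvectors capturing a configured
fraction (default 90%) of the eigenvalue mass, yielding mutually
uncorrelated adjusted scores Z*.

Eigen-truncation is the only decorrelation backend: a Cholesky root is
fragile for the ill-conditioned correlation matrices that arise with many
correlated traits, while dropping the trailing eigenspace regularises the
inverse square root. ``info_cut=1.0`` with the eigenvalue floor acts as the
full-rank escape hatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

MAF_MAX = 5e-4
PRUNE_CUT = 0.9
INFO_CUT = 0.9
EIGVAL_FLOOR = 1e-8


class InsufficientDataError(ValueError):
    """Too few qualifying low-MAF variants to estimate R."""


@dataclass
class PhenoCorrModel:
    """Estimated phenotypic correlation matrix over the retained phenotypes."""

    R: np.ndarray
    kept_phenotypes: np.ndarray
    n_snps_used: int

    def __post_init__(self):
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")


@dataclass
class Decorrelator:
    """R^(-1/2) restricted to the top-M eigenspace of R."""

    eigenvectors: np.ndarray  # (k, M)
    eigenvalues: np.ndarray  # (M,), positive, descending
    M: int
    info_fraction: float
    kept_phenotypes: Optional[np.ndarray] = None

    @property
    def n_pheno(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def transform(self) -> np.ndarray:
        """The (k, M) matrix V diag(lambda^(-1/2)); Z* = Z @ transform."""
        return self.eigenvectors / np.sqrt(self.eigenvalues)[None, :]

    def to_tsv(self, path) -> None:
        """Serialise to a small text file with a metadata header."""
        kept = (
            ",".join(map(str, self.kept_phenotypes))
            if self.kept_phenotypes is not None
            else ""
        )
        with open(path, "w") as fh:
            fh.write(f"# M={self.M}\n")
            fh.write(f"# info_fraction={self.info_fraction:.12g}\n")
            fh.write(f"# kept_phenotypes={kept}\n")
            fh.write("\t".join(f"{v:.17g}" for v in self.eigenvalues) + "\n")
            for row in self.eigenvectors:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "Decorrelator":
        meta = {}
        rows = []
        eigenvalues = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, val = line[2:].partition("=")
                    meta[key] = val
                elif eigenvalues is None:
                    eigenvalues = np.array([float(v) for v in line.split("\t")])
                else:
                    rows.append([float(v) for v in line.split("\t")])
        kept = (
            np.array([int(v) for v in meta["kept_phenotypes"].split(",")])
            if meta.get("kept_phenotypes")
            else None
        )
        return cls(
            eigenvectors=np.array(rows),
            eigenvalues=eigenvalues,
            M=int(meta["M"]),
            info_fraction=float(meta["info_fraction"]),
            kept_phenotypes=kept,
        )


def shrink_correlation(R: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Linear shrinkage of a sample correlation matrix towards the identity.

    Uses the Schafer-Strimmer intensity: lambda* = sum Var(r_ij) / sum r_ij^2
    with Var(r_ij) ~= (1 - r_ij^2)^2 / n, clipped to [0, 1]. With few samples
    per dimension the off-diagonals are mostly noise and lambda* -> 1; with
    many samples lambda* -> 0 and the estimate is left untouched.
    """
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R[off] ** 2
    denom = float(np.sum(r2))
    if denom <= 0:
        return np.eye(R.shape[0]), 1.0
    var_r = np.sum((1.0 - r2) ** 2) / max(n, 2)
    lam = float(np.clip(var_r / denom, 0.0, 1.0))
    out = (1.0 - lam) * R + lam * np.eye(R.shape[0])
    return out, lam


def estimate_pheno_corr(
    s,
    maf_max: float = MAF_MAX,
    prune_cut: float = PRUNE_CUT,
    shrinkage: Optional[str] = None,
) -> PhenoCorrModel:
    """Estimate R from the Z columns of the low-MAF variant pool and prune
    near-duplicate phenotypes.

    Pruning is a deterministic greedy sweep in input order: when a retained
    pair has |r| > ``prune_cut``, the later-indexed phenotype is removed.

    ``shrinkage="auto"`` applies Schafer-Strimmer linear shrinkage towards
    the identity after pruning — essential when the low-MAF pool is small
    relative to the phenotype count, where raw sampling noise in R would
    otherwise rotate the decorrelation basis at random. The default (None)
    returns the raw Pearson estimate, appropriate at genome scale where the
    pool has hundreds of variants per phenotype.
    """
    low = np.nonzero(s.maf < maf_max)[0]
    if len(low) < 2:
        raise InsufficientDataError(
            f"only {len(low)} variants with MAF < {maf_max}; need at least 2"
        )
    R = np.corrcoef(s.Z[low], rowvar=False)
    R = np.atleast_2d(R)
    k = R.shape[0]
    if k < 2:
        raise InsufficientDataError("need at least 2 phenotypes")

    kept: list[int] = []
    for j in range(k):
        if all(abs(R[i, j]) <= prune_cut for i in kept):
            kept.append(j)
    kept_arr = np.array(kept, dtype=int)
    Rk = R[np.ix_(kept_arr, kept_arr)]
    Rk = 0.5 * (Rk + Rk.T)
    np.fill_diagonal(Rk, 1.0)
    if len(kept) < k:
        logger.info(
            "estimate_pheno_corr: pruned %d near-duplicate phenotypes (|r| > %g)",
            k - len(kept), prune_cut,
        )
    if shrinkage == "auto":
        Rk, lam = shrink_correlation(Rk, len(low))
        logger.info("estimate_pheno_corr: shrinkage intensity %.3f", lam)
    elif shrinkage is not None:
        raise ValueError(f"unknown shrinkage mode {shrinkage!r}")
    return PhenoCorrModel(R=Rk, kept_phenotypes=kept_arr, n_snps_used=len(low))


def build_decorrelator(
    m: PhenoCorrModel,
    info_cut: float = INFO_CUT,
    eigval_floor: float = EIGVAL_FLOOR,
) -> Decorrelator:
    """Eigen-decompose R and keep the smallest leading eigenspace capturing
    at least ``info_cut`` of the eigenvalue mass (trace of R).

    Non-positive (and floor-level) eigenvalues are never retained. Each
    eigenvector's largest-magnitude entry is made positive so the transform
    is reproducible across linear-algebra backends.
    """
    if not (0.0 < info_cut <= 1.0):
        raise ValueError("info_cut must lie in (0, 1]")
    vals, vecs = np.linalg.eigh(m.R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = float(np.trace(m.R))
    cum = np.cumsum(vals) / trace
    M = int(np.searchsorted(cum, info_cut - 1e-12) + 1)
    M = min(M, int(np.sum(vals > eigval_floor)))
    if M < 1:
        raise ValueError("no positive eigenvalues above the floor")
    vals, vecs = vals[:M].copy(), vecs[:, :M].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    piv = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[piv, np.arange(M)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs[None, :]
    info_fraction = float(np.sum(vals) / trace)
    return Decorrelator(
        eigenvectors=vecs,
        eigenvalues=vals,
        M=M,
        info_fraction=info_fraction,
        kept_phenotypes=m.kept_phenotypes,
    )


def decorrelate(Z: np.ndarray, d: Decorrelator) -> np.ndarray:
    """Z* = Z V diag(lambda^(-1/2)): each row becomes M mutually uncorrelated
    adjusted scores."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != d.n_pheno:
        raise ValueError(
            f"Z has {Z.shape[1]} columns but the decorrelator expects {d.n_pheno}"
        )
    return Z @ d.transform
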