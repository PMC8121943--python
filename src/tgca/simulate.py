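"""Generators for Z-scores under known truth, and synthetic study fixtures.

Four generative truths are supported for a single variant's vector of k
Z-scores:

``gauss2``
    pi_neg N(mu_neg, s1) + pi_null N(0,1) + pi_pos N(mu_pos, s2),
    pi_neg = pi_pos = (1 - pi_null)/2.
``gauss1``
    pi_null N(0,1) + pi_pos N(mu_pos, s2)  (no negative component).
``gauss3``
    adds a second positive component N(mu_pos2, s3);
    pi_neg = 2 pi_pos = 2 pi_pos2.
``heavy_t``
    the two non-null components are location-shifted Cauchy, t(1) + mu;
    a deliberately misspecified heavy-tailed truth.

Component means are drawn mu_neg ~ -|N(1,1)|, mu_pos (and mu_pos2) ~ |N(1,1)|
and variances ~ chi-square(1), covering a wide slab of the parameter space.
Component memberships use deterministic largest-remainder counts (not
multinomial draws), because the true-theta formula presumes fixed component
sizes. The true theta of a labelled draw is

    theta_true = |mean(z over negative labels)| + |mean(z over positive labels)|

with the two positive components of gauss3 pooled. Under correlated
generation the labelled blocks are first decorrelated by their own
submatrix inverse square roots.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import MixtureParams, fit_tgca_mixture, compute_theta, snp_seed
from .sumstats import PhenotypeMeta

logger = logging.getLogger(__name__)

MODELS = ("gauss2", "gauss1", "gauss3", "heavy_t")
PI_NULL_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)

# label codes
NEG, NULL, POS, POS2 = -1, 0, 1, 2


@dataclass(frozen=True)
class SimScenario:
    """One generative truth with drawn parameters and a seed."""

    model: str
    pi_null: float
    k: int
    seed: int
    mu_neg: float = 0.0
    mu_pos: float = 0.0
    mu_pos2: float = 0.0
    sigma2_1: float = 1.0
    sigma2_2: float = 1.0
    sigma2_3: float = 1.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 < self.pi_null < 1.0):
            raise ValueError("pi_null must lie in (0, 1)")

    @classmethod
    def draw(cls, model: str, pi_null: float, k: int, seed: int) -> "SimScenario":
        """Draw the component parameters from their sampling distributions."""
        rng = np.random.default_rng(seed)
        mu_neg = -abs(rng.normal(1.0, 1.0))
        mu_pos = abs(rng.normal(1.0, 1.0))
        mu_pos2 = abs(rng.normal(1.0, 1.0))
        s1, s2, s3 = rng.chisquare(1.0, size=3)
        s1, s2, s3 = (max(v, 1e-6) for v in (s1, s2, s3))
        return cls(
            model=model, pi_null=pi_null, k=k, seed=seed,
            mu_neg=float(mu_neg), mu_pos=float(mu_pos), mu_pos2=float(mu_pos2),
            sigma2_1=float(s1), sigma2_2=float(s2), sigma2_3=float(s3),
        )

    def proportions(self) -> dict[int, float]:
        """Per-label mixture proportions under this model."""
        non_null = 1.0 - self.pi_null
        if self.model in ("gauss2", "heavy_t"):
            return {NEG: non_null / 2, NULL: self.pi_null, POS: non_null / 2}
        if self.model == "gauss1":
            return {NULL: self.pi_null, POS: non_null}
        # gauss3: pi_neg = 2 pi_pos = 2 pi_pos2
        return {
            NEG: non_null / 2,
            NULL: self.pi_null,
            POS: non_null / 4,
            POS2: non_null / 4,
        }


@dataclass
class LabelledZ:
    """A generated Z-vector with its pre-assigned component labels."""

    z: np.ndarray
    labels: np.ndarray

    @property
    def counts(self) -> dict[int, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def _largest_remainder_counts(props: dict[int, float], k: int) -> dict[int, int]:
    """Apportion k elements to labels by largest-remainder rounding."""
    labels = sorted(props)
    exact = np.array([props[l] * k for l in labels])
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = k - int(base.sum())
    for i in np.argsort(-rem)[:short]:
        base[i] += 1
    return dict(zip(labels, base.tolist()))


def _standard_cauchy(rng: np.random.Generator, size: int) -> np.ndarray:
    # ratio-of-normals construction of t(1), for seed portability
    a = rng.normal(size=size)
    b = rng.normal(size=size)
    b[b == 0.0] = 1e-300
    return a / b


def _component_moments(sc: SimScenario, label: int) -> tuple[float, float]:
    """(mean, sd) of the Gaussian component for a label code."""
    if label == NULL:
        return 0.0, 1.0
    if label == NEG:
        return sc.mu_neg, float(np.sqrt(sc.sigma2_1))
    if label == POS:
        return sc.mu_pos, float(np.sqrt(sc.sigma2_2))
    return sc.mu_pos2, float(np.sqrt(sc.sigma2_3))


def simulate_scenario(sc: SimScenario) -> LabelledZ:
    """Draw k independent Z-scores with fixed per-component counts."""
    if sc.k < 10:
        raise ValueError("k must be at least 10")
    rng = np.random.default_rng(sc.seed)
    counts = _largest_remainder_counts(sc.proportions(), sc.k)
    labels = np.concatenate([np.full(c, lab) for lab, c in sorted(counts.items())])
    labels = rng.permutation(labels)
    z = np.empty(sc.k)
    for lab in counts:
        idx = labels == lab
        n = int(idx.sum())
        if sc.model == "heavy_t" and lab in (NEG, POS):
            mu = sc.mu_neg if lab == NEG else sc.mu_pos
            z[idx] = _standard_cauchy(rng, n) + mu
        else:
            mu, sd = _component_moments(sc, lab)
            z[idx] = rng.normal(mu, sd, size=n)
    return LabelledZ(z=z, labels=labels)


def true_theta_independent(lz: LabelledZ) -> float:
    """Realised true theta of a labelled draw:

        |sum(z over negative labels)| / k + |sum(z over positive labels)| / k

    i.e. the label-proportion-weighted absolute mean effect of each non-null
    side (both positive components pooled), the quantity the mixture
    statistic |pi_pos mu_pos| + |pi_neg mu_neg| estimates. An empty side
    contributes 0.
    """
    k = lz.z.size
    neg = lz.z[lz.labels == NEG]
    pos = lz.z[(lz.labels == POS) | (lz.labels == POS2)]
    t = 0.0
    if neg.size:
        t += abs(float(neg.sum())) / k
    if pos.size:
        t += abs(float(pos.sum())) / k
    return t


# ---------------------------------------------------------------------------
# correlated generation (Gaussian copula)
# ---------------------------------------------------------------------------


def _check_psd(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    vals = np.linalg.eigvalsh(R)
    if vals.min() < -tol:
        raise ValueError("R is not positive semi-definite")
    return R


def simulate_correlated(sc: SimScenario, R: np.ndarray) -> LabelledZ:
    """Correlated draw via a Gaussian copula: a correlated standard-normal
    vector u ~ N(0, R) is mapped elementwise through the assigned Gaussian
    component's location-scale transform, preserving both the marginal
    mixture and the correlation structure. Heavy-tailed truths are not
    supported under correlation."""
    if sc.model == "heavy_t":
        raise ValueError("correlated generation supports Gaussian models only")
    R = _check_psd(R)
    if R.shape[0] != sc.k:
        raise ValueError("R dimension must equal k")
    rng = np.random.default_rng(sc.seed)
    counts = _largest_remainder_counts(sc.proportions(), sc.k)
    labels = np.concatenate([np.full(c, lab) for lab, c in sorted(counts.items())])
    labels = rng.permutation(labels)
    vals, vecs = np.linalg.eigh(R)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]
    u = root @ rng.normal(size=sc.k)
    z = np.empty(sc.k)
    for lab in counts:
        idx = labels == lab
        mu, sd = _component_moments(sc, lab)
        z[idx] = mu + sd * u[idx]
    return LabelledZ(z=z, labels=labels)


def _inv_sqrt(mat: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root; eigen-truncated when near-singular."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() <= floor:
        logger.warning(
            "singular labelled-block correlation; using eigen-truncated inverse root"
        )
    keep = vals > floor
    return (vecs[:, keep] / np.sqrt(vals[keep])[None, :]) @ vecs[:, keep].T


def true_theta_correlated(lz: LabelledZ, R: np.ndarray) -> float:
    """True theta under correlation: each labelled block is decorrelated by
    the inverse square root of its own correlation submatrix before the
    independent-case (proportion-weighted) formula is applied."""
    R = np.asarray(R, dtype=float)
    k = lz.z.size
    neg_idx = np.nonzero(lz.labels == NEG)[0]
    pos_idx = np.nonzero((lz.labels == POS) | (lz.labels == POS2))[0]
    t = 0.0
    for idx in (neg_idx, pos_idx):
        if idx.size == 0:
            continue
        sub = R[np.ix_(idx, idx)]
        z_star = lz.z[idx] @ _inv_sqrt(sub)
        t += abs(float(z_star.sum())) / k
    return t


# ---------------------------------------------------------------------------
# recovery study
# ---------------------------------------------------------------------------


def run_recovery_study(
    models: Sequence[str] = MODELS,
    pi_null_grid: Sequence[float] = PI_NULL_GRID,
    n_reps: int = 999,
    k: int = 200,
    seed: int = 0,
    R: Optional[np.ndarray] = None,
    info_cut: float = 0.9,
    n_starts: int = 5,
    max_iter: int = 9999,
) -> pd.DataFrame:
    """Simulate, fit and record theta recovery over a model x pi_null grid.

    With ``R`` given, Z-scores are generated correlated and decorrelated at
    ``info_cut`` before fitting (heavy_t is skipped), and the true theta uses
    the correlated-case formula. Returns one row per replicate with columns
    (model, pi_null, rep, theta_true, theta_hat, converged).
    """
    from .phenocorr import PhenoCorrModel, build_decorrelator, decorrelate

    decor = None
    if R is not None:
        R = _check_psd(R)
        model_R = PhenoCorrModel(
            R=R, kept_phenotypes=np.arange(R.shape[0]), n_snps_used=0
        )
        decor = build_decorrelator(model_R, info_cut=info_cut)
    rows = []
    for model in models:
        if decor is not None and model == "heavy_t":
            continue
        for pi0 in pi_null_grid:
            for rep in range(n_reps):
                sseed = snp_seed(seed, f"{model}:{pi0}:{rep}")
                sc = SimScenario.draw(model, pi0, k, sseed)
                if decor is None:
                    lz = simulate_scenario(sc)
                    theta_true = true_theta_independent(lz)
                    z_fit = lz.z
                else:
                    lz = simulate_correlated(sc, R)
                    theta_true = true_theta_correlated(lz, R)
                    z_fit = decorrelate(lz.z[None, :], decor)[0]
                fit = fit_tgca_mixture(
                    z_fit, seed=sseed + 1, n_starts=n_starts,
                    max_iter=max_iter, compute_cov=False,
                )
                rows.append(
                    {
                        "model": model,
                        "pi_null": pi0,
                        "rep": rep,
                        "theta_true": theta_true,
                        "theta_hat": compute_theta(fit.params),
                        "converged": fit.converged,
                    }
                )
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per (model, pi_null) cell: Pearson correlation and regression slope of
    theta_hat on theta_true over converged replicates."""
    out = []
    for (model, pi0), g in table.groupby(["model", "pi_null"]):
        g = g[g["converged"]]
        r = slope = np.nan
        if len(g) >= 3 and g["theta_true"].std() > 0:
            r = float(np.corrcoef(g["theta_true"], g["theta_hat"])[0, 1])
            slope = float(
                np.polyfit(g["theta_true"], g["theta_hat"], 1)[0]
            )
        out.append(
            {
                "model": model,
                "pi_null": pi0,
                "n_converged": len(g),
                "pearson_r": r,
                "slope": slope,
            }
        )
    return pd.DataFrame(out)


def clustered_corr(
    k: int,
    seed: int = 0,
    frac_clustered: float = 0.5,
    block_range: tuple[int, int] = (2, 10),
    rho_range: tuple[float, float] = (0.2, 0.7),
) -> np.ndarray:
    """A biobank-like phenotype correlation matrix: about half of the traits
    fall into exchangeable clusters of 2-10 related phenotypes (within-
    cluster correlation 0.2-0.7), the rest are near-independent. Uniformly
    strong correlation across all traits is deliberately avoided — real
    multi-domain phenotype panels are sparsely correlated."""
    rng = np.random.default_rng(seed)
    R = np.eye(k)
    total = 0
    n_clust = int(k * frac_clustered)
    while total < n_clust - 1:
        sz = int(rng.integers(block_range[0], block_range[1] + 1))
        sz = min(sz, n_clust - total)
        if sz < 2:
            break
        rho = float(rng.uniform(*rho_range))
        idx = slice(total, total + sz)
        R[idx, idx] = rho * np.ones((sz, sz)) + (1 - rho) * np.eye(sz)
        total += sz
    return R


def run_power_study(
    theta_true: float = 0.3,
    pi_null_grid: Sequence[float] = (0.1, 0.5, 0.9),
    n_reps: int = 200,
    k: int = 200,
    sigma2: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the Wald test at a fixed true theta across pi_null.

    The non-null means are set to mu = theta_true / (1 - pi_null) on both
    sides, so the total contribution is held constant while the component
    separation grows with the null fraction: the same theta spread over
    fewer non-null traits means larger per-trait effects, hence a more
    identifiable mixture and higher power.
    """
    from .mixture import compute_theta, theta_se_delta, wald_test_theta

    rows = []
    for pi0 in pi_null_grid:
        mu = theta_true / (1.0 - pi0)
        n_tested = 0
        n_rej = 0
        n_no_se = 0
        rng = np.random.default_rng(snp_seed(seed, f"power:{pi0}"))
        for rep in range(n_reps):
            km = kp = int(round(k * (1 - pi0) / 2))
            k0 = k - km - kp
            z = np.concatenate(
                [
                    rng.normal(-mu, np.sqrt(sigma2), km),
                    rng.normal(0.0, 1.0, k0),
                    rng.normal(mu, np.sqrt(sigma2), kp),
                ]
            )
            fit = fit_tgca_mixture(rng.permutation(z), seed=snp_seed(seed, f"{pi0}:{rep}"))
            if not fit.converged or fit.boundary_flag or fit.param_cov is None:
                n_no_se += 1
                continue
            se = theta_se_delta(fit)
            if se <= 0:
                n_no_se += 1
                continue
            n_tested += 1
            if wald_test_theta(compute_theta(fit.params), se) < alpha:
                n_rej += 1
        rows.append(
            {
                "pi_null": pi0,
                "power": n_rej / n_tested if n_tested else np.nan,
                "n_tested": n_tested,
                "n_without_se": n_no_se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic multi-phenotype study fixture
# ---------------------------------------------------------------------------


def default_phenotypes(n_pheno: int, seed: int = 0) -> list[PhenotypeMeta]:
    """Plausible phenotype metadata: biobank-scale sample sizes, a mix of
    continuous and binary traits.

    Effective sample sizes (case counts for binary traits) are kept within a
    factor of ~5 of each other: the square-root-of-N standardisation assumes
    comparably powered GWAS, and a very rare binary trait (weight w_j >> 1)
    would have its null noise variance inflated by w_j^2 — a genuine
    limitation of the weighting on real data, but not a condition the
    mixture model is meant to operate under.
    """
    rng = np.random.default_rng(seed)
    metas = []
    for j in range(n_pheno):
        n_total = int(rng.integers(150_000, 360_000))
        if j % 3 == 0:
            n_cases = int(rng.integers(60_000, n_total // 2))
            metas.append(
                PhenotypeMeta(f"pheno_{j:03d}", "binary", n_total, n_cases,
                              domain_label="medical conditions")
            )
        else:
            metas.append(
                PhenotypeMeta(f"pheno_{j:03d}", "continuous", n_total,
                              domain_label="physical measures")
            )
    return metas


def generate_synthetic_study(
    n_snps: int,
    phenotypes: Sequence[PhenotypeMeta],
    R: Optional[np.ndarray],
    planted: Optional[Sequence[Optional[MixtureParams]]],
    seed: int,
    out_dir,
) -> dict:
    """Write a complete synthetic multi-phenotype summary-statistic study.

    Each SNP's Z-row is drawn from its planted mixture (null N(0,1) when the
    planted entry is None), with cross-phenotype correlation R induced by a
    Gaussian copula. MAFs are drawn log-uniform over [1e-4, 0.5] so both the
    low-MAF correlation-estimation pool and the analysed pool are populated;
    SNPs with a planted signal are forced into the analysed MAF range.
    P-values are consistent with the written Z-scores. Returns a manifest
    dict (also written as manifest.json) naming the files.
    """
    k = len(phenotypes)
    if planted is not None and len(planted) != n_snps:
        raise ValueError("planted list length must equal n_snps")
    if R is None:
        R = np.eye(k)
    R = _check_psd(R)
    if R.shape[0] != k:
        raise ValueError("R dimension must equal the phenotype count")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    maf = np.exp(rng.uniform(np.log(1e-4), np.log(0.5), size=n_snps))
    vals, vecs = np.linalg.eigh(R)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]

    Z = np.empty((n_snps, k))
    for i in range(n_snps):
        u = root @ rng.normal(size=k)
        p = planted[i] if planted is not None else None
        if p is None:
            Z[i] = u
        else:
            if maf[i] <= 0.005:
                maf[i] = rng.uniform(0.01, 0.5)
            # deterministic component counts (largest remainder), as in the
            # labelled simulators: the planted theta is then exact up to
            # within-component noise
            counts = _largest_remainder_counts(
                {NEG: p.pi_neg, NULL: p.pi_null, POS: p.pi_pos}, k
            )
            comp = rng.permutation(
                np.concatenate([np.full(c, lab) for lab, c in sorted(counts.items())])
            )
            mu = np.where(comp == NEG, p.mu_neg, np.where(comp == POS, p.mu_pos, 0.0))
            sd = np.sqrt(
                np.where(comp == NEG, p.sigma2_1, np.where(comp == POS, p.sigma2_2, 1.0))
            )
            Z[i] = mu + sd * u
    P = 2.0 * stats.norm.sf(np.abs(Z))

    snp_ids = np.array([f"1:{10_000 * (i + 1)}:A:G" for i in range(n_snps)])
    pos = 10_000 * (np.arange(n_snps) + 1)
    files = []
    for j, meta in enumerate(phenotypes):
        n_eff = meta.n_cases if meta.trait_type == "binary" else meta.n_total
        se = 1.0 / np.sqrt(float(n_eff))
        df = pd.DataFrame(
            {
                "variant": snp_ids,
                "chr": "1",
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "beta": Z[:, j] * se,
                "se": se,
                "pval": P[:, j],
                "n": meta.n_total,
                "n_cases": meta.n_cases if meta.n_cases is not None else "",
                "minor_AF": maf,
            }
        )
        fname = os.path.join(out_dir, f"{meta.phenotype_id}.sumstats.tsv")
        df.to_csv(fname, sep="\t", index=False, float_format="%.10g")
        files.append(fname)

    pheno_path = os.path.join(out_dir, "phenotypes.tsv")
    pd.DataFrame(
        [
            {
                "phenotype_id": m.phenotype_id,
                "trait_type": m.trait_type,
                "n_total": m.n_total,
                "n_cases": m.n_cases if m.n_cases is not None else "",
                "domain_label": m.domain_label or "",
            }
            for m in phenotypes
        ]
    ).to_csv(pheno_path, sep="\t", index=False)

    manifest = {
        "n_snps": n_snps,
        "n_phenotypes": k,
        "seed": seed,
        "planted_snps": (
            [str(snp_ids[i]) for i in range(n_snps) if planted[i] is not None]
            if planted is not None
            else []
        ),
        "phenotype_table": os.path.basename(pheno_path),
        "files": [os.path.basename(f) for f in files],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
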