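import numpy as np
import pandas as pd
import pytest

from tgca import PhenotypeMeta, SummaryStatSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sumstats(
    n_snps=50,
    n_pheno=4,
    seed=0,
    maf=None,
    Z=None,
    P=None,
    pheno=None,
    standardized=False,
):
    """Build a small in-memory SummaryStatSet with controllable pieces."""
    r = np.random.default_rng(seed)
    if pheno is None:
        pheno = [
            PhenotypeMeta(f"p{j}", "continuous", 100_000 + 10_000 * j)
            for j in range(n_pheno)
        ]
    k = len(pheno)
    if Z is None:
        Z = r.normal(size=(n_snps, k))
    if P is None:
        from scipy import stats

        P = 2.0 * stats.norm.sf(np.abs(Z))
    if maf is None:
        maf = r.uniform(0.01, 0.5, size=n_snps)
    return SummaryStatSet(
        snp_ids=np.array([f"rs{i}" for i in range(n_snps)], dtype=object),
        chrom=np.array(["1"] * n_snps, dtype=object),
        pos=np.arange(1, n_snps + 1) * 1000,
        maf=np.asarray(maf, dtype=float),
        Z=np.asarray(Z, dtype=float),
        P=np.asarray(P, dtype=float),
        pheno=list(pheno),
        standardized=standardized,
    )


@pytest.fixture
def small_sumstats():
    return make_sumstats()


def write_sumstat_file(path, variants, z=None, beta=None, se=None, extra=None,
                       n=100_000, n_cases="", maf=0.1):
    """Write a minimal tab-separated summary-statistics file."""
    n_rows = len(variants)
    df = pd.DataFrame(
        {
            "variant": variants,
            "chr": ["1"] * n_rows,
            "pos": np.arange(1, n_rows + 1) * 100,
            "ref": ["A"] * n_rows,
            "alt": ["G"] * n_rows,
            "pval": [0.5] * n_rows,
            "n": [n] * n_rows,
            "n_cases": [n_cases] * n_rows,
            "minor_AF": [maf] * n_rows,
        }
    )
    if z is not None:
        df["z"] = z
    if beta is not None:
        df["beta"] = beta
        df["se"] = se
    if extra:
        for key, val in extra.items():
            df[key] = val
    df.to_csv(path, sep="\t", index=False)
    return path
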