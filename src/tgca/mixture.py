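"""Three-component Gaussian mixture with a frozen standard-normal null.

Each variant's vector of decorrelated, sample-size-standardised Z-scores
``z = (z_1, ..., z_k)`` is modelled as i.i.d. draws from

    pi_neg * N(mu_neg, sigma2_1) + pi_null * N(0, 1) + pi_pos * N(mu_pos, sigma2_2)

with ``mu_neg <= 0 <= mu_pos`` and the null component fixed at N(0, 1).
The total genetic contribution statistic is

    theta = |pi_pos * mu_pos| + |pi_neg * mu_neg|

i.e. the summed absolute mean effect carried by the non-null components.
Parameters are estimated per SNP by EM (multi-start, frozen null), the
observed information is obtained by central finite differences on the
profile likelihood with pi_null eliminated, and the standard error of
theta follows by the delta method; H0: theta = 0 is tested by a Wald
chi-square(1) statistic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

logger = logging.getLogger(__name__)

#: lower bound on the non-null component variances; prevents the classical
#: single-point likelihood spike of unconstrained Gaussian mixtures
VAR_FLOOR = 1e-3

#: default EM settings
MAX_ITER = 9999
TOL = 1e-8
N_STARTS = 5

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the three-component mixture (null frozen at N(0,1))."""

    pi_neg: float
    pi_null: float
    pi_pos: float
    mu_neg: float
    mu_pos: float
    sigma2_1: float
    sigma2_2: float

    def __post_init__(self):
        if not np.isclose(self.pi_neg + self.pi_null + self.pi_pos, 1.0, atol=1e-8):
            raise ValueError("mixing proportions must sum to 1")
        for p in (self.pi_neg, self.pi_null, self.pi_pos):
            if p < -1e-12 or p > 1 + 1e-12:
                raise ValueError("mixing proportions must lie in [0, 1]")
        if self.mu_neg > 1e-12 or self.mu_pos < -1e-12:
            raise ValueError("component means must satisfy mu_neg <= 0 <= mu_pos")
        if self.sigma2_1 <= 0 or self.sigma2_2 <= 0:
            raise ValueError("component variances must be positive")

    def free_vector(self) -> np.ndarray:
        """The 6 free parameters (pi_neg, pi_pos, mu_neg, mu_pos, s1, s2)."""
        return np.array(
            [self.pi_neg, self.pi_pos, self.mu_neg, self.mu_pos,
             self.sigma2_1, self.sigma2_2]
        )


@dataclass
class MixtureFit:
    """Result of one EM fit: parameters, likelihood and curvature."""

    params: MixtureParams
    loglik: float
    n_iter: int
    converged: bool
    param_cov: Optional[np.ndarray] = None
    boundary_flag: bool = False


@dataclass
class TGCAResult:
    """Per-SNP total-genetic-contribution estimate with inference."""

    snp_id: str
    theta: float
    se_theta: float
    z_theta: float
    p_theta: float
    fit: MixtureFit
    chrom: Optional[str] = None
    pos: Optional[int] = None


# ---------------------------------------------------------------------------
# likelihood and EM (compiled)
# ---------------------------------------------------------------------------


_LOG_SQRT2PI = float(np.log(np.sqrt(2.0 * np.pi)))
_NEG_HUGE = -1e308


@njit(cache=True)
def _loglik6(z, pi_m, pi_p, mu_m, mu_p, s1, s2):
    """Mixture log-likelihood, evaluated in log space (max-shifted per point)
    so that extreme Z-scores far from every component stay finite."""
    pi0 = 1.0 - pi_m - pi_p
    if pi_m < 0.0 or pi_p < 0.0 or pi0 < 0.0 or s1 <= 0.0 or s2 <= 0.0:
        return -np.inf
    lpi_m = np.log(pi_m) - 0.5 * np.log(s1) - _LOG_SQRT2PI if pi_m > 0.0 else _NEG_HUGE
    lpi_0 = np.log(pi0) - _LOG_SQRT2PI if pi0 > 0.0 else _NEG_HUGE
    lpi_p = np.log(pi_p) - 0.5 * np.log(s2) - _LOG_SQRT2PI if pi_p > 0.0 else _NEG_HUGE
    a1 = -0.5 / s1
    a2 = -0.5 / s2
    ll = 0.0
    for i in range(z.size):
        zi = z[i]
        em = lpi_m + a1 * (zi - mu_m) ** 2
        e0 = lpi_0 - 0.5 * zi * zi
        ep = lpi_p + a2 * (zi - mu_p) ** 2
        m = em
        if e0 > m:
            m = e0
        if ep > m:
            m = ep
        ll += m + np.log(np.exp(em - m) + np.exp(e0 - m) + np.exp(ep - m))
    return ll


@njit(cache=True)
def _em_inner_traced(z, pi_m, pi_p, mu_m, mu_p, s1, s2, max_iter, tol,
                     var_floor, ll_trace):
    """EM with the null frozen at N(0,1) and sign constraints on the means.

    The M-step maximises the expected complete-data log-likelihood over the
    constrained parameter space: means are projected onto mu_neg <= 0 <= mu_pos
    and variances onto [var_floor, inf), both of which preserve the EM
    monotonicity guarantee. ``ll_trace`` (possibly empty) records the
    log-likelihood at each iteration for diagnostics.
    """
    k = z.size
    r_m = np.empty(k)
    r_p = np.empty(k)
    ll_old = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space (also evaluates the log-likelihood at the
        # current params); max-shifting keeps extreme Z-scores finite
        pi0 = 1.0 - pi_m - pi_p
        lpi_m = np.log(pi_m) - 0.5 * np.log(s1) - _LOG_SQRT2PI if pi_m > 0.0 else _NEG_HUGE
        lpi_0 = np.log(pi0) - _LOG_SQRT2PI if pi0 > 0.0 else _NEG_HUGE
        lpi_p = np.log(pi_p) - 0.5 * np.log(s2) - _LOG_SQRT2PI if pi_p > 0.0 else _NEG_HUGE
        a1 = -0.5 / s1
        a2 = -0.5 / s2
        ll = 0.0
        for i in range(k):
            zi = z[i]
            em = lpi_m + a1 * (zi - mu_m) ** 2
            e0 = lpi_0 - 0.5 * zi * zi
            ep = lpi_p + a2 * (zi - mu_p) ** 2
            m = em
            if e0 > m:
                m = e0
            if ep > m:
                m = ep
            dm = np.exp(em - m)
            d0 = np.exp(e0 - m)
            dp = np.exp(ep - m)
            tot = dm + d0 + dp
            r_m[i] = dm / tot
            r_p[i] = dp / tot
            ll += m + np.log(tot)
        if ll_trace.size >= it:
            ll_trace[it - 1] = ll
        if it > 1 and abs(ll - ll_old) < tol * (abs(ll_old) + 1e-300):
            converged = True
            break
        ll_old = ll
        # M-step
        sm = 0.0
        sp = 0.0
        for i in range(k):
            sm += r_m[i]
            sp += r_p[i]
        pi_m = sm / k
        pi_p = sp / k
        if sm > 0.0:
            num = 0.0
            for i in range(k):
                num += r_m[i] * z[i]
            mu_m = num / sm
            if mu_m > 0.0:
                mu_m = 0.0
            v = 0.0
            for i in range(k):
                v += r_m[i] * (z[i] - mu_m) ** 2
            s1 = v / sm
            if s1 < var_floor:
                s1 = var_floor
        if sp > 0.0:
            num = 0.0
            for i in range(k):
                num += r_p[i] * z[i]
            mu_p = num / sp
            if mu_p < 0.0:
                mu_p = 0.0
            v = 0.0
            for i in range(k):
                v += r_p[i] * (z[i] - mu_p) ** 2
            s2 = v / sp
            if s2 < var_floor:
                s2 = var_floor
    return pi_m, pi_p, mu_m, mu_p, s1, s2, ll, it, converged


_EMPTY_TRACE = np.empty(0)


def _em_inner(z, pi_m, pi_p, mu_m, mu_p, s1, s2, max_iter, tol, var_floor):
    return _em_inner_traced(
        z, pi_m, pi_p, mu_m, mu_p, s1, s2, max_iter, tol, var_floor,
        _EMPTY_TRACE,
    )


def em_loglik_trace(
    z: np.ndarray,
    start: tuple,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    var_floor: float = VAR_FLOOR,
) -> np.ndarray:
    """Run one EM from an explicit start (pi_neg, pi_pos, mu_neg, mu_pos,
    s1, s2) and return the per-iteration log-likelihood trajectory — the
    observable that certifies EM monotonicity."""
    z = np.asarray(z, dtype=float)
    trace = np.full(max_iter, np.nan)
    out = _em_inner_traced(z, *start, max_iter, tol, var_floor, trace)
    n_used = out[7]
    return trace[:n_used]


def default_starts(z: np.ndarray, var_floor: float = VAR_FLOOR) -> list:
    """The deterministic portion of the start portfolio, in search order."""
    return [
        _moment_start(z),
        _lazy_start(z),
        _spike_start(z, var_floor),
        _tight_moment_start(z),
        _cluster_spike_start(z, var_floor),
    ]


# ---------------------------------------------------------------------------
# initialisation and fitting
# ---------------------------------------------------------------------------


def _moment_start(z: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Moment-based starting point: tail means and tail fractions of z."""
    above = z[z > 1.0]
    below = z[z < -1.0]
    mu_p = float(above.mean()) if above.size else 1.0
    mu_m = float(below.mean()) if below.size else -1.0
    pi_p = max(float(np.mean(z > 1.5)), 0.01)
    pi_m = max(float(np.mean(z < -1.5)), 0.01)
    # keep the start strictly interior
    tot = pi_m + pi_p
    if tot > 0.9:
        pi_m *= 0.9 / tot
        pi_p *= 0.9 / tot
    return pi_m, pi_p, mu_m, mu_p, 1.0, 1.0


def _lazy_start(z: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Bulk-oriented start: component means at the data quartiles and
    variances at the sample variance; reaches the broad, weakly-separated
    optima that tail-seeking starts jump over."""
    q25, q75 = np.quantile(z, [0.25, 0.75])
    v = max(float(np.var(z)), 0.05)
    return 0.25, 0.25, min(float(q25), -1e-3), max(float(q75), 1e-3), v, v


def _spike_start(z: np.ndarray, var_floor: float):
    """Degeneracy-probing start: narrow components at the extreme order
    statistics, where the floored likelihood frequently has its global
    maximum (single-point spikes)."""
    return (
        0.02, 0.02, min(float(z.min()), -1e-3), max(float(z.max()), 1e-3),
        2.0 * var_floor, 2.0 * var_floor,
    )


def _tight_moment_start(z: np.ndarray):
    """Moment start with narrow component variances, so small well-separated
    tail clusters are not washed out by a unit-variance component."""
    pi_m, pi_p, mu_m, mu_p, _, _ = _moment_start(z)
    return pi_m, pi_p, mu_m, mu_p, 0.05, 0.05


def _cluster_spike_start(z: np.ndarray, var_floor: float):
    """Narrow components on the two extreme order statistics of each side,
    catching two-point spike optima that single-point spikes miss."""
    zs = np.sort(z)
    lo = min(float(zs[:2].mean()), -1e-3)
    hi = max(float(zs[-2:].mean()), 1e-3)
    return 0.04, 0.04, lo, hi, 2.0 * var_floor, 2.0 * var_floor


def _grid_starts(z: np.ndarray, var_floor: float) -> list:
    """Deterministic sweep over tail cut-offs and component-variance scales;
    reaches tight tail-cluster optima that moment-style starts smooth over."""
    starts = []
    for cut in (1.0, 1.5, 2.0, 2.5):
        lo_tail = z[z < -cut]
        hi_tail = z[z > cut]
        mu_m = float(lo_tail.mean()) if lo_tail.size else -cut
        mu_p = float(hi_tail.mean()) if hi_tail.size else cut
        pi_m = max(float(lo_tail.size) / z.size, 0.01)
        pi_p = max(float(hi_tail.size) / z.size, 0.01)
        for s0 in (2.0 * var_floor, 0.05, 1.0):
            starts.append((pi_m, pi_p, min(mu_m, -1e-3), max(mu_p, 1e-3), s0, s0))
    return starts


def _jittered_start(z: np.ndarray, rng: np.random.Generator, var_floor: float):
    """Randomised start: means at random quantiles of the data (interior
    positions included — narrow components inside the bulk are legitimate
    optima) and variances spanning the spike-to-bulk range, drawn per side."""
    q_lo = float(np.quantile(z, rng.uniform(0.01, 0.49)))
    q_hi = float(np.quantile(z, rng.uniform(0.51, 0.99)))
    v = max(float(np.var(z)), 0.05)
    pi_m = float(rng.uniform(0.02, 0.40))
    pi_p = float(rng.uniform(0.02, 0.40))
    s1 = float(np.exp(rng.uniform(np.log(var_floor), np.log(2.0 * v))))
    s2 = float(np.exp(rng.uniform(np.log(var_floor), np.log(2.0 * v))))
    return pi_m, pi_p, min(q_lo, -1e-3), max(q_hi, 1e-3), s1, s2


def _is_boundary(pi_m, pi_p, mu_m, mu_p, s1, s2, var_floor) -> bool:
    pi0 = 1.0 - pi_m - pi_p
    return (
        pi_m < 1e-9
        or pi_p < 1e-9
        or pi0 < 1e-9
        or mu_m == 0.0
        or mu_p == 0.0
        or s1 <= var_floor
        or s2 <= var_floor
    )


def _observed_information(z: np.ndarray, p: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Negative Hessian of the profile log-likelihood (pi_null eliminated)
    at ``p = (pi_neg, pi_pos, mu_neg, mu_pos, s1, s2)``, by central finite
    differences."""

    def f(q: np.ndarray) -> float:
        return _loglik6(z, q[0], q[1], q[2], q[3], q[4], q[5])

    n = p.size
    h = rel_step * np.maximum(1.0, np.abs(p))
    hess = np.empty((n, n))
    f0 = f(p)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        hess[i, i] = (f(p + ei) - 2.0 * f0 + f(p - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(p + ei + ej) - f(p + ei - ej) - f(p - ei + ej) + f(p - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return -hess


def fit_tgca_mixture(
    z: Sequence[float],
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    n_starts: int = N_STARTS,
    seed: Optional[int] = None,
    compute_cov: bool = True,
    var_floor: float = VAR_FLOOR,
) -> MixtureFit:
    """Fit the mixture to one SNP's adjusted Z-score vector.

    Runs ``n_starts`` EM runs (one moment-based start plus seeded jittered
    restarts) and keeps the best log-likelihood; ties are broken towards the
    smaller theta. Fitting never raises on numerical failure: a fit that
    cannot be completed is returned with ``converged=False`` or
    ``boundary_flag=True``.

    Parameters
    ----------
    z
        Adjusted Z-scores (length >= 10, all finite).
    compute_cov
        If True, compute the 6x6 free-parameter covariance from the inverse
        observed information at the optimum (skipped on boundary fits).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 10:
        raise ValueError("need a 1-d vector of at least 10 Z-scores")
    if not np.all(np.isfinite(z)):
        raise ValueError("Z-scores must be finite")
    rng = np.random.default_rng(seed)

    best = None
    best_key = (-np.inf, np.inf)  # (loglik, theta)
    deterministic = [
        _moment_start(z),
        _lazy_start(z),
        _spike_start(z, var_floor),
        _tight_moment_start(z),
        _cluster_spike_start(z, var_floor),
    ]
    if n_starts > len(deterministic):
        deterministic.extend(_grid_starts(z, var_floor))
    for s in range(max(1, n_starts)):
        if s < len(deterministic):
            start = deterministic[s]
        else:
            start = _jittered_start(z, rng, var_floor)
        out = _em_inner(z, *start, max_iter, tol, var_floor)
        pi_m, pi_p, mu_m, mu_p, s1, s2, ll, it, conv = out
        if not np.isfinite(ll):
            continue
        th = abs(pi_p * mu_p) + abs(pi_m * mu_m)
        better = ll > best_key[0] + 1e-9 or (
            abs(ll - best_key[0]) <= 1e-9 and th < best_key[1] - 1e-12
        )
        if best is None or better:
            best = out
            best_key = (ll, th)

    if best is None:
        # every restart diverged; report an unconverged null-like fit
        params = MixtureParams(0.0, 1.0, 0.0, -0.0, 0.0, 1.0, 1.0)
        return MixtureFit(params, float("nan"), 0, False, None, True)

    pi_m, pi_p, mu_m, mu_p, s1, s2, ll, it, conv = best
    boundary = _is_boundary(pi_m, pi_p, mu_m, mu_p, s1, s2, var_floor)
    params = MixtureParams(
        pi_neg=float(pi_m),
        pi_null=float(1.0 - pi_m - pi_p),
        pi_pos=float(pi_p),
        mu_neg=float(min(mu_m, 0.0)),
        mu_pos=float(max(mu_p, 0.0)),
        sigma2_1=float(s1),
        sigma2_2=float(s2),
    )
    cov = None
    if compute_cov and conv and not boundary:
        info = _observed_information(z, params.free_vector())
        cov = _invert_information(info)
        if cov is None:
            boundary = True
    return MixtureFit(params, float(ll), int(it), bool(conv), cov, bool(boundary))


def _invert_information(info: np.ndarray) -> Optional[np.ndarray]:
    """Invert the observed information; None when it is not positive definite
    (ill-conditioned likelihood surface near a boundary)."""
    if not np.all(np.isfinite(info)):
        return None
    try:
        np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        return None
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    if np.any(np.diag(cov) <= 0):
        return None
    return cov


# ---------------------------------------------------------------------------
# theta, delta-method SE and Wald test
# ---------------------------------------------------------------------------


def compute_theta(p: MixtureParams) -> float:
    """theta = |pi_pos mu_pos| + |pi_neg mu_neg|."""
    return abs(p.pi_pos * p.mu_pos) + abs(p.pi_neg * p.mu_neg)


def theta_se_delta(fit: MixtureFit) -> float:
    """Delta-method standard error of theta-hat.

    With mu_neg <= 0 <= mu_pos, theta = pi_pos mu_pos - pi_neg mu_neg, so the
    gradient in (pi_neg, pi_pos, mu_neg, mu_pos, s1, s2) is
    (-mu_neg, mu_pos, -pi_neg, pi_pos, 0, 0).
    """
    if fit.boundary_flag or fit.param_cov is None:
        raise ValueError(
            "standard error unavailable: fit is on a constraint boundary or "
            "the information matrix could not be inverted"
        )
    p = fit.params
    g = np.array([-p.mu_neg, p.mu_pos, -p.pi_neg, p.pi_pos, 0.0, 0.0])
    var = float(g @ fit.param_cov @ g)
    return float(np.sqrt(max(var, 0.0)))


def wald_test_theta(theta: float, se: float) -> float:
    """Two-sided Wald p-value for H0: theta = 0, via chi-square(1)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(stats.chi2.sf((theta / se) ** 2, df=1))


# ---------------------------------------------------------------------------
# genome-wide driver
# ---------------------------------------------------------------------------


def snp_seed(master_seed: int, snp_id: str) -> int:
    """Deterministic per-SNP seed, invariant to SNP ordering."""
    h = hashlib.sha256(f"{master_seed}:{snp_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def fit_genome(
    s,
    d,
    master_seed: int = 0,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    n_starts: int = N_STARTS,
    compute_cov: bool = True,
) -> list[TGCAResult]:
    """Decorrelate a standardised SummaryStatSet and fit every SNP.

    Non-converged and boundary SNPs are retained in the output with their
    flags set and NaN inference fields; filtering is the caller's choice.
    """
    from .phenocorr import decorrelate  # local import to avoid a cycle

    if not getattr(s, "standardized", False):
        raise ValueError("summary statistics must be standardised before fitting")
    z_star = decorrelate(s.Z, d)
    results: list[TGCAResult] = []
    n_nonconv = 0
    n_boundary = 0
    for i, sid in enumerate(s.snp_ids):
        fit = fit_tgca_mixture(
            z_star[i],
            max_iter=max_iter,
            tol=tol,
            n_starts=n_starts,
            seed=snp_seed(master_seed, str(sid)),
            compute_cov=compute_cov,
        )
        theta = compute_theta(fit.params)
        se = z_th = p_th = float("nan")
        if fit.converged and not fit.boundary_flag and fit.param_cov is not None:
            se = theta_se_delta(fit)
            if se > 0:
                z_th = theta / se
                p_th = wald_test_theta(theta, se)
        if not fit.converged:
            n_nonconv += 1
        if fit.boundary_flag:
            n_boundary += 1
        results.append(
            TGCAResult(
                snp_id=str(sid),
                theta=float(theta),
                se_theta=se,
                z_theta=z_th,
                p_theta=p_th,
                fit=fit,
                chrom=str(s.chrom[i]) if s.chrom is not None else None,
                pos=int(s.pos[i]) if s.pos is not None else None,
            )
        )
    logger.info(
        "fit_genome: %d SNPs fitted (%d non-converged, %d boundary/no-SE)",
        len(results), n_nonconv, n_boundary,
    )
    return results
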