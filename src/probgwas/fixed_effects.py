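"""Linear and logistic association engines with Wald, LRT and score tests.

Linear model: E(Y) = X beta, var(Y) = sigma^2 I, with
beta_hat = (X'X)^{-1} X'Y, sigma2_hat = RSS / (N - r_X) where r_X is the
column rank of X, and var(beta_hat) = sigma2_hat (X'X)^{-1}.  Three variance
flavours are exposed:

* standard: residual variance estimated under the alternative;
* score: residual variance estimated under the SNP-free null (the
  ``--score`` option);
* robust: White/HC0 sandwich (X'X)^{-1} X'RX (X'X)^{-1} with R the diagonal
  of squared residuals (the ``--robust`` option).

Logistic model: E(Y) = expit(X beta), fitted by iteratively re-weighted
least squares; var(beta_hat) = (X'WX)^{-1} with W = diag(pi (1 - pi)), and
the HC0 sandwich (X'WX)^{-1} X'RX (X'WX)^{-1} with R = diag((y - pi)^2).

Per-term significance uses the Wald statistic (beta/se)^2; the global test
of all SNP-involving terms is a likelihood-ratio test against the model with
those terms dropped (beta_g = 0), on as many degrees of freedom as there are
SNP terms (interactions included).  Genome-wide inflation is summarized by
the genomic-control factor lambda = median(T^2) / 0.455, the chi-square
1-df median.

Rank-deficient designs (monomorphic SNPs, collinear interactions) yield a
non-estimable result with NA fields rather than an exception, so a scan
never aborts on one bad SNP.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "FitResult",
    "LinearFit",
    "LogisticFit",
    "fit_linear",
    "loglik_normal",
    "wald_test",
    "lrt",
    "varcov_robust_linear",
    "fit_logistic",
    "varcov_robust_logistic",
    "score_variance_option",
    "score_test_linear",
    "genomic_control_lambda",
]

#: relative rank tolerance for singularity detection
RANK_RTOL = 1e-8

#: chi-square 1-df median used by genomic control
CHI2_1DF_MEDIAN = 0.455


@dataclasses.dataclass
class FitResult:
    """Per-SNP association summary (SNP terms only)."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    chi2_global: float
    df: int
    n_used: int
    converged: bool
    term_names: list[str] = dataclasses.field(default_factory=list)

    @classmethod
    def not_estimable(cls, term_names: list[str], n_used: int) -> "FitResult":
        q = len(term_names)
        return cls(
            beta=np.full(q, np.nan),
            se=np.full(q, np.nan),
            loglik=np.nan,
            chi2_global=np.nan,
            df=q,
            n_used=n_used,
            converged=False,
            term_names=list(term_names),
        )

    @property
    def pvalue_global(self) -> float:
        if np.isnan(self.chi2_global):
            return np.nan
        return float(stats.chi2.sf(self.chi2_global, self.df))


@dataclasses.dataclass
class LinearFit:
    """Full OLS fit internals for one design matrix."""

    beta_full: np.ndarray
    sigma2_hat: float
    varcov: np.ndarray
    residuals: np.ndarray
    rank: int
    loglik: float
    ok: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.varcov))


@dataclasses.dataclass
class LogisticFit:
    beta_full: np.ndarray
    varcov: np.ndarray
    fitted: np.ndarray  # pi_hat
    loglik: float
    n_iter: int
    converged: bool
    ok: bool


def _rank_and_solve(X: np.ndarray, Y: np.ndarray):
    """Least squares with explicit rank detection; None if rank-deficient."""
    n, k = X.shape
    if n <= k:
        return None
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=RANK_RTOL)
    if rank < k:
        return None
    return beta, rank


def fit_linear(Y: np.ndarray, X: np.ndarray) -> LinearFit:
    """Ordinary least squares with MLE coefficients and (N - r_X) variance.

    A singular X'X (monomorphic SNP, duplicated column) produces an
    ``ok=False`` fit with NaN fields instead of raising.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    sol = _rank_and_solve(X, Y)
    if sol is None:
        return LinearFit(
            np.full(k, np.nan), np.nan, np.full((k, k), np.nan),
            np.full(n, np.nan), 0, np.nan, ok=False,
        )
    beta, rank = sol
    resid = Y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - rank)
    xtx_inv = np.linalg.inv(X.T @ X)
    varcov = sigma2 * xtx_inv
    # log-likelihood at the MLE variance RSS/N, per the normal likelihood
    sigma2_ml = max(rss / n, np.finfo(float).tiny)
    ll = loglik_normal(Y, X, beta, sigma2_ml)
    return LinearFit(beta, sigma2, varcov, resid, rank, ll, ok=True)


def loglik_normal(Y, X, beta, sigma2: float) -> float:
    """Gaussian log-likelihood -N/2 log(2 pi sigma^2) - RSS/(2 sigma^2)."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    Y = np.asarray(Y, dtype=float)
    r = Y - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    n = Y.shape[0]
    return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - (r @ r) / (2.0 * sigma2))


def wald_test(beta_g: np.ndarray, varcov_gg: np.ndarray) -> tuple[float, int]:
    """Joint Wald statistic beta' var(beta)^{-1} beta and its df."""
    beta_g = np.atleast_1d(np.asarray(beta_g, dtype=float))
    varcov_gg = np.atleast_2d(np.asarray(varcov_gg, dtype=float))
    df = beta_g.shape[0]
    if not np.isfinite(varcov_gg).all():
        return np.nan, df
    try:
        chi2 = float(beta_g @ np.linalg.solve(varcov_gg, beta_g))
    except np.linalg.LinAlgError:
        return np.nan, df
    return chi2, df


def lrt(loglik_alt: float, loglik_null: float, df: int) -> tuple[float, int]:
    """Likelihood-ratio statistic 2 (l_alt - l_null)."""
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -1e-6:
        return np.nan, df
    return max(stat, 0.0), df


def varcov_robust_linear(X: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """White sandwich (HC0): (X'X)^{-1} X'RX (X'X)^{-1}, R = diag(r_i^2).

    With constant r_i^2 = sigma2_hat this reduces to the standard estimator.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(residuals, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = (X * (r * r)[:, None]).T @ X
    return xtx_inv @ meat @ xtx_inv


def fit_logistic(
    Y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Logistic regression by IRLS.

    Starts from beta = 0 with the intercept at logit(mean(Y)); converges on
    |delta deviance| < tol.  Complete separation is reported as a
    non-converged fit (coefficients diverge) rather than an exception.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    bad = LogisticFit(
        np.full(k, np.nan), np.full((k, k), np.nan), np.full(n, np.nan),
        np.nan, 0, converged=False, ok=False,
    )
    ybar = Y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return bad
    if _rank_and_solve(X, Y) is None:
        return bad

    beta = np.zeros(k)
    beta[0] = np.log(ybar / (1.0 - ybar))  # assumes intercept first
    dev_old = np.inf
    converged = False
    pi = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1.0 - pi)
        z = eta + (Y - pi) / np.maximum(w, 1e-12)
        xw = X * w[:, None]
        try:
            beta = np.linalg.solve(xw.T @ X, xw.T @ z)
        except np.linalg.LinAlgError:
            return bad
        eta = np.clip(X @ beta, -30.0, 30.0)
        pi = 1.0 / (1.0 + np.exp(-eta))
        ll = float(Y @ np.log(np.maximum(pi, 1e-300))
                   + (1.0 - Y) @ np.log(np.maximum(1.0 - pi, 1e-300)))
        dev = -2.0 * ll
        if abs(dev_old - dev) < tol:
            converged = True
            break
        dev_old = dev
    w = pi * (1.0 - pi)
    xwx = (X * w[:, None]).T @ X
    try:
        varcov = np.linalg.inv(xwx)
    except np.linalg.LinAlgError:
        return bad
    # flag quasi-separation: some weights numerically zero and huge betas
    if converged and np.abs(beta).max() > 25.0:
        converged = False
    ll = float(Y @ np.log(np.maximum(pi, 1e-300))
               + (1.0 - Y) @ np.log(np.maximum(1.0 - pi, 1e-300)))
    return LogisticFit(beta, varcov, pi, ll, it, converged, ok=True)


def varcov_robust_logistic(X: np.ndarray, fitted: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Logistic HC0 sandwich: (X'WX)^{-1} X'RX (X'WX)^{-1}, R = diag((y-pi)^2)."""
    X = np.asarray(X, dtype=float)
    pi = np.asarray(fitted, dtype=float)
    w = pi * (1.0 - pi)
    bread = np.linalg.inv((X * w[:, None]).T @ X)
    r2 = (np.asarray(Y, dtype=float) - pi) ** 2
    meat = (X * r2[:, None]).T @ X
    return bread @ meat @ bread


def score_variance_option(
    Y: np.ndarray, X: np.ndarray, snp_cols: np.ndarray
) -> np.ndarray:
    """Variance-covariance of the full coefficient vector with the residual
    variance taken from the SNP-free null fit (the ``--score`` option).

    ``snp_cols`` indexes the SNP-involving columns of ``X``; the remaining
    columns form the null design.
    """
    X = np.asarray(X, dtype=float)
    keep = np.setdiff1d(np.arange(X.shape[1]), np.asarray(snp_cols))
    null = fit_linear(np.asarray(Y, float), X[:, keep])
    if not null.ok:
        return np.full((X.shape[1], X.shape[1]), np.nan)
    return null.sigma2_hat * np.linalg.inv(X.T @ X)


def score_test_linear(
    Y: np.ndarray, Xg: np.ndarray, Xx: np.ndarray
) -> tuple[float, int]:
    """Rao score test of beta_g = 0 in the linear model.

    Uses null residuals and SNP columns orthogonalized against the null
    design, with the null residual variance (MLE divisor N).
    """
    Y = np.asarray(Y, dtype=float)
    Xg = np.atleast_2d(np.asarray(Xg, dtype=float))
    if Xg.shape[0] != Y.shape[0]:
        Xg = Xg.T
    Xx = np.asarray(Xx, dtype=float)
    null = fit_linear(Y, Xx)
    q = Xg.shape[1]
    if not null.ok:
        return np.nan, q
    proj = Xx @ np.linalg.lstsq(Xx, Xg, rcond=RANK_RTOL)[0]
    Xgc = Xg - proj
    sigma2_0 = float(null.residuals @ null.residuals) / Y.shape[0]
    u = Xgc.T @ null.residuals
    v = sigma2_0 * (Xgc.T @ Xgc)
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        return np.nan, q
    return chi2, q


def genomic_control_lambda(statistics: np.ndarray) -> float:
    """Genomic-control inflation factor: median 1-df statistic / 0.455."""
    statistics = np.asarray(statistics, dtype=float)
    statistics = statistics[np.isfinite(statistics)]
    if statistics.size == 0:
        raise ValueError("no finite statistics supplied")
    return float(np.median(statistics) / CHI2_1DF_MEDIAN)
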