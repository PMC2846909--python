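"""Two-step mixed-model score test for samples with differential relatedness.

Naive fixed-effects association in family-structured samples is inflated
because relatives share polygenic background.  The two-step remedy:

**Step 1** fits, once, the SNP-free polygenic model
``Y = Xx beta_x + G + e`` with ``var(Y) = Omega = sigma^2 ((1 - h2) I + h2 Phi)``,
where ``Phi`` is the relationship matrix (twice the kinship matrix) and
``h2`` the (narrow-sense) heritability, by maximum likelihood.  A single
eigendecomposition ``Phi = Q L Q'`` makes the profile likelihood over ``h2``
an O(n k) evaluation, so the fit costs one O(n^3) factorization total.

**Step 2** score-tests each SNP against the step-1 residuals
``r = Y - Xx beta_x_hat`` using the fitted inverse variance-covariance
``Omega_inv``:

    beta_g   = (Xg' Omega_inv Xg)^{-1} Xg' Omega_inv r
    var^{-1} = Xg' Omega_inv Xg
    T^2      = beta_g' (Xg' Omega_inv Xg) beta_g      ~  chi2(q)

In the scan, SNP columns are first orthogonalized against the base design in
the ``Omega_inv`` inner product (for an intercept-only base this is
Omega-weighted centering); this makes ``Xg' Omega_inv Xg`` the exact score
variance and the statistic chi-square calibrated under the null.

Kinship can come from a pedigree (recursive expectation) or from genome-wide
marker data via the allele-frequency-weighted estimator

    kinship_ij = 1/L sum_l (g_il - p_l)(g_jl - p_l) / (p_l (1 - p_l))

with genotypes coded 0, 1/2, 1 and ``p_l`` the frequency of the allele whose
homozygote is coded 1.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, TYPE_CHECKING

import numpy as np
from scipy import optimize

from .io_mach import DoseMatrix, ProbMatrix
from .design import dose_from_probs, nuisance_design

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Pedigree

__all__ = [
    "KinshipMatrix",
    "PolygenicFit",
    "MmscoreResult",
    "MmscoreScan",
    "genomic_kinship",
    "pedigree_kinship",
    "fit_polygenic",
    "mmscore_test",
    "mmscore_scan",
    "mmscore_pipeline",
]

#: loci with p outside this band are treated as monomorphic and skipped
KINSHIP_FREQ_BAND = (0.001, 0.999)


@dataclasses.dataclass
class KinshipMatrix:
    """Relationship matrix Phi = 2 x kinship, keyed by sample id."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match id list")
        if not np.allclose(self.phi, self.phi.T, atol=1e-8):
            raise ValueError("phi not symmetric")


@dataclasses.dataclass
class PolygenicFit:
    """Step-1 maximum-likelihood fit of the SNP-free polygenic model."""

    beta_x_hat: np.ndarray
    sigma2_hat: float
    h2_hat: float
    omega_inv: np.ndarray
    residuals: np.ndarray
    loglik: float
    flagged: bool  # h2 at boundary or likelihood flat in h2


@dataclasses.dataclass
class MmscoreResult:
    beta_g: np.ndarray
    varcov_g_inv: np.ndarray
    score_chi2: float
    df: int

    @property
    def se(self) -> np.ndarray:
        try:
            return np.sqrt(np.diag(np.linalg.inv(self.varcov_g_inv)))
        except np.linalg.LinAlgError:
            return np.full(self.beta_g.shape, np.nan)


@dataclasses.dataclass
class MmscoreScan:
    """Vectorized per-SNP mmscore output (additive 1-df tests)."""

    snp_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    n_used: np.ndarray
    df: int = 1


# ---------------------------------------------------------------------------
# kinship


def genomic_kinship(
    genotypes: np.ndarray,
    freqs: Optional[np.ndarray] = None,
    ids: Optional[list[str]] = None,
) -> KinshipMatrix:
    """Marker-based kinship from genotypes coded {0, 1/2, 1}.

    ``freqs`` is the per-locus frequency of the allele whose homozygote is
    coded 1; estimated from the data (half the column mean of dosage-coded
    genotypes equals the column mean here) when omitted.  Monomorphic loci
    are skipped.  Returns Phi = 2 x kinship.
    """
    G = np.asarray(genotypes, dtype=float)
    n, L = G.shape
    if freqs is None:
        freqs = G.mean(axis=0)
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = KINSHIP_FREQ_BAND
    use = (freqs > lo) & (freqs < hi)
    if not use.any():
        raise ValueError("all loci monomorphic; kinship not estimable")
    Gc = G[:, use] - freqs[use]
    w = 1.0 / np.sqrt(freqs[use] * (1.0 - freqs[use]))
    Z = Gc * w
    kinship = (Z @ Z.T) / use.sum()
    if ids is None:
        ids = [str(i) for i in range(n)]
    return KinshipMatrix(ids, 2.0 * kinship)


def pedigree_kinship(pedigree: "Pedigree") -> KinshipMatrix:
    """Expected kinship from parent links (recursive tabular method).

    Founders are assumed outbred and mutually unrelated:
    phi_ii = 0.5 (1 + phi_father,mother), phi_ij = 0.5 (phi_f(i),j + phi_m(i),j).
    Individuals must be ordered parents-before-children (validated).
    """
    father = np.asarray(pedigree.father, dtype=int)
    mother = np.asarray(pedigree.mother, dtype=int)
    n = len(father)
    for i in range(n):
        for p in (father[i], mother[i]):
            if p >= i:
                raise ValueError(
                    f"pedigree not topologically sorted (individual {i} has "
                    f"parent {p}); cyclic or out-of-order links"
                )
    kin = np.zeros((n, n))
    for i in range(n):
        f, m = father[i], mother[i]
        if f < 0 and m < 0:
            kin[i, i] = 0.5
        else:
            kf = kin[f, :i] if f >= 0 else 0.0
            km = kin[m, :i] if m >= 0 else 0.0
            kin[i, :i] = 0.5 * (kf + km)
            kin[:i, i] = kin[i, :i]
            kin[i, i] = 0.5 * (1.0 + (kin[f, m] if (f >= 0 and m >= 0) else 0.0))
    return KinshipMatrix(list(pedigree.ids), 2.0 * kin)


# ---------------------------------------------------------------------------
# step 1: polygenic model


def fit_polygenic(
    Y: np.ndarray,
    X_x: np.ndarray,
    phi: KinshipMatrix,
    h2_max: float = 0.99,
) -> PolygenicFit:
    """Maximize the Gaussian likelihood of Y ~ N(Xx beta, sigma^2 ((1-h2)I + h2 Phi)).

    beta and sigma^2 are profiled out analytically at each h2 (GLS estimate
    and mean weighted RSS); h2 is found by bounded 1-d search on [0, h2_max].
    Eigendecomposing Phi once makes each profile evaluation O(n k).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X_x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n < k + 2:
        raise ValueError("too few samples for the polygenic fit")
    evals, Q = np.linalg.eigh(phi.phi)
    Yt = Q.T @ Y
    Xt = Q.T @ X

    def profile(h2: float):
        d = (1.0 - h2) + h2 * evals
        if d.min() <= 1e-10:
            return None
        w = 1.0 / d
        xtwx = (Xt * w[:, None]).T @ Xt
        try:
            beta = np.linalg.solve(xtwx, (Xt * w[:, None]).T @ Yt)
        except np.linalg.LinAlgError:
            return None
        r = Yt - Xt @ beta
        rss_w = float((w * r * r).sum())
        sigma2 = rss_w / n
        ll = -0.5 * (
            n * np.log(2.0 * np.pi) + n * np.log(sigma2) + np.log(d).sum() + n
        )
        return ll, beta, sigma2, d

    def negll(h2: float) -> float:
        prof = profile(h2)
        return np.inf if prof is None else -prof[0]

    opt = optimize.minimize_scalar(
        negll, bounds=(0.0, h2_max), method="bounded",
        options={"xatol": 1e-6},
    )
    h2_hat = float(opt.x)
    prof = profile(h2_hat)
    if prof is None or not opt.success:
        raise RuntimeError(f"polygenic likelihood maximization failed: {opt}")
    ll, beta, sigma2, d = prof

    # boundary / flat-likelihood diagnostics (e.g. Phi = I: h2 unidentifiable)
    grid = np.array([negll(h) for h in (0.0, 0.25, 0.5, 0.75, h2_max)])
    flat = float(grid.max() - grid.min()) < 1e-6
    boundary = h2_hat < 1e-3 or h2_hat > h2_max - 1e-3

    omega_inv = (Q * (1.0 / (sigma2 * d))) @ Q.T
    residuals = Y - X @ beta
    return PolygenicFit(
        beta_x_hat=beta,
        sigma2_hat=sigma2,
        h2_hat=h2_hat,
        omega_inv=omega_inv,
        residuals=residuals,
        loglik=float(ll),
        flagged=flat or boundary,
    )


# ---------------------------------------------------------------------------
# step 2: score test


def mmscore_test(
    residuals: np.ndarray, omega_inv: np.ndarray, Xg: np.ndarray
) -> MmscoreResult:
    """Score test of one SNP design against step-1 residuals.

    Applies the estimating equations verbatim: beta_g = (Xg'W Xg)^{-1} Xg'W r
    with W = omega_inv, inverse variance Xg'W Xg, and the joint statistic
    beta_g' (Xg'W Xg) beta_g.  Callers that want the calibrated genome-scan
    statistic should orthogonalize Xg against the base design first (see
    :func:`mmscore_scan`).
    """
    r = np.asarray(residuals, dtype=float)
    Xg = np.asarray(Xg, dtype=float)
    if Xg.ndim == 1:
        Xg = Xg[:, None]
    q = Xg.shape[1]
    A = omega_inv @ Xg
    V = Xg.T @ A
    u = A.T @ r
    try:
        beta = np.linalg.solve(V, u)
    except np.linalg.LinAlgError:
        return MmscoreResult(np.full(q, np.nan), np.full((q, q), np.nan), np.nan, q)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        return MmscoreResult(np.full(q, np.nan), np.full((q, q), np.nan), np.nan, q)
    chi2 = float(beta @ V @ beta)
    return MmscoreResult(beta, V, chi2, q)


def _as_dose_matrix(geno) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(geno, ProbMatrix):
        return dose_from_probs(geno.p_AA, geno.p_AB), geno.missing, geno.snp_names
    if isinstance(geno, DoseMatrix):
        return geno.dose, geno.missing, geno.snp_names
    G = np.asarray(geno, dtype=float)
    return G, np.zeros(G.shape, dtype=bool), [str(j) for j in range(G.shape[1])]


def mmscore_scan(
    residuals: np.ndarray,
    omega_inv: np.ndarray,
    geno,
    X_x: Optional[np.ndarray] = None,
) -> MmscoreScan:
    """Additive mmscore test for every SNP column, vectorized.

    ``geno`` may be a DoseMatrix, ProbMatrix or plain (n, m) dose array.
    Each dose column is orthogonalized against ``X_x`` (default: intercept
    only) in the omega_inv inner product before the quadratic form, which is
    exactly the score-test variance of the SNP term.  Missing cells
    contribute nothing (projected value zero) and reduce ``n_used``.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.shape[0]
    G, missing, names = _as_dose_matrix(geno)
    if X_x is None:
        X_x = np.ones((n, 1))
    X_x = np.asarray(X_x, dtype=float)

    if missing.any():
        G = np.where(missing, np.nan, G)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(missing, col_mean, G)
    n_used = n - missing.sum(axis=0)

    B = omega_inv @ X_x                      # (n, k)
    M = np.linalg.inv(X_x.T @ B)             # (k, k)
    BtG = B.T @ G                            # (k, m)
    WG = omega_inv @ G - B @ (M @ BtG)       # Omega_inv @ (projected G)
    num = G.T @ (omega_inv @ r)              # Xg' W r (projection leaves it
    #                                          unchanged since Xx' W r = 0)
    den = np.einsum("ij,ij->j", G, WG)  # = Gc' W Gc (projection idempotent)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / den
        chi2 = num * num / den
        se = 1.0 / np.sqrt(den)
    bad = ~(den > 1e-12)
    beta[bad] = np.nan
    chi2[bad] = np.nan
    se[bad] = np.nan
    return MmscoreScan(names, beta, se, chi2, n_used)


def mmscore_pipeline(
    Y: np.ndarray,
    covariates: Optional[np.ndarray],
    geno,
    phi: Optional[KinshipMatrix] = None,
    omega_inv: Optional[np.ndarray] = None,
    residuals: Optional[np.ndarray] = None,
) -> tuple[MmscoreScan, Optional[PolygenicFit]]:
    """Full two-step scan.

    Either supply ``phi`` (step 1 is run internally: polygenic ML fit of Y on
    the covariates) or a precomputed ``omega_inv`` plus the step-1
    ``residuals`` (the externally-residualized phenotype); in the latter case
    ``Y`` is used as residuals when ``residuals`` is None.
    """
    if (phi is None) == (omega_inv is None):
        raise ValueError("supply exactly one of phi or omega_inv")
    pfit = None
    if phi is not None:
        X_x = nuisance_design(covariates) if covariates is not None and np.size(
            covariates
        ) else np.ones((len(Y), 1))
        pfit = fit_polygenic(np.asarray(Y, float), X_x, phi)
        omega_inv = pfit.omega_inv
        residuals = pfit.residuals
        base = X_x
    else:
        residuals = np.asarray(Y, float) if residuals is None else np.asarray(
            residuals, float
        )
        if covariates is not None and np.size(covariates):
            base = nuisance_design(covariates)
        else:
            base = np.ones((len(residuals), 1))
    scan = mmscore_scan(residuals, omega_inv, geno, X_x=base)
    return scan, pfit
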