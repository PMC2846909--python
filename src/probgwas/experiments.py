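"""End-to-end calibration experiments built from the library pieces.

These drivers reproduce the package's null-calibration study: simulate a
family-structured sample with the standard trait decomposition (10% + 5%
fixed effects, 25.5% polygenic via 200 causal SNPs, 59.5% residual), then
measure the behaviour of the association engines on independent null SNPs.
They exist so that the test suite and reproduction scripts exercise one
code path.

Problem sizes default to a desk-scale study: ~1,125 individuals in 150
three-generation families, a 20,000-locus kinship panel (standing in for a
dense genome-wide panel), and 50,000 null test SNPs with MAF >= 1% and
imputation quality drawn uniformly from [0.8, 1.0].
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import design, fixed_effects as fe, mixed, simulate

__all__ = [
    "NullCalibration",
    "null_calibration_experiment",
    "heritability_replicates",
    "variance_share_replicates",
    "summarize_statistics",
]


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclasses.dataclass
class NullCalibration:
    """Per-SNP 1-df statistics of each engine on the null test set."""

    n_samples: int
    n_snps: int
    h2_hat: float
    mmscore: np.ndarray
    linear: np.ndarray
    linear_robust: np.ndarray


def null_calibration_experiment(
    seed: int,
    n_families: int = 150,
    n_null: int = 50_000,
    kinship_loci: int = 20_000,
    spec: simulate.TraitSpec = simulate.TraitSpec(),
    quality_range: tuple[float, float] = (0.8, 1.0),
    maf_min: float = 0.01,
) -> NullCalibration:
    """Simulate the family null study and scan it with mmscore and naive OLS.

    Causal, kinship-panel and null-test loci are disjoint sets.  The naive
    scans regress the trait on dose plus the two fixed covariates, ignoring
    relatedness; mmscore runs the two-step mixed-model score test with a
    genomic kinship matrix estimated from the kinship panel.
    """
    s = _stage_seeds(seed, 7)
    ped = simulate.simulate_pedigree(n_families, seed=s[0])
    m_causal = spec.n_causal_snps
    # oversample null loci: the MAF filter discards some
    n_pool = int(n_null * 1.25)
    freqs = np.concatenate([
        simulate.draw_founder_freqs(m_causal + kinship_loci, seed=s[1]),
        simulate.draw_founder_freqs(n_pool, seed=s[2], low=0.01, high=0.5),
    ])
    G = simulate.gene_drop(ped, freqs, seed=s[3])
    causal_idx = np.arange(m_causal)
    pheno, _, _ = simulate.simulate_trait(ped, G, spec=spec, seed=s[4],
                                          causal_idx=causal_idx)

    phi = mixed.genomic_kinship(G[:, m_causal:m_causal + kinship_loci])
    X_x = design.nuisance_design(pheno.covariates)
    pfit = mixed.fit_polygenic(pheno.outcome, X_x, phi)

    G_null = G[:, m_causal + kinship_loci:]
    maf = np.minimum(G_null.mean(axis=0), 1 - G_null.mean(axis=0))
    G_null = G_null[:, maf >= maf_min][:, :n_null]
    quality = np.random.default_rng(s[5]).uniform(*quality_range,
                                                  G_null.shape[1])
    probs = simulate.blur_to_probabilities(G_null, quality, seed=s[6])
    dose = design.dose_from_probs(probs.p_AA, probs.p_AB)

    scan = mixed.mmscore_scan(pfit.residuals, pfit.omega_inv, dose, X_x=X_x)

    # naive fixed-effects Wald statistics (standard and robust variance)
    n, m = dose.shape
    Y = pheno.outcome
    t_std = np.empty(m)
    t_rob = np.empty(m)
    for j in range(m):
        X = np.column_stack([dose[:, j], X_x])
        fit = fe.fit_linear(Y, X)
        if not fit.ok:
            t_std[j] = t_rob[j] = np.nan
            continue
        t_std[j] = (fit.beta_full[0] / fit.se[0]) ** 2
        vr = fe.varcov_robust_linear(X, fit.residuals)
        t_rob[j] = fit.beta_full[0] ** 2 / vr[0, 0]

    return NullCalibration(
        n_samples=n, n_snps=m, h2_hat=pfit.h2_hat,
        mmscore=scan.chi2, linear=t_std, linear_robust=t_rob,
    )


def summarize_statistics(stats_1df: np.ndarray) -> dict[str, float]:
    """lambda, mean and tail exceedance rates of 1-df statistics."""
    from scipy import stats as sps

    t = np.asarray(stats_1df, dtype=float)
    t = t[np.isfinite(t)]
    return {
        "lambda": fe.genomic_control_lambda(t),
        "mean": float(t.mean()),
        "type1_at_05": float((t > sps.chi2.ppf(0.95, 1)).mean()),
        "type1_at_01": float((t > sps.chi2.ppf(0.99, 1)).mean()),
        "n_snps": int(t.size),
    }


def heritability_replicates(
    seed: int,
    n_replicates: int = 20,
    n_families: int = 80,
    n_loci: int = 400,
    spec: simulate.TraitSpec = simulate.TraitSpec(),
) -> np.ndarray:
    """Step-1 ML heritability estimates over independent replicates.

    Each replicate simulates ~600 individuals (80 three-generation
    families), draws the trait under the standard decomposition, and fits
    the polygenic model with the expected (pedigree) relationship matrix,
    adjusting for the two fixed covariates.
    """
    out = np.empty(n_replicates)
    seeds = _stage_seeds(seed, 4 * n_replicates)
    for r in range(n_replicates):
        s = seeds[4 * r:4 * r + 4]
        ped = simulate.simulate_pedigree(n_families, seed=s[0])
        freqs = simulate.draw_founder_freqs(n_loci, seed=s[1])
        G = simulate.gene_drop(ped, freqs, seed=s[2])
        pheno, _, _ = simulate.simulate_trait(ped, G, spec=spec, seed=s[3])
        pfit = mixed.fit_polygenic(
            pheno.outcome, design.nuisance_design(pheno.covariates),
            mixed.pedigree_kinship(ped),
        )
        out[r] = pfit.h2_hat
    return out


def variance_share_replicates(
    seed: int,
    n_replicates: int = 200,
    n_families: int = 80,
    n_loci: int = 400,
    spec: simulate.TraitSpec = simulate.TraitSpec(),
) -> np.ndarray:
    """Empirical polygenic share var(polygenic)/var(trait) per replicate."""
    s = _stage_seeds(seed, 3 + n_replicates)
    ped = simulate.simulate_pedigree(n_families, seed=s[0])
    freqs = simulate.draw_founder_freqs(n_loci, seed=s[1])
    G = simulate.gene_drop(ped, freqs, seed=s[2])
    shares = np.empty(n_replicates)
    for r in range(n_replicates):
        pheno, comps, _ = simulate.simulate_trait(ped, G, spec=spec, seed=s[3 + r])
        shares[r] = comps["polygenic"].var() / pheno.outcome.var()
    return shares
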