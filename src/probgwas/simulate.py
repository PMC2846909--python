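"""Synthetic family data for calibration studies.

Emulates the ingredients of a null-calibration experiment in a sample with
differential relatedness:

* a pedigree of extended families (founders, sibs, grandchildren,
  avuncular pairs), parameterized rather than copied from any real cohort;
* genotypes gene-dropped through the pedigree: founders drawn from
  Hardy-Weinberg proportions, offspring inheriting one random parental
  allele per locus, loci independent (no linkage disequilibrium);
* imputation-style posterior genotype probabilities obtained by Dirichlet
  perturbation of the true genotype, with the concentration solved so that
  the squared correlation between expected dose and true dose matches a
  requested quality r^2;
* a quantitative trait composed of four independent parts with a fixed
  variance decomposition: two fixed covariate effects (10% and 5% of total
  variance), a polygenic effect carried by 200 causal SNPs (25.5%), and
  Gaussian noise (59.5%) — so the covariate-adjusted heritability is 30%.

Every operation is deterministic given its seed; one root seed can be
fanned out to per-stage streams with :func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Sequence

import numpy as np

from . import io_mach
from .design import dose_from_probs
from .io_mach import PhenoTable, ProbMatrix, SnpInfo

__all__ = [
    "Pedigree",
    "TraitSpec",
    "simulate_pedigree",
    "draw_founder_freqs",
    "gene_drop",
    "blur_to_probabilities",
    "simulate_trait",
    "make_null_testset",
]


@dataclasses.dataclass
class Pedigree:
    """Parent links; index -1 marks a founder parent slot."""

    ids: list[str]
    father: np.ndarray  # (n,) int, index into ids or -1
    mother: np.ndarray
    generation: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.father = np.asarray(self.father, dtype=int)
        self.mother = np.asarray(self.mother, dtype=int)
        self.generation = np.asarray(self.generation, dtype=int)
        n = len(self.ids)
        if not (len(self.father) == len(self.mother) == len(self.generation) == n):
            raise ValueError("pedigree arrays must match id list length")
        for i in range(n):
            if self.father[i] >= i or self.mother[i] >= i:
                raise ValueError("parents must precede children")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.father < 0) & (self.mother < 0)


@dataclasses.dataclass
class TraitSpec:
    """Variance decomposition of the simulated trait (shares of total)."""

    var_fixed1: float = 0.10
    var_fixed2: float = 0.05
    var_polygenic: float = 0.255
    var_residual: float = 0.595
    n_causal_snps: int = 200

    def __post_init__(self) -> None:
        total = (
            self.var_fixed1 + self.var_fixed2 + self.var_polygenic + self.var_residual
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance components sum to {total}, not 1")

    @property
    def adjusted_h2(self) -> float:
        """Heritability after adjusting for the fixed effects."""
        return self.var_polygenic / (self.var_polygenic + self.var_residual)


def simulate_pedigree(
    n_families: int,
    family_type: str = "three_generation",
    seed: int = 0,
) -> Pedigree:
    """Deterministic pedigree of ``n_families`` independent families.

    ``three_generation``: grandparent couple, two generation-1 sibs, a
    founder spouse for the first, and 2-3 grandchildren (~7.5 members,
    giving sib, parent-offspring, grandparent and avuncular pairs).
    ``sibship``: two founder parents and 2-3 children.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    father: list[int] = []
    mother: list[int] = []
    gen: list[int] = []

    def add(fam: int, tag: str, f: int, m: int, g: int) -> int:
        ids.append(f"F{fam}_{tag}")
        father.append(f)
        mother.append(m)
        gen.append(g)
        return len(ids) - 1

    for fam in range(n_families):
        if family_type == "three_generation":
            gp_f = add(fam, "gpf", -1, -1, 0)
            gp_m = add(fam, "gpm", -1, -1, 0)
            c1 = add(fam, "c1", gp_f, gp_m, 1)
            add(fam, "c2", gp_f, gp_m, 1)
            sp = add(fam, "sp1", -1, -1, 1)
            for j in range(int(rng.integers(2, 4))):
                add(fam, f"g{j}", c1, sp, 2)
        elif family_type == "sibship":
            p_f = add(fam, "f", -1, -1, 0)
            p_m = add(fam, "m", -1, -1, 0)
            for j in range(int(rng.integers(2, 4))):
                add(fam, f"c{j}", p_f, p_m, 1)
        else:
            raise ValueError(f"unknown family_type {family_type!r}")
    return Pedigree(ids, np.array(father), np.array(mother), np.array(gen))


def draw_founder_freqs(
    L: int, seed: int = 0, low: float = 0.05, high: float = 0.5
) -> np.ndarray:
    """Founder frequencies of the allele coded 1, uniform on [low, high]."""
    return np.random.default_rng(seed).uniform(low, high, size=L)


def gene_drop(
    pedigree: Pedigree, founder_freqs: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Drop alleles through the pedigree; returns genotypes coded {0, 1/2, 1}.

    Founders are drawn from Hardy-Weinberg proportions at each locus;
    offspring inherit one uniformly chosen allele from each parent; loci are
    independent.
    """
    p = np.asarray(founder_freqs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("founder frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    n, L = pedigree.n, p.shape[0]
    a1 = np.zeros((n, L), dtype=np.uint8)
    a2 = np.zeros((n, L), dtype=np.uint8)
    for i in range(n):
        f, m = pedigree.father[i], pedigree.mother[i]
        if f < 0:
            a1[i] = rng.random(L) < p
        else:
            pick = rng.integers(0, 2, size=L, dtype=np.uint8)
            a1[i] = np.where(pick == 1, a1[f], a2[f])
        if m < 0:
            a2[i] = rng.random(L) < p
        else:
            pick = rng.integers(0, 2, size=L, dtype=np.uint8)
            a2[i] = np.where(pick == 1, a1[m], a2[m])
    return (a1.astype(np.float64) + a2) / 2.0


def _dirichlet_concentration(quality: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Concentration c such that corr^2(expected dose, true dose) == quality.

    The posterior row for true genotype g is Dirichlet(c * onehot(g) + pi)
    with pi the Hardy-Weinberg prior at allele-1 frequency p.  The moments
    of the implied dose are available in closed form, so c is found by
    bisection on log(c), vectorized over loci.
    """
    quality = np.asarray(quality, dtype=float)
    p = np.asarray(p, dtype=float)
    q2 = 1.0 - p
    pi = np.stack([p * p, 2 * p * q2, q2 * q2], axis=-1)  # (L, 3): AA, AB, BB
    x = np.array([2.0, 1.0, 0.0])
    var_x = 2 * p * q2
    dose_pi = 2 * p

    def r2(logc: np.ndarray) -> np.ndarray:
        c = np.exp(logc)
        a0 = c + 1.0
        between = (c / a0) ** 2 * var_x
        within = np.zeros_like(p)
        for g in range(3):
            m = pi / a0[..., None]
            m[..., g] += c / a0
            mA, mH = m[..., 0], m[..., 1]
            v = (4 * mA * (1 - mA) + mH * (1 - mH) - 4 * mA * mH) / (c + 2.0)
            within = within + pi[..., g] * v
        return between / (between + within)

    lo = np.full(p.shape, -8.0)
    hi = np.full(p.shape, 16.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = r2(mid) < quality
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return np.exp(0.5 * (lo + hi))


def blur_to_probabilities(
    genotypes: np.ndarray,
    quality,
    seed: int = 0,
    freqs: Optional[np.ndarray] = None,
    sample_ids: Optional[list[str]] = None,
    snp_names: Optional[list[str]] = None,
    chunk: int = 4096,
) -> ProbMatrix:
    """Imputation-style posterior probabilities around true genotypes.

    ``quality`` (scalar or per-SNP vector, in (0, 1]) is the target squared
    correlation between the expected dose and the true dose.  quality == 1
    gives exact one-hot rows.  Rows sum to 1 by construction.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    quality = np.broadcast_to(np.asarray(quality, dtype=float), (m,)).copy()
    if ((quality <= 0) | (quality > 1)).any():
        raise ValueError("quality must lie in (0, 1]")
    if freqs is None:
        freqs = G.mean(axis=0).clip(1e-3, 1 - 1e-3)
    rng = np.random.default_rng(seed)
    # genotype class per cell: 0=AA (g=1), 1=AB (g=1/2), 2=BB (g=0)
    cls = np.rint(2.0 * (1.0 - G)).astype(np.int8)

    exact = quality >= 1.0 - 1e-12
    conc = np.ones(m)
    if (~exact).any():
        conc[~exact] = _dirichlet_concentration(quality[~exact], freqs[~exact])

    p_AA = np.empty((n, m))
    p_AB = np.empty((n, m))
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        sl = slice(j0, j1)
        pj, cj = freqs[sl], conc[sl]
        pi = np.stack([pj * pj, 2 * pj * (1 - pj), (1 - pj) ** 2], axis=-1)
        alpha = np.broadcast_to(pi, (n, j1 - j0, 3)).copy()
        idx = cls[:, sl]
        np.put_along_axis(
            alpha, idx[..., None], np.take_along_axis(alpha, idx[..., None], -1)
            + cj[None, :, None], -1,
        )
        draws = rng.gamma(shape=alpha)
        draws /= draws.sum(axis=-1, keepdims=True)
        ex = exact[sl]
        if ex.any():
            onehot = np.eye(3)[idx[:, ex]]
            draws[:, ex, :] = onehot
        p_AA[:, sl] = draws[..., 0]
        p_AB[:, sl] = draws[..., 1]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if snp_names is None:
        snp_names = [f"snp{j}" for j in range(m)]
    return ProbMatrix(list(sample_ids), list(snp_names), p_AA, p_AB)


def simulate_trait(
    pedigree: Pedigree,
    genotypes: np.ndarray,
    spec: TraitSpec = TraitSpec(),
    seed: int = 0,
    causal_idx: Optional[np.ndarray] = None,
) -> tuple[PhenoTable, dict[str, np.ndarray], np.ndarray]:
    """Quantitative trait = fixed1 + fixed2 + polygenic + residual.

    The polygenic part is carried by ``spec.n_causal_snps`` randomly chosen
    polymorphic loci with equal per-SNP variance contributions and random
    effect signs; each of the four components is scaled to its exact sample
    variance share, so the decomposition holds empirically per replicate up
    to the (small) sampling covariance between components.

    Returns the phenotype table (trait + the two covariates), the component
    arrays, and the causal locus indices.
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes, dtype=float)
    n, L = G.shape
    if n != pedigree.n:
        raise ValueError("genotype rows do not match pedigree size")

    if causal_idx is None:
        poly_ok = np.flatnonzero(G.std(axis=0) > 0)
        if poly_ok.size < spec.n_causal_snps:
            raise ValueError(
                f"only {poly_ok.size} polymorphic loci for "
                f"{spec.n_causal_snps} causal SNPs"
            )
        causal_idx = rng.choice(poly_ok, size=spec.n_causal_snps, replace=False)
    causal_idx = np.asarray(causal_idx)

    def scaled(v: np.ndarray, share: float) -> np.ndarray:
        if share == 0.0:
            return np.zeros(n)
        sd = v.std()
        if sd == 0:
            raise ValueError("degenerate component")
        return np.sqrt(share) * (v - v.mean()) / sd

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    fixed1 = scaled(z1, spec.var_fixed1)
    fixed2 = scaled(z2, spec.var_fixed2)

    if causal_idx.size and spec.var_polygenic > 0:
        dose = 2.0 * G[:, causal_idx]
        signs = rng.choice([-1.0, 1.0], size=causal_idx.size)
        w = signs / np.maximum(dose.std(axis=0), 1e-12)
        poly = scaled(dose @ w, spec.var_polygenic)
    else:
        poly = np.zeros(n)
    resid = scaled(rng.standard_normal(n), spec.var_residual)

    trait = fixed1 + fixed2 + poly + resid
    pheno = PhenoTable(
        sample_ids=list(pedigree.ids),
        outcome_kind="quantitative",
        outcome=trait,
        covariates=np.column_stack([z1, z2]),
        covariate_names=["covar1", "covar2"],
        missing=np.zeros(n, dtype=bool),
    )
    components = {
        "fixed1": fixed1,
        "fixed2": fixed2,
        "polygenic": poly,
        "residual": resid,
    }
    return pheno, components, causal_idx


def make_null_testset(
    genotypes: np.ndarray,
    out_dir,
    m: int,
    sample_ids: Optional[Sequence[str]] = None,
    maf_min: float = 0.01,
    quality_range: tuple[float, float] = (0.8, 1.0),
    seed: int = 0,
    prefix: str = "null",
) -> tuple[str, str, str]:
    """Write a null (non-causal) SNP test set as mlinfo/mldose/mlprob files.

    Loci are drawn from ``genotypes`` columns whose estimated minor-allele
    frequency is at least ``maf_min``, blurred with per-SNP quality drawn
    uniformly from ``quality_range``.  Returns the three file paths.
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes, dtype=float)
    n, L = G.shape
    freq1 = G.mean(axis=0)
    maf = np.minimum(freq1, 1 - freq1)
    eligible = np.flatnonzero(maf >= maf_min)
    if eligible.size < m:
        raise ValueError(f"only {eligible.size} loci pass MAF >= {maf_min}, need {m}")
    pick = np.sort(rng.choice(eligible, size=m, replace=False))
    quality = rng.uniform(*quality_range, size=m)
    names = [f"{prefix}_rs{j}" for j in range(m)]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]

    probs = blur_to_probabilities(
        G[:, pick],
        quality,
        seed=int(rng.integers(2**31)),
        freqs=freq1[pick].clip(1e-3, 1 - 1e-3),
        sample_ids=list(sample_ids),
        snp_names=names,
    )
    dose = dose_from_probs(probs.p_AA, probs.p_AB)
    est_freq1 = dose.mean(axis=0) / 2.0

    info = [
        SnpInfo(
            snp_name=names[j],
            allele1="A",
            allele2="B",
            freq1=round(float(est_freq1[j]), 6),
            maf=round(float(min(est_freq1[j], 1 - est_freq1[j])), 6),
            quality=round(float(quality[j]), 6),
            rsq=round(float(quality[j]), 6),
        )
        for j in range(m)
    ]
    os.makedirs(out_dir, exist_ok=True)
    info_path = os.path.join(out_dir, f"{prefix}.mlinfo")
    dose_path = os.path.join(out_dir, f"{prefix}.mldose")
    prob_path = os.path.join(out_dir, f"{prefix}.mlprob")
    io_mach.write_mlinfo(info, info_path)
    io_mach.write_mldose(
        io_mach.DoseMatrix(
            list(sample_ids), names, dose, np.zeros(dose.shape, dtype=bool)
        ),
        dose_path,
    )
    io_mach.write_mlprob(probs, prob_path)
    return info_path, dose_path, prob_path
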