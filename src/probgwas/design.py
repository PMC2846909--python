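"""SNP design-matrix construction from posterior probabilities or dosages.

The general genotypic model regresses on two columns, (P_AA, P_AB), giving
the 2-df effect vector (beta_AA, beta_AB) relative to the BB reference.
Restricted single-df sub-models follow by constraining those coefficients:

=============  =======================  =================
model          constraint               predictor column
=============  =======================  =================
genotypic2df   none                     [P_AA, P_AB]
additive       beta_AA = 2 beta_AB      P_AB + 2 P_AA  (the allele-A dose)
dominantB      beta_AB = 0              P_AA
recessiveB     beta_AA = beta_AB        P_AA + P_AB
overdominant   beta_AA = 0              P_AB
=============  =======================  =================

Only the additive model is available from a dosage file; every other model
needs the two-probability representation.

An optional gene-environment interaction multiplies every SNP column by a
chosen covariate (elementwise, i.e. by the diagonal matrix W of covariate
values), doubling the degrees of freedom of the global SNP test.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Union

import numpy as np

from .io_mach import DoseMatrix, ProbMatrix

__all__ = [
    "GeneticModel",
    "DesignBundle",
    "UsageError",
    "dose_from_probs",
    "build_snp_design",
    "nuisance_design",
    "add_interaction",
]


class UsageError(ValueError):
    """Inconsistent user request (flags, model/input mismatch, bad index)."""


class GeneticModel(str, enum.Enum):
    ADDITIVE = "additive"
    GENOTYPIC_2DF = "genotypic2df"
    DOMINANT_B = "dominantB"
    RECESSIVE_B = "recessiveB"
    OVERDOMINANT = "overdominant"


#: models that require the (P_AA, P_AB) representation
_NEEDS_PROBS = {
    GeneticModel.GENOTYPIC_2DF,
    GeneticModel.DOMINANT_B,
    GeneticModel.RECESSIVE_B,
    GeneticModel.OVERDOMINANT,
}


@dataclasses.dataclass
class DesignBundle:
    """Per-SNP design: SNP columns Xg, nuisance columns Xx (with intercept)."""

    Xg: np.ndarray  # (n, q)
    Xx: np.ndarray  # (n, 1 + k), first column ones
    term_names: list[str]
    interaction_col: int | None = None  # 1-based covariate index, if applied

    def __post_init__(self) -> None:
        if self.Xx.ndim != 2 or not np.allclose(self.Xx[:, 0], 1.0):
            raise UsageError("nuisance design must start with an intercept column")
        if self.Xg.shape[0] != self.Xx.shape[0]:
            raise UsageError("Xg and Xx row counts differ")
        if self.Xg.shape[1] != len(self.term_names):
            raise UsageError("term_names length does not match Xg columns")


def dose_from_probs(p_AA, p_AB):
    """Expected allele-A count: P_AB + 2*P_AA, in [0, 2]."""
    p_AA = np.asarray(p_AA, dtype=float)
    p_AB = np.asarray(p_AB, dtype=float)
    return p_AB + 2.0 * p_AA


def build_snp_design(
    geno: Union[DoseMatrix, ProbMatrix],
    snp_index: int,
    model: GeneticModel = GeneticModel.ADDITIVE,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """SNP predictor columns for one SNP.

    Returns ``(Xg, term_names, missing)`` where ``Xg`` is (n, q) and
    ``missing`` flags samples with no genotype data at this SNP.
    """
    model = GeneticModel(model)
    if isinstance(geno, DoseMatrix):
        if model in _NEEDS_PROBS:
            raise UsageError(
                f"model {model.value!r} requires genotype probabilities "
                "(mlprob input), not dosages"
            )
        col = geno.dose[:, snp_index]
        return col[:, None], ["SNP_add"], geno.missing[:, snp_index].copy()

    pa = geno.p_AA[:, snp_index]
    pb = geno.p_AB[:, snp_index]
    missing = geno.missing[:, snp_index].copy()
    if model is GeneticModel.ADDITIVE:
        return dose_from_probs(pa, pb)[:, None], ["SNP_add"], missing
    if model is GeneticModel.GENOTYPIC_2DF:
        return np.column_stack([pa, pb]), ["SNP_AA", "SNP_AB"], missing
    if model is GeneticModel.DOMINANT_B:
        return pa[:, None], ["SNP_domB"], missing
    if model is GeneticModel.RECESSIVE_B:
        return (pa + pb)[:, None], ["SNP_recB"], missing
    if model is GeneticModel.OVERDOMINANT:
        return pb[:, None], ["SNP_overdom"], missing
    raise UsageError(f"unknown genetic model {model!r}")  # pragma: no cover


def nuisance_design(covariates: np.ndarray) -> np.ndarray:
    """Prepend the intercept column to the covariate matrix."""
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def add_interaction(bundle: DesignBundle, col: int) -> DesignBundle:
    """Append SNP-by-covariate columns W @ Xg for covariate number ``col``.

    ``col`` is 1-based over the phenotype-file covariates (excluding id and
    outcome), i.e. it indexes ``Xx[:, col]`` past the intercept.  The
    covariate's main effect must already be present in Xx — that holds by
    construction here, and keeps the interaction model hierarchical.
    """
    k = bundle.Xx.shape[1] - 1
    if not (1 <= col <= k):
        raise UsageError(
            f"--interaction {col} out of range: phenotype file has {k} covariate(s)"
        )
    w = bundle.Xx[:, col]
    inter = bundle.Xg * w[:, None]
    return DesignBundle(
        Xg=np.column_stack([bundle.Xg, inter]),
        Xx=bundle.Xx,
        term_names=bundle.term_names + [t + "_int" for t in bundle.term_names],
        interaction_col=col,
    )
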