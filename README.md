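# probgwas

Genome-wide association analysis of **imputed** SNP data: regression of
quantitative, binary and time-to-event traits on posterior genotype
probabilities or allelic dosages, with robust and null-variance options, and
a fast **two-step mixed-model score test** for samples with differential
relatedness (family studies, genetic isolates, outbred animal populations).

## The problem

Genotype imputation yields, for each person and SNP, a posterior
distribution P<sub>g</sub> = (P<sub>AA</sub>, P<sub>AB</sub>, P<sub>BB</sub>)
rather than a hard genotype call. Using the best-guess genotype biases
effect estimates; the clean alternative implemented here is regression on
the posterior probabilities themselves (or on the expected allele count,
the *dose* P<sub>AB</sub> + 2·P<sub>AA</sub> ∈ [0, 2]).

For each SNP the trait model is

    E(Y) = Xg βg + Xx βx

with Xg the SNP columns ([P_AA, P_AB] for the general 2-df genotypic model;
one column for the additive, dominant, recessive or over-dominant
sub-models; optionally doubled by SNP×covariate interaction columns W·Xg)
and Xx the nuisance design. Per-term Wald tests use the standard variance
σ̂²(XᵀX)⁻¹, the null-model residual variance (`--score`), or the White/HC0
sandwich (XᵀX)⁻¹XᵀRX(XᵀX)⁻¹ (`--robust`); the global SNP test is a
likelihood-ratio test of βg = 0. Binary traits use logistic regression
(IRLS); survival traits use Cox partial likelihood (Efron or Breslow ties).

In samples with related individuals, ignoring the phenotypic correlation
between relatives inflates these statistics. The two-step remedy:

1. **Step 1** (once): fit the SNP-free polygenic model
   Y ~ N(Xx βx, Ω), Ω = σ²((1−h²)I + h²Φ), by maximum likelihood, where
   Φ is the relationship matrix (twice the kinship matrix) from a pedigree
   or estimated from genome-wide markers as
   kinship·ᵢⱼ = (1/L)Σₗ(gᵢₗ−pₗ)(gⱼₗ−pₗ)/(pₗ(1−pₗ)), genotypes coded 0, ½, 1.
2. **Step 2** (per SNP): score-test each SNP against the step-1 residuals
   r = Y − Xx β̂x using Ω̂⁻¹:
   β̂g = (XgᵀΩ̂⁻¹Xg)⁻¹XgᵀΩ̂⁻¹r, T² = β̂gᵀ(XgᵀΩ̂⁻¹Xg)β̂g ~ χ²(q).

Genome-wide inflation is summarized by the genomic-control factor
λ = median(T²)/0.455.

## Worked example

Simulate a small family sample, write MACH-format files, and scan it:

```python
import numpy as np
from probgwas import io_mach, simulate

ped = simulate.simulate_pedigree(40, family_type="sibship", seed=7)
G = simulate.gene_drop(ped, simulate.draw_founder_freqs(500, seed=8), seed=9)
simulate.make_null_testset(G, ".", m=20, sample_ids=ped.ids, seed=10,
                           prefix="demo")
# a phenotype with a true effect of 0.5 per dose unit at demo_rs1
info = io_mach.read_mlinfo("demo.mlinfo")
dm = io_mach.read_mldose("demo.mldose", info)
rng = np.random.default_rng(11)
y = 0.5 * dm.dose[:, 1] + rng.standard_normal(dm.n_samples)
ph = io_mach.PhenoTable(list(ped.ids), "quantitative", y,
                        rng.standard_normal((dm.n_samples, 1)), ["age"],
                        np.zeros(dm.n_samples, bool))
io_mach.write_phenotype(ph, "demo.pheno")
```

```bash
probgwas linear --pheno demo.pheno --dose demo.mldose --info demo.mlinfo \
    --out demo.out
```

First lines of `demo.out` (columns abridged):

```
name      Al1 Al2 Freq1  MAF    ... beta_SNP_add sebeta_SNP_add chi2     df
demo_rs0  A   B   0.4269 0.4269 ... 0.0726636    0.132773       0.304227 1
demo_rs1  A   B   0.3740 0.3740 ... 0.450266     0.114194       15.1625  1
demo_rs2  A   B   0.2933 0.2933 ... -0.0702597   0.129754       0.297825 1
```

The causal SNP `demo_rs1` is recovered with β̂ = 0.45 (truth 0.5,
se 0.11) and a 1-df likelihood-ratio χ² of 15.2; the null SNPs sit near
zero. `probgwas logistic` and `probgwas cox` scan binary and survival
traits the same way; `probgwas linear --kinship FILE` (or
`--mmscore IVFILE` with externally residualized phenotypes) runs the
two-step mixed-model score test.

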