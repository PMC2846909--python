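# Methods

## Models and tests

**Linear engine.** E(Y) = Xβ, var(Y) = σ²I. β̂ = (XᵀX)⁻¹XᵀY;
σ̂² = RSS/(N − r_X) with r_X = rank(X) (the pure-MLE divisor N differs by
O(k/n) and is used only inside the Gaussian log-likelihood, where the MLE
variance is the internally consistent choice). var(β̂) = σ̂²(XᵀX)⁻¹.
Per-term significance is Wald (β̂/se)²; the global SNP test is the LRT
2(ℓ̂₁ − ℓ̂₀) against the model with every SNP-involving column (interactions
included) removed, on that many df. Three variance flavours: standard,
null-residual variance (`--score`), and White/HC0
(XᵀX)⁻¹XᵀRX(XᵀX)⁻¹ with R = diag(rᵢ²) (`--robust`); with constant
rᵢ² = σ̂² the sandwich reduces exactly to the standard matrix. Under
`--robust`/`--score` the global test is the Wald quadratic form in the
chosen variance (an LRT is not defined for those variances).

**Logistic engine.** E(Y) = expit(Xβ) fitted by IRLS from β = 0 with the
intercept at logit(ȳ); convergence on |Δdeviance| < 1e-8, at most 50
iterations. var(β̂) = (XᵀWX)⁻¹, W = diag(π(1−π)); the robust version is
(XᵀWX)⁻¹XᵀRX(XᵀWX)⁻¹ with R = diag((y−π)²). Quasi-separation is flagged
(non-converged) when a coefficient runs away (|β| > 25); linear predictors
are clipped at ±30 to keep the weights finite.

**Cox engine.** Right-censored data only. Newton–Raphson on the partial
likelihood with step-halving (the log-likelihood never decreases along the
accepted path); tol 1e-9 on the log-likelihood, max 20 iterations. Ties:
Efron by default, Breslow by flag; without ties the two coincide to
machine precision. Risk-set sums are reversed cumulative sums over the
time-sorted sample, so an iteration is O(n p²). Monotone likelihood is
flagged when the fitted linear-predictor range exceeds 50. Standard errors
come from the inverse observed information; the global SNP test is the
partial-likelihood LRT.

**Singularity policy.** All engines detect rank deficiency (monomorphic
SNPs, collinear interaction columns) via least-squares rank with relative
tolerance 1e-8 and return an NA result for that SNP; a genome scan never
aborts on one bad SNP.

## Two-step mixed-model score test

Step 1 maximizes the Gaussian likelihood of Y ~ N(Xxβx, σ²((1−h²)I + h²Φ))
once, without SNP terms. βx and σ² are profiled out analytically at each
h² (GLS estimate; mean weighted RSS), leaving a 1-d bounded search on
h² ∈ [0, 0.99] (scipy bounded Brent, xatol 1e-6). A single
eigendecomposition Φ = QΛQᵀ makes each profile evaluation O(nk) and the
whole fit one O(n³) factorization — this is what keeps a genome-wide
two-step analysis tractable where a per-SNP mixed-model fit is not. A flat
profile (e.g. Φ = I, where h² is unidentifiable) or a boundary estimate is
flagged on the returned fit.

Step 2 computes, per SNP, β̂g = (XgᵀΩ̂⁻¹Xg)⁻¹XgᵀΩ̂⁻¹r and
T² = β̂gᵀ(XgᵀΩ̂⁻¹Xg)β̂g with r the step-1 residuals. In the genome scan the
SNP columns are first orthogonalized against the base design Xx in the
Ω̂⁻¹ inner product (for an intercept-only base this is Ω-weighted
centering). This projection is what makes XgᵀΩ̂⁻¹Xg the exact score-test
variance of the SNP term; without it the statistic is grossly
mis-calibrated for uncentered dose columns. `mmscore_test` applies the
estimating equations to whatever columns it is given (so callers can study
the raw form); `mmscore_scan`/`mmscore_pipeline` apply the projection. The
scan is vectorized: one Ω̂⁻¹·G matrix product covers all SNPs, so 5·10⁴
SNPs at n ≈ 1,100 take seconds.

The externally-supplied-matrix path (`--mmscore IVFILE`) expects the file
to contain Ω̂⁻¹ itself (not a correlation-scaled version) and the phenotype
column to hold the step-1 residualized trait; calibration under this
convention is verified by simulation. Supplying the same fit internally or
externally yields identical per-SNP statistics.

**Kinship.** Pedigree kinship uses the standard recursive tabulation
(founders outbred and unrelated; φᵢᵢ = ½(1+φ_fm), φᵢⱼ = ½(φ_f(i),j +
φ_m(i),j)). Genomic kinship uses the allele-frequency-weighted estimator
over loci with frequency in [0.001, 0.999]; it is unbiased at the true
frequencies, while plugging in sample frequencies adds the usual −1/n
centering bias (visible in small samples; irrelevant at study sizes here).
Negative eigenvalues arising from finite-locus noise are kept for fitting
(the profile guards against a non-positive-definite Ω at large h²) and
truncated at zero only where a PSD matrix is required.

## Synthetic data

The generator emulates the structure of a family-based null-calibration
study; it does **not** model linkage disequilibrium, recombination maps,
assortative mating, or real imputation from reference haplotypes, so
passing tests demonstrate statistical calibration under independent loci
and clean Mendelian transmission — not robustness to LD or imputation
artefacts.

* **Pedigree**: parameterized families. The default `three_generation`
  family is a grandparent couple, two generation-1 sibs, one founder
  spouse, and 2–3 grandchildren (~7.5 members; sib, parent–offspring,
  grandparent and avuncular pairs); 150 families give ~1,125 individuals.
  A `sibship` type (2 founders + 2–3 children) is available.
* **Genotypes**: gene drop; founders from Hardy–Weinberg at per-locus
  founder frequencies (default Uniform(0.05, 0.5); Uniform(0.01, 0.5) for
  null test pools), offspring inherit one uniformly chosen allele per
  parent, loci independent.
* **Imputation blur**: the posterior row for true genotype g is
  Dirichlet(c·onehot(g) + π) with π the Hardy–Weinberg prior. The
  concentration c is solved per locus (closed-form moments + vectorized
  bisection) so that corr²(expected dose, true dose) equals the requested
  quality; quality 1 gives exact one-hot rows. Null test sets draw quality
  uniformly from [0.8, 1.0] and keep loci with estimated MAF ≥ 1%.
* **Trait**: four independent components — two standard-normal covariates
  scaled to explain 10% and 5% of variance, a polygenic score over 200
  causal SNPs (equal per-SNP variance, random signs) scaled to 25.5%, and
  Gaussian noise at 59.5% — so the covariate-adjusted heritability is
  25.5/(25.5+59.5) = 30%. Each component is scaled to its exact sample
  variance share; the realized shares of total variance still fluctuate
  through the sampling covariance between components. Causal loci are
  drawn disjoint from the kinship panel and from the null test set.
* **Determinism**: every operation takes a seed; the experiment drivers
  fan one root seed into per-stage streams via `numpy.random.SeedSequence`.

## Calibration study conditions

The experiment drivers (`probgwas.experiments`) fix the desk-scale study:
150 three-generation families (~1,125 people), a 20,000-locus kinship
panel standing in for a dense genome-wide marker set (a larger panel
reduces kinship-estimator noise, which otherwise attenuates h² slightly),
50,000 null test SNPs, and the trait decomposition above. Heritability
recovery uses 20 replicates of 80 families (~600 people) with the expected
(pedigree) relationship matrix — the expectation is exactly the quantity
the step-1 model parameterizes, so it isolates the estimator from
kinship-panel noise; the variance-share study uses 200 trait replicates on
one genotype set.

## Numerical choices and degenerate inputs

* Rank tolerance 1e-8 (relative) everywhere a design can be singular.
* Genomic-control λ divides the median statistic by 0.455, the
  conventional χ²₁ median constant.
* The per-SNP null model for the LRT is cached per missingness pattern and
  recomputed only when a SNP's missing cells change the analysis sample.
* Missing dosage cells in the mmscore scan are set to the column mean
  (zero after centering, i.e. they contribute nothing) and reduce n_used;
  the external Ω̂⁻¹ path refuses samples with missing phenotypes outright,
  since a jointly fitted matrix cannot be subset.
* Dose values outside [0, 2] and probabilities outside the simplex are
  format errors at parse time (tolerance 1e-6); negative dosage tokens and
  NA/nan are missing codes.

## Known limitations

* Genotype files are loaded into memory; there is no SNP-streaming mode
  (the MACH row-per-sample layout would require a full file pass per SNP
  chunk). Memory is ~16 bytes per sample×SNP cell for dosages.
* Mixed-model analysis covers quantitative traits only; binary and
  survival outcomes have no relatedness-aware engine.
* The CLI's mmscore path is additive-model, no interactions; the library's
  `mmscore_test` handles general multi-column SNP designs.
* No Firth correction or exact logistic regression; separation is flagged,
  not repaired. No stratified or frailty Cox, no delayed entry.
* The interaction model requires the interaction covariate's main effect
  in the base design (it is there by construction), keeping the model
  hierarchical.
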