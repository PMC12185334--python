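# Methods

## The estimand

The trio-PGS design separates two pathways from parental genotype to
offspring methylation. Writing Y_ij for the (residualized) β-value of
offspring *j* in family *i* at one CpG,

    Y_ij = μ + Σ_t ( δ_t PGS_ij^t + α_m,t PGS_m(i)^t + α_p,t PGS_p(i)^t )
             + β₁ D2_ij + β₂ D3_ij + ε_ij

δ_t is the direct effect of the offspring's own standardized PGS for trait
*t*; α_m,t and α_p,t are the maternal and paternal indirect (genetic
nurture) effects — associations of a parental PGS with child methylation
*conditional on the child's own PGS*, which transmitted alleles cannot
produce. Six traits enter simultaneously, so each trait's coefficients are
adjusted for the (modest) cross-trait PGS correlations; D2/D3 index the
methylation dataset. With an intercept this is a 21-column design.

Identification rests on the usual assumptions of the design: random mating
(spousal PGS correlation ≈ 0), no confounding of the parental PGS with
omitted environment correlated with child methylation (population
stratification is addressed by residualizing PGSs on genetic PCs), and
linearity on the analysis scale.

## Estimation

Twins and siblings share a family, so observations are not independent.
Coefficients solve the Gaussian identity-link estimating equations; the
variance is the family-clustered sandwich

    cov(β̂) = B⁻¹ ( Σ_i U_i U_iᵀ ) B⁻¹,
    B = Σ_i X_iᵀ V_i⁻¹ X_i,  U_i = X_iᵀ V_i⁻¹ r_i,

implemented directly (no model-fitting library). Under the default
**independence** working structure the point estimates equal OLS; an
**exchangeable** structure (moment-estimated common within-family
correlation, iterated to convergence, Woodbury closed form for V⁻¹) is
provided and reproduces independence exactly when all clusters are
singletons. Both structures are cross-checked against statsmodels GEE to
machine precision in the test suite. p-values use the standard-normal
reference for the robust Wald z, the convention for GEE; no small-sample
degrees-of-freedom adjustment is applied by default.

Two finite-cluster facts are documented and measured rather than hidden:

- the plain sandwich is mildly anticonservative when clusters number only a
  few hundred (empirical size ≈ 0.06 at 500 families, ≈ 0.053 at 1000+);
  the type-I calibration test therefore runs at 1500 families, inside the
  asymptotic regime the estimator is designed for;
- for confidence intervals at 500 families the plain sandwich covers at
  ≈ 93%; `fit_gee_probe(..., cov_type="bias_reduced")` implements the
  Mancl–DeRouen leverage-adjusted meat, restoring ≈ 95% coverage (verified
  against the statsmodels `bias_reduced` covariance). The default remains
  the plain sandwich, matching the R package conventionally used for this
  analysis.

Non-convergence is operational: rank-deficient design, non-finite response,
a non-finite working-correlation update, or hitting the iteration cap. Such
probes stay in the results table flagged `converged=False` with no
inferential fields, and the bookkeeping identity total = successful +
non-converged is asserted on every run. A probe fit with exactly zero
residuals (e.g. a constant-zero probe) returns exact coefficients with zero
sandwich variance and undefined z/p.

## Preprocessing

States are explicit and ordered: raw → masked → imputed → residualized.

- **QC filter**: drop probes flagged cross-reactive, SNP-overlapping or on a
  sex chromosome, or with success rate < 0.95 (strict).
- **Outlier masking**: per probe, values outside [Q1 − 3·IQR, Q3 + 3·IQR]
  are set missing, quantiles by linear interpolation between order
  statistics (the common default; configurable `k`), computed once on the
  original values in a single pass. Probes with < 4 non-missing values are
  left unmasked with a warning. Masking precedes imputation; the reverse
  order is also defensible, but a fixed order keeps runs reproducible and
  the chosen one never imputes from outlying values.
- **Imputation**: probes missing > 5% (strict) are dropped; the rest are
  probe-mean filled. An optional EM-style truncated-SVD refinement
  (`method="svd"`) iterates a low-rank reconstruction and is verified to
  beat the mean fill on low-rank data; the mean fill is the tested default
  because a component count is an extra free parameter.
- **Residualization**: OLS residuals per probe on sex, age, epithelial and
  NK cell proportions, array row and bisulfite plate (categoricals
  dummy-expanded against a reference level). The dataset indicator is *not*
  residualized out: dataset dummies belong to the association model itself.
  Rank-deficient designs raise an error naming the collinear columns;
  residualization is a projection and is idempotent to numerical tolerance.
- **Top-variance selection**: the floor(q·M) most variable probes, q = 0.10
  by default; ties broken lexicographically by probe id for determinism.

PGS preparation mirrors the genotype side: per trait × role, OLS residuals
on two genotyping-platform dummies and 10 genetic PCs, z-scored over
observed values (mean 0, SD 1, ddof = 1), then missing parental scores set
to 0 — the mean of a standardized score — and flagged. Standardizing
*before* imputation keeps the observed-score scale intact; the reverse
order would shrink the SD by the missingness fraction. Missing offspring
scores are a design violation and raise. The zero-imputation keeps families
in the analysis at the cost of attenuating parental-effect estimates toward
zero; the simulator can quantify that attenuation, the estimator does not
correct it.

## Multiple testing

Neighbouring CpGs are correlated, so Bonferroni over raw probe count is too
severe. The effective number of tests follows Nyholt:

    Meff = 1 + (M − 1) · (1 − Var(λ)/M)

with λ the eigenvalues of the probe × probe Pearson correlation matrix and
Var the sample variance (ddof = 1). When probes ≫ samples the spectrum is
computed from the n × n dual cross-product of the standardized data (equal
nonzero eigenvalues, zeros appended) — the M × M matrix is never formed;
both paths agree to 1e−8 where both are feasible. Meff is rounded **up**
before dividing (smaller α, conservative). The Li–Ji refinement
(Σ [1(λ≥1) + frac(λ)]) is available as an option. Constant probes have no
defined correlation and raise.

## The synthetic cohort

What the generator emulates:

- **Genotypes**: unlinked biallelic loci, allele frequencies uniform on
  [0.05, 0.95]; parents in Hardy–Weinberg proportions under random mating;
  offspring receive one fair-drawn allele per parent per locus; MZ co-twins
  (probability `p_mz`, default 0.5) share one genome. A crude per-locus
  spousal-assortment knob exists, default 0: observed spousal PGS
  correlations in such cohorts are small (mean ≈ 0.04) and are not
  targeted.
- **PGSs**: weighted dosage sums with standard-normal weights, z-scored
  within generation. Mendelian transmission makes the same-trait
  parent–offspring correlation converge to 0.5 and the MZ co-twin
  correlation exactly 1.
- **Covariates**: sex (51.5% boys), age ~ N(10, 2.8²) years clipped to
  [1, 18], epithelial/NK cell proportions from Beta distributions typical
  of buccal tissue (~0.83 and ~0.03), 8 array rows, 96-sample plates,
  dataset labels with shares (0.06, 0.75, 0.19), 10 genetic PCs, three
  genotyping platforms as two dummies.
- **Methylation**: a Gaussian liability per offspring × probe — baseline μ,
  sparse trait effects (δ, α_m, α_p) on declared causal probes, optional
  covariate effects, a family random intercept u_ic ~ N(0, family_sd²)
  shared by co-twins, and noise e ~ N(0, noise_sd²) — mapped through the
  inverse logit to a β-value strictly inside (0, 1). Defaults family_sd =
  noise_sd = 0.5 give liability ICC 0.5. The logit is the exact inverse
  map, so estimator-recovery checks are run on the liability scale where
  the generative coefficients live; on the β scale the same coefficients
  appear attenuated by the link's slope.
- **Missing parental PGSs**: per family, mother/father scores are blanked
  with marginal probabilities 0.079 / 0.189 and joint both-missing
  probability 0.051, reproducing 78.3% of families with both parents
  scored. Offspring are never masked.

One master seed fans out into named substreams (genotypes, weights,
covariates, methylation, missingness, manifest), so enlarging one component
does not perturb the others, and every `simulate_*` call is bit-identical
under a repeated seed.

What it does **not** emulate — and hence what passing tests do not show
about real data: linkage disequilibrium and realistic PGS weighting,
X-chromosome transmission, assortative mating (unless dialled in),
inter-probe correlation structure (probes are conditionally independent
given covariates, so the spectral reduction is modest in simulation whereas
real arrays compress by orders of magnitude), non-Gaussian β distributions
(bimodality, boundary inflation), batch artefacts beyond linear covariate
effects, and cell-composition heterogeneity beyond two proportions.

## Problem sizes

The analysis drivers use 764 families (1528 offspring, the cohort scale),
500 loci and 4000 probes. The test suite runs the statistical guarantees at
the sizes the claims require: OLS equivalence and sandwich arithmetic on
small exact fixtures; type-I error over 2000 null probes at 1500 families;
parameter recovery of (δ, α_m, α_p) = (0.3, 0.2, 0.1) over 200 replicates
of 500 families; top-variance selection once at the full array scale
(728,899 probes). The acceptance script simulates 2000 families at 500
loci.

## Known limitations

- Independence working structure loses a little efficiency relative to a
  correctly specified exchangeable structure; point estimates are identical
  in expectation and the sandwich keeps inference valid either way.
- Zero-imputed parental PGSs attenuate α estimates; families with missing
  parents contribute no information about the missing parent's effect but
  still stabilize the remaining coefficients.
- Meff on simulated data is close to the probe count by construction (see
  above); the published-scale reduction (~73k probes → ~1.9k effective
  tests) requires real inter-probe correlation and is not reproducible from
  the generator.
- The per-probe model is marginal: no attempt is made to model joint
  methylation across probes or mediation to child outcomes.
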