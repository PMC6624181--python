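# Methods

## Model

`pharaoh-gee` tests the joint association between biological pathways and
*Q* correlated phenotypes measured on the same *N* individuals (repeated
measurements, or a cluster of related traits such as the components of the
metabolic syndrome), using rare genetic variants as input. The model has
three levels:

1. **Variant → gene.** Rare variants (minor-allele frequency below a
   configurable threshold, default 0.05) are collapsed per gene into a
   burden score, the weighted sum of allele counts with weights
   γ_j = |log₁₀ MAF_j|, so rarer alleles count more. The *N* × (*T*+1)
   matrix **X** of gene burdens (intercept column prepended, columns ordered
   pathway-major) is mean-centered and rescaled so that diag(**X**′**X**) =
   *N* **I**. Genes annotated to several pathways contribute one column per
   membership; the pathway blocks never share columns.
2. **Gene → pathway.** Each pathway *k* has a latent component score
   f_ik = Σ_t x_ikt w_tk, a weighted sum of its own gene burdens. The
   weight matrix **W** is block-sparse: column *k* is non-zero only at the
   rows of pathway *k*'s genes, and the intercept entry W₀₀ is fixed at 1.
3. **Pathway → phenotype.** The marginal mean of phenotype *q* follows a
   GEE-style model g(μ_iq) = β₀q + Σ_k f_ik β_kq with identity link for
   continuous phenotypes and logit link for binary ones, and a working
   within-cluster correlation R(α) (independence, exchangeable, AR-1 or
   unstructured) describing the dependence among the *Q* phenotypes of one
   individual: cov(ỹ_i) = φ A_i^{1/2} R(α) A_i^{1/2}, A_i = diag(ν(μ_iq)).

Two ridge penalties make the model identifiable and control the strong
correlations among gene burdens and among pathways: λ_G on the free weights
w and λ_P on the pathway coefficients **B** (intercept row unpenalized).
Only the products w_tk·β_kq enter the linear predictor, so the split of
scale between a pathway's weight block and its coefficient row is fixed by
the penalties alone (see *Numerical notes*).

## Estimation

Parameters are estimated by alternating closed-form penalized
generalized-least-squares solves:

- **Coefficient step.** For fixed **W**, stack b = vec of the rows of **B**
  and solve (Σᵢ Qᵢ′Vᵢ⁻¹Qᵢ + λ_P P) b = Σᵢ Qᵢ′Vᵢ⁻¹zᵢ with Qᵢ = f̃ᵢ′ ⊗ I_Q.
- **Weight step.** For fixed **B**, solve the analogous system for the free
  weights with design Mᵢ = x̃ᵢ′ ⊗ **B**′ restricted to the structurally
  non-zero positions; the fixed intercept component enters as an offset.
- **Correlation / dispersion step.** Update α by moment estimators on the
  Pearson residuals r_ij = (y_ij − μ̂_ij)/ν^{1/2}(μ̂_ij), and the dispersion
  by φ̂ = Σ r̂²_ij / (NQ − K − Σ_k T_k) for continuous phenotypes; for binary
  phenotypes φ is fixed at 1 by default (estimable behind a flag).

For binary phenotypes both solves use the standard GEE working-response
linearization z = η + (y − μ)·g′(μ). The weight matrix Vᵢ is the working
covariance **of z**, A^{1/2}R⁻¹A^{1/2}/φ for the logit link — for the
identity link this is exactly Σᵢ⁻¹, and in general it makes the fixed point
solve the canonical penalized GEE score equation
Σᵢ Dᵢ′Σᵢ⁻¹(yᵢ − μᵢ) = (penalty gradient). Weighting z by Σᵢ⁻¹ itself would
put a factor 1/ν² on the raw residual and is numerically explosive; this is
a deliberate design choice, not an approximation.

Iteration stops when the largest absolute change in (b, w) falls below
`tol` (default 1e-5, `max_iter` 200). Initialization is deterministic:
w = 1/√T_k per block (unit-norm components under the scaling constraint),
**B** zero except intercepts at g(ȳ_q). After convergence each pathway's
(weights, coefficient row) pair is flipped jointly so the largest-magnitude
weight is positive — a pure sign convention that leaves η unchanged.

### Numerical notes

The alternation on a bilinear predictor has two failure modes that the
implementation addresses explicitly:

- **Scale valley.** Since only w·β products are identified, the iteration
  crawls along the near-flat direction where blocks trade scale. After each
  sweep every pathway block is moved to the penalty-optimal point of its
  invariance ray (c⁴ = λ_P‖β_k‖²/(λ_G‖w_k‖²)), which removes that valley
  at no cost to the fixed point.
- **Saturation under the logit link.** A too-aggressive step can push means
  to 0/1, where the working response explodes. Steps are guarded by a merit
  function — the penalized generalized Pearson χ², Σᵢ(yᵢ−μᵢ)′Σᵢ⁻¹(yᵢ−μᵢ)
  plus the two ridge terms — with halving toward the previous iterate when
  a step escapes a modest band above the best merit seen. The GEE fixed
  point does not exactly minimize this merit, so the band (20% above the
  running best) matters: requiring strict descent would block convergence.
- **Endgame.** Once the sweep's step size drops below 3×10⁻², the solver
  switches to a joint damped Newton step on (b, w) — the linearized system
  of both blocks plus the bilinear cross-derivative term of the score. It
  zeroes the same penalized score (verified in tests against the blockwise
  fixed-point conditions) and converges quadratically where the sweep is
  linear. Rejected Newton steps fall back to an ordinary sweep.

Means are clamped to [1e-8, 1−1e-8] for binomial variance evaluations; a
non-positive-definite unstructured correlation estimate is repaired by an
eigenvalue floor at 1e-6 and rescaling to unit diagonal; φ is floored at
1e-10 so exact fits stay finite.

## Penalty selection

k-fold cross-validation (default k = 5, grid {0.01, 0.1, 1, 10, 100} on
both axes) minimizes the **unpenalized** holdout quasi-deviance — Σ(y−μ)²
for continuous, the binomial deviance for binary phenotypes. Burden
standardization is recomputed inside each training fold and applied to the
holdout fold, so no holdout information leaks into the fit. Ties are broken
toward the larger penalty pair. Note that with a bilinear predictor the fit
depends on the penalties mainly through their geometric mean, so the CV
surface is near-constant along λ_G·λ_P contours.

## Inference

The joint effect of pathway *k* on all *Q* phenotypes
(H₀: β_k1 = … = β_kQ = 0) is tested with the Wald-type statistic
T = β̃_k′ cov⁻¹(β̃_k) β̃_k. Significance comes from permutations: whole
phenotype **rows** are permuted across individuals (preserving the
within-cluster correlation under the null) and the full model is refitted
with the same penalties and correlation structure. By default cov(β̃_k) is
the sample covariance of the permuted coefficient vectors (the cheap
"indirect" estimator); a penalized-GEE sandwich estimator
(H+E)⁻¹M(H+E)⁻¹ with the ridge contribution in the bread is available as
an alternative. p-values use the add-one rule
p = (1 + #{T_null ≥ T_obs})/(n_perm + 1) and are never zero. Gene-level
p-values are two-sided quantiles of each fitted weight against its
permutation null, with the sign convention applied to every permuted fit.
Multiplicity is handled by BH step-up q-values and by Westfall–Young
single-step max-T adjusted p-values from the same permutations. Penalties
are held fixed across permutations (re-running CV inside every permutation
is computationally prohibitive and would add noise, not validity).

## Simulator

The generator emulates a rare-variant sequencing study: K = 10 pathways ×
10 genes, each gene carrying 5–20 variants with MAFs drawn log-uniformly
from [10⁻⁴, 0.01] (roughly the rare spectrum of a kilobase of coding
sequence) and Hardy–Weinberg binomial genotypes; N = 1000 individuals at
full scale. Only pathway 1 is causal: its first H₁ ∈ {1, 2} genes feed the
latent predictor η_iq = β Σ_{t≤H₁} w Σ_j |log₁₀MAF_tj| g_itj, with the
gene-level effect w ∈ {0.1, 0.2, 0.5, 1.0} and pathway-level effect
β ∈ {0.15, 0.2, 0.25} shared across the Q = 3 phenotypes. Binary phenotypes
arise by thresholding a latent MVN(0, Σ_ρ) draw with exchangeable
correlation ρ ∈ {0.25, 0.5}: y_iq = 1 iff Z_iq < η_iq, so larger η raises
the case probability and the null prevalence is exactly ½ with latent
inter-phenotype correlation ρ.

What the generator does **not** emulate: linkage disequilibrium between
variants, site-frequency spectra from an explicit demographic model,
covariates, missing genotypes/phenotypes at realistic rates, and protective
(sign-mixed) variant effects. Passing the simulation-based tests therefore
demonstrates calibration and power ordering under idealized rare-variant
architecture, not performance on any particular real cohort.

### Study harness and problem sizes

`run_study` fits and permutation-tests every replicate and reports: power
(fraction of replicates where the causal pathway has BH q < 0.05), type-I
error (fraction of non-causal pathway tests with p < α, default α = 0.01),
and the empirical FDR, mean over replicates of V/max(R, 1) — the quantity
the BH procedure actually controls. Discovery is strict (q < 0.05). Note a
granularity effect at desk scale: with 199 permutations the smallest
attainable p is 1/200, whose q-value with K = 10 pathways is exactly 0.05,
so a lone extreme pathway only becomes a discovery when a second pathway
ties it (both then have q = 0.025); at the permutation resolutions used for
real analyses (n_perm ≥ 1000) this atom disappears. Power comparisons in
the test suite therefore use K = 4 pathways, where the two smallest
attainable p-values both clear the strict threshold.
The default harness scale is 50 replicates of
N = 500 with n_perm = 199 and λ_G = λ_P = 1 (at this scale holdout
quasi-deviance carries too little signal for CV to be informative, so the
penalties are fixed); the full design (300 replicates, N = 1000) is a
config change. The test suite runs further reduced versions (10–12
replicates, N = 150–400, fewer pathways for the global-null calibration and
the power comparisons); each test states its sizes.

## Known limitations

- Families are gaussian/identity and binomial/logit only; the family enum
  is extensible but count phenotypes are not implemented.
- Complete cases only: no unbalanced clusters or missing phenotypes.
- The permutation test assumes exchangeability of individuals under the
  null; confounders (e.g. population structure) are not adjusted for —
  there is no covariate path in v1.
- Conditional FDR summaries (V/R among discovery-containing replicates
  only) are reported by `StudyResult.fdr_among_discoveries` but are not a
  controlled quantity at low power: a single false-discovery replicate can
  push the conditional ratio to 1 even though BH is operating correctly.
- The per-pathway Wald covariance from permutations assumes the null
  coefficient distribution is well summarized by its second moment;
  with very small n_perm the inverse is noisy (n_perm ≥ Q + 2 enforced,
  ≥ 1000 recommended for real analyses).
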