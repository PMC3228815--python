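# Methods

## Model

For *n* unrelated individuals with response *y* (any exponential-family
GLM; gaussian/identity and binomial/logit are the intended cases),
covariates *x*, and additive minor-allele dosages *z* partitioned into *K*
groups each holding at least two variants, the linear predictor is

    eta_i = beta_0 + sum_j x_ij beta_j + sum_k g_k S_ik,
    S_ik  = sum_{j in G_k} b_j z_ij            (the genetic score of group k).

The response mean is mu = h^-1(eta) and the likelihood carries a dispersion
phi (estimated for gaussian/gamma, fixed at 1 for binomial/poisson).
Missing dosages must be imputed first; `data_io.impute_mean` fills each
missing entry with the variant's observed mean, which preserves per-variant
allele frequencies exactly.

The product g_k · b_j is not identified by the likelihood alone; the priors
break the ridge:

* **Weights** b_j ~ N(mu_j, tau_j^2) with tau_j half-Cauchy C+(0, s_k),
  written as the two-level hierarchy tau_j^2 | lambda_j ~ InvGamma(1/2,
  1/lambda_j), lambda_j ~ InvGamma(1/2, 1/s_k^2).  The prior mean mu_j
  (default 1; external functional scores in (0, 1] may be supplied) is the
  fixed-weight baseline; the predictor decomposes identically as
  g_k Σ mu_j z_ij + Σ g_k (b_j − mu_j) z_ij, a burden term plus a
  deviation term, and the per-variant coefficient of the deviation,
  theta_j = g_k (b_j − mu_j), is reported as the *adjusted main effect*.
* **Group scales** s_k are estimated: with t_k = 1/s_k^2 given a
  Gamma(0.5, 0.5) hyperprior, the conditional mode is
  t_k = (J_k/2 − 1/2) / (Σ_j 1/lambda_j + 1/2), floored at 1e-6 so
  tiny groups stay defined.  A fixed-scale variant freezes every s_k
  (default 0.5).
* **Group effects and covariates** get g ~ N(0, psi),
  psi ~ Gamma(0.5, 0.5); the conditional mode is psi = sqrt(1 + g^2) − 1,
  floored at psi_min = 1e-4.  This weakly informative prior mainly guards
  against the numerically unstable group effects that low-frequency scores
  can produce.
* Intercept: N(0, 1e6).  Dispersion: p(phi) ∝ 1/phi.

## Fitting: EM within IWLS

Each sub-model is fitted by interleaving an E-step for the prior
hyperparameters with one weighted-least-squares step on augmented data:

1. **E-step.**  Expected prior precisions: for weight columns,
   w_j = 1/(1/lambda_j + (b_j − mu_j)^2/2) and
   lambda_j ← 1/s_k^2 + w_j.  Only 1/lambda enters anywhere downstream, so
   the lambda state is tracked as the harmonic plug-in whose reciprocal is
   the conditional expectation E[1/lambda_j] = 1/(1/s_k^2 + w_j) under the
   InvGamma(1, 1/s_k^2 + w_j) conditional.  At zero deviation w_j grows
   without bound across iterations — the half-Cauchy spike — so null
   weights are pinned at mu_j; at large deviations w_j ≈ 2/(b_j − mu_j)^2,
   the heavy tail that releases genuine signals.  Then s_k from the group's
   lambdas, psi from each shrunk coefficient.
2. **M-step.**  One IWLS step on the data augmented with one
   pseudo-observation per penalized coefficient (response = prior mean,
   design = indicator, weight = expected prior precision; gaussian/gamma
   scale the augmented weight by the current phi so the prior acts on the
   coefficient scale).  Because each pseudo-row touches one coefficient,
   augmentation is a diagonal addition to the weighted normal equations.
3. **Dispersion** (gaussian/gamma): posterior mode under p(phi) ∝ 1/phi
   from the weighted working residuals including the augmented rows,
   phi = S/(n + p + 2).

Standard errors are square roots of the diagonal of the inverse augmented
normal-equations matrix at the mode (posterior curvature); p-values use a
t reference with n − p degrees of freedom when the dispersion is estimated
and a normal reference otherwise.

The joint model alternates the two conditional GLMs — the group-effect
model on the K score columns, then the weight model on the per-variant
predictors g_{k[j]} z_ij with the intercept + covariate part as an offset —
taking **one** EM-IWLS step per sub-model per outer iteration, and stops
when the group-model deviance satisfies |D_t − D_{t−1}|/(|D_t| + 0.1) <
tol (default 1e-5, max 200 outer iterations; the same criterion governs
the standalone fitter).  Initialisation: intercept at link(mean response),
covariates and group effects 0, weights at mu_j, lambda = 1, s = 0.5,
psi = 1, phi = 1 — so the first outer iteration reproduces the
fixed-weight (burden) model, a useful anchor.

The delta-method SE of an adjusted effect,
Var(theta) = g^2 Var(b) + (b − mu)^2 Var(g), omits the cross-covariance of
g and b: the alternating scheme never forms their joint covariance.  This
is a documented approximation; when b = mu and both SEs vanish, p = 1 is
reported.

## Numerical choices and degenerate inputs

* Means are clipped into the open link domain (1e-10) inside IWLS.
* A group whose score column is constant (e.g. all carriers removed) keeps
  g = 0 with SE = ∞, p = 1, and a warning — not an exception — so
  replicate studies keep running.
* Monomorphic variants are rejected by the per-variant model and removed
  by `drop_non_segregating` in the study pipeline, mirroring standard
  preprocessing of resequencing data.
* Singleton groups are rejected; route single variants to the covariates
  (as done for the two common non-synonymous variants in the motivating
  data).  MAF classification uses rare ⟺ MAF < 0.01 strictly.
* Non-convergence is flagged on the result, never raised; the study engine
  excludes and counts such replicates.
* Groups are updated in input order; estimates are invariant to group and
  row permutations (property-tested).

## Synthetic data

The simulator emulates the structure of a population-based resequencing
study of one candidate gene: common-variant MAFs uniform on (0.01, 0.5),
rare-variant MAFs log-uniform down to the singleton frequency 1/(2n);
independent Hardy–Weinberg dosages Binomial(2, q); covariates = a
three-level ancestry factor (0.6/0.2/0.2), age ~ U(18, 65), sex ~
Bernoulli(0.5), BMI ~ N(28, 5); two common singleton variants (MAF 0.030,
0.016) carried as covariates; a continuous trait with residual SD 0.2 on
the log scale, and a binary trait by median split (prevalence exactly 1/2).
Covariate and singleton effects default to zero.

Per-group effects are drawn U(0, beta_h) with independent sign flips with
probability p.neg, where

    beta_h = sqrt( 3 h sigma_e^2 / ((1 − h) Σ_j 2 q_j (1 − q_j)) )

calibrates the group's expected explained-variance fraction to h (under
independent HWE genotypes, E[beta^2] = beta_h^2/3 gives
E[Var(Σ beta z)] = (beta_h^2/3) Σ 2q(1−q)); the Monte-Carlo check in the
acceptance suite recovers h = 0.007 to within ±0.002 over 500 datasets.
The catalog (`scenario_catalog`) holds the named three-group and six-group
designs at n = 3008 and n = 1499 with h ∈ {0, 0.5%, 0.7%} and
p.neg ∈ {0, 0.4}.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), population stratification beyond the ancestry factor's
label, genotyping error, and covariate–trait associations (effects default
to 0).  Passing tests therefore demonstrate calibration and relative
method behaviour under idealised genotypes, not performance on real LD
structure.

## Study engine and problem sizes

`run_study` simulates replicate datasets (seed = base_seed + r), drops
non-segregating variants, fits any subset of {proposed, fixed_scale,
weights_fixed, all_variants_minp}, and tallies significance frequencies at
alpha ∈ {0.05, 0.01, 0.001} over converged replicates.  The per-variant
comparator uses the unadjusted minimum p-value over a group — its inflated
null rate is a finding about that method, not a bug.  The test and
acceptance runs use 400 replicates for type-I checks and 200 for power
comparisons at n = 3008, sizes chosen to keep Monte-Carlo error a few
percentage points while the whole suite stays desk-scale; Wilson 95%
intervals accompany every comparison.

## Known limitations

* **Weight identifiability at small group effects.**  The information a
  single rare variant contributes to its weight scales as
  g^2 · n · 2q(1−q)/phi, which at group heritabilities below about 1% and
  n ≈ 3000 is of order 0.02–0.1 — far below any prior precision strong
  enough to keep null groups calibrated.  In that regime the fitted
  weights stay essentially at their prior means and the joint model's
  power approaches the fixed-weight model's (measured at n = 3008,
  h = 0.7%, 40% protective variants: 0.185 vs 0.130 at alpha = 0.01 over
  200 replicates — same direction, overlapping Wilson intervals).  When
  the signal supports it (e.g. h = 5% at n = 3000) the weights
  differentiate sharply: power 0.90 vs 0.43, with opposite signs recovered
  for risk and protective variants.  Type-I error of the group test stays
  at or slightly below nominal throughout (0.02–0.05 at alpha = 0.05);
  the shrinkage that guarantees this is mildly conservative for rare-variant
  groups (null p-value KS distance ≈ 0.06 from uniform).
* The delta-method SE omits the g–b cross term (above).
* No LD-aware simulation; no MCMC exploration of the full posterior —
  inference is mode + curvature.
* Group-at-a-time updating for very large variant panels is out of scope;
  the joint weight update is intended for at most a few thousand columns.
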