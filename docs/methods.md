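# Methods

## The model

Sex is treated as a threshold trait.  Individual *i* carries an unobserved
liability

    l_i = x_i' beta + a_i + m_dam(i) + e_i,        e_i ~ N(0, 1),

and is male iff l_i > 0.  The breeding values follow the infinitesimal
model over the pedigree, `a ~ N(0, A sigma2_a)` with A the numerator
relationship matrix; `m` is one normal deviate per dam
(`m ~ N(0, I sigma2_m)`) shared by all her offspring, capturing maternal
effects on sex tendency.  Because each individual contributes a single
binary record, neither the threshold nor the residual variance is
identifiable; we fix the threshold at 0 and the residual variance at 1, so
the model is a probit animal model and

    h2_lat = sigma2_a / (sigma2_a + sigma2_m + 1)

is the narrow-sense heritability of liability.  Fixed effects: an
intercept, experimental block, and a parental-origin factor coding the
(dam line, sire line) combination with FF (both female-biased) as the
reference; backcross offspring get hybrid codes (HF, HM, FH, MH).  When
heritability is computed from a model with fixed effects, the variance of
the fixed-effect linear predictor over the observed design rows,
recomputed per posterior draw, is added to the denominator so that
variance absorbed by fixed effects is not silently dropped from the
phenotypic total.

## Pedigree algebra

A is built by Henderson's tabular recursion (`a_ii = 1 + a_{sd}/2`,
`a_ij = (a_{j,s} + a_{j,d})/2`); its inverse comes directly from the
pedigree via the factorization `A^-1 = (I - P)' D^-1 (I - P)`, where P
maps individuals to half their parents and D holds Mendelian-sampling
variances `d_i = 1/2 - (F_s + F_d)/4` (3/4 - F/4 with one known parent, 1
for founders), with inbreeding coefficients F from memoized pedigree
kinship.  Founders are treated as unrelated and non-inbred: the design's
isofemale lines were certainly inbred, but the pedigree carries no deeper
ancestry, and no correction is exposed.  Matrix order is the topological
sort of the pedigree with input-order tie-breaks.

## Gibbs sampler

Fitting uses Albert–Chib data augmentation:

1. **Liabilities** are drawn from `N(eta_i, 1)` truncated above 0 for
   males, below 0 for females (inverse-CDF sampling with tail clipping at
   1e-15).
2. **All location effects jointly.**  The joint Gaussian draw of
   (beta, a, m) | l is computed through a reduced-animal-model
   factorization: individuals with descendants ("parents") keep explicit
   breeding values, terminal individuals' values are split into the
   parent average plus a Mendelian deviation phi_i with variance
   `d_i sigma2_a`, which is integrated into the record's residual
   (variance `1 + d_i sigma2_a`).  The block (beta, a_parents, m) is then
   sampled from the mixed-model equations — a dense Cholesky of order
   p + n_parents + n_dams, a few hundred for the designs here — and each
   phi_i from its exact univariate conditional.  This factorization *is*
   the joint draw, at a fraction of the cost of factorizing the full
   mixed-model equations every iteration.
3. **Variance components** get scaled-inverse-chi-square conditional
   draws, `sigma2_a | a ~ (a'A^-1 a + nu V) / chi2(q + nu)` with q the
   number of pedigree individuals, and likewise sigma2_m from the dam
   effects; the residual stays at 1.
4. **Interweaving.**  Binary-trait data augmentation mixes the variance
   scales notoriously slowly.  After the centered updates, each
   component's scale is redrawn in the non-centered parameterization
   (holding a/sigma_a fixed, sigma_a acts as a regression coefficient
   with a Gaussian conditional); the draw is proposed from that Gaussian
   and accepted with a Metropolis ratio carrying the exact prior, so the
   move is valid for any prior.  This roughly quadruples the effective
   sample size of sigma2_a in our benchmarks and can be disabled
   (`interweave=False`).

Chains are independent, seeded by spawning from a single seed, and runs
are bit-reproducible.  With random effects suppressed the sampler reduces
exactly to Bayesian probit regression, which the tests exploit
(agreement with a directly optimized probit MLE, and a KS comparison
after pinning the variance components with degenerate priors).  The
sampler is additionally cross-checked against an independent JAGS
implementation of the same model on a small dataset
(tests/test_oracle_jags.py).

**Priors.**  Defaults are the conventional weakly-informative
inverse-gamma, V = 1 and nu = 0.002 per variance component, and
N(0, 1e10) on fixed effects; both are user-settable, including informed
variance priors via (V, nu).

**A caution on weak priors.**  With a single binary record per individual
the likelihood becomes nearly scale-free once the variance components
dwarf the fixed residual: inflating sigma2_a, sigma2_m and the liabilities
together changes the fit only through the ratio structure.  Under the
nearly scale-free nu = 0.002 prior the marginal posterior of sigma2_a
therefore has an extremely heavy upper tail at moderate data sizes, and
long chains legitimately wander into large-variance regions on some
datasets.  This is a property of the model class, not of the sampler; it
is the usual motivation for informed priors in binary threshold models.
Posterior summaries at the desk scale should be read accordingly (wide
HPDs, posterior means above the mode).

**Diagnostics.**  ESS uses Geyer's initial-positive-sequence truncation of
the autocorrelation sum; the potential scale reduction factor is
`sqrt(1 + B/(nW))` across chains (exactly 1 for identical chains); pMCMC
is twice the smaller tail proportion of draws around zero, floored at
1/n.  Credible intervals are HPD (shortest interval at the target mass),
not equal-tailed; both conventions coincide for symmetric posteriors but
HPD is reported throughout.

## Scale conversion

For the probit link the latent-to-observed conversion has closed forms.
With linear predictor mu_j on design row j and total non-residual random
variance sigma2_re = sigma2_a + sigma2_m:

    t_j   = mu_j / sqrt(1 + sigma2_re)
    p_j   = Phi(t_j)
    Psi_j = phi(t_j) / sqrt(1 + sigma2_re)

    p             = mean_j p_j
    sigma2_a_obs  = (mean_j Psi_j)^2 * sigma2_a
    var_obs       = mean_j[p_j (1 - p_j)] + Var_j(p_j)   (= p(1 - p) exactly)
    h2_obs        = sigma2_a_obs / var_obs

The two var_obs terms are the within-row Bernoulli variance and the
across-row variance of expected prevalence; for a binary trait their sum
collapses to the pooled p(1-p).  The conversion is applied to every
posterior draw (mu_j = x_j' beta per draw), so the h2_obs posterior
reflects the joint posterior of all components.  With a single design row
the formula reduces to Dempster–Lerner,
`h2_obs = h2_lat z^2 / (p(1-p))`, `z = phi(Phi^-1(p))`, giving the factor
2/pi at p = 1/2; the grid equivalence of the two routes to 1e-8 is an
acceptance test.  Observed-scale heritability is strictly below
latent-scale heritability for any p in (0,1): thresholding turns part of
the additive variance into non-additive variance on the binary scale.

## Synthetic data

The generators emulate a two-line crossing experiment:

* **Selection lines.**  ~56 single-pair families are screened per
  generation; the 8 with the most biased brood sex ratio provide the next
  generation's dams (selection acts on females only; sires are drawn from
  the line at large, family-first so that male-biased families do not
  dominate the sire pool by producing more sons).  Ties in the ranking are
  broken by a seeded uniform jitter.  Under the default liability
  variances (sigma2_a = 0.35, sigma2_m = 0.05) the lines diverge to
  screened-mean BSRs around 0.71 and 0.26 after six generations —
  somewhat stronger than the empirical lines this design mimics (0.64 /
  0.35), which is expected since real screening adds measurement error
  and husbandry losses that are not modelled.
* **Diallel + backcross dataset.**  Founder families of the two lines are
  seeded with breeding-value means chosen so the line-mean BSRs are 0.64
  and 0.35 (`Phi^-1(p) * sqrt(sigma2_a + sigma2_m + 1)`).  Parental broods,
  a realized subset of the enumerated incomplete diallel (default 9 of the
  12-16 possible crosses per cross-type x block cell, matching the
  realized 8-10), and backcrosses of the between-line F1 families to fresh
  selection-line families complete the dataset.  Brood sizes are
  1-shifted negative binomial (mean ~30, dispersion 8), leaving a small
  fraction below the >11 analysis filter.  Offspring breeding values are
  parent-average plus a Mendelian deviate with variance
  `sigma2_a (1/2 - (F_s + F_d)/4)`; one maternal deviate per dam; sexes
  from the thresholded liability.  Founder sexes are design assignments,
  not liability draws, so phenotype tables contain brood offspring only.
* **What is not emulated.**  Real brood data involve husbandry losses,
  possible temperature (environmental) effects on sex, within-line genetic
  architecture beyond the infinitesimal model, and repeat broods per
  female; passing tests therefore demonstrate correctness of the methods
  under the liability model, not robustness to those features.

## Problem sizes and numerical choices

Desk-scale defaults are sized for interactive runs and the test suite:
datasets of ~2,900 individuals (16 + 16 parental families, 5 crosses per
diallel cell, 40 backcrosses, broods of ~25) and MCMC runs of 2 chains x
3,000 iterations (burn-in 500, thin 5, 1,000 retained).  The study-scale
settings (6 chains x 1,000,000 iterations, burn-in 100,000, thinning
5,000, 1,080 retained) are provided as `STUDY_SETTINGS` and used for
retained-draw accounting; they are practical on real hardware but not in a
quick test cycle.  Randomization tests default to 5,000 simulations with a
+1-corrected p-value and a pooled proportion male (a per-group option is a
documented alternative); percentile bands are 2.5/97.5.  The probit-BSR
spread statistic uses the continuity correction (k + 1/2)/(n + 1) so
all-male/all-female broods stay finite.  Truncated-normal draws clip the
uniform quantile at 1e-15 (bias negligible for |eta| < 7).  Matrix
comparisons in tests use 1e-6 (dense-vs-pedigree inverse) and 1e-8
(closed-form conversions).

## Known limitations

* The reduced-animal-model block update assumes terminal individuals are
  phenotyped-or-ignorable; models where a terminal's record must carry a
  different residual structure are out of scope.
* Brood CSV input to the full pipeline currently requires the simulator's
  phenotype table for the animal-model stage; fitting external data goes
  through `build_model` directly with a user-built phenotype frame.
* Heritability is reported for the probit link only; no non-binary traits.
* The observed-scale conversion assumes the fitted model's random effects
  are normal on the liability scale; model misspecification (e.g.
  non-normal common environments) biases both scales.
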