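# Methods

## Trait construction

Longevity is scored on 14 yearly binary records per cow, ages 2 through
15. Ages are expressed in completed years (`floor` of the fractional
age); a calving at *m* months is assigned to the yearly slot
`clamp(round(m / 12), 2, 15)`. The three definitions differ only in
how non-calving ages are coded:

* **TL** (traditional longevity): 1 while the cow is alive, 0 from the
  first age after culling. Within a cow the codes are non-increasing.
* **FLa** (functional, no missing): 1 if the cow calved at that age, 0
  otherwise — whether culled or merely not calving.
* **FLb** (functional, with missing): 1 if calved, 0 after culling,
  *missing* while alive without a recorded calving. Missing cells are
  excluded from the likelihood entirely.

Quality control removes, in a fixed order (so report counts are
reproducible): records with missing birth date, herd, culling reason or
date; cows with more than one culling record; cows born before 1990;
first calvings outside 19–30 months; culling ages over 20 years. A cow
culled over 15 years old is assigned to the natural-death group
regardless of its recorded reason ("culled due to age"); cows with an
unknown reason under 15 fall into miscellaneous. The rounding of
fractional calving ages to yearly slots is a declared convention — the
coding rules are usually stated per whole year of age and leave the
mapping of fractional ages open.

## Model

The working model for the binary codes (and for the continuous
responses in gaussian-mode simulations) is the linear random regression
animal model

```
y = X b + H q + Z a + W p + e
```

where every effect is a curve over age: each level owns `k+1`
random-regression coefficients on normalized Legendre polynomials
`phi_n(x) = sqrt((2n+1)/2) P_n(x)` of order `k`, evaluated at the
standardized age `x = -1 + 2 (age - 2) / 13`. "Order k" means
polynomial degree `k`, hence `k + 1` coefficients per effect and trait.

* `b` — fixed effects: an embryo-transfer contrast and one regression
  curve per year-season of birth (two six-month seasons; the
  granularity of "season" is a package convention). Prior
  `N(0, 1e10 I)`.
* `q` — herd-year-season curves, `q ~ N(0, Rq ⊗ I)`.
* `a` — additive genetic curves, `a ~ N(0, G0 ⊗ A)` with `A` the
  pedigree numerator relationship matrix.
* `p` — permanent-environment curves, `p ~ N(0, Rp ⊗ I)`.
* `e` — Gaussian residual, either one variance or one variance per
  yearly age class (14 classes).

`A^-1` is built by Henderson's rules with inbreeding (Meuwissen–Luo
recursion for `F`); ignoring inbreeding biases variance components, so
it is always accounted for. Unknown parents are treated as unrelated
founders; no genetic groups. Multi-trait analyses stack trait blocks:
coefficient vectors have dimension `(k+1) * n_traits`, covariance
matrices grow accordingly, and between-trait residual covariances are
fixed at zero (in the culling-reason analyses each cow appears in
exactly one trait, so they are not estimable anyway).

Applying a linear (Gaussian working likelihood) model to binary codes is
the standard practice in stayability-type evaluations; a threshold/probit
model is deliberately out of scope.

## Priors and Gibbs sampler

Coefficient covariance matrices carry inverted-Wishart priors
`IW(nu, Psi)` with `nu = 3` and `Psi = nu * (share * vp / mean_j ||t_j||^2) * I`,
where `vp` is the phenotypic variance of the response and the shares
are (q, a, p) = (0.1, 0.3, 0.2). This makes the implied age-scale prior
variance of each effect a stated share of the phenotypic variance while
remaining weak (3 prior degrees of freedom). Residual class variances
carry scaled inverse chi-square priors with `nu_e = 3` and scale
`0.4 * vp`. These hyperparameters are package defaults; published
analyses of this kind describe their priors only as weakly informative.

All full conditionals are conjugate and sampled exactly:

1. location effects, blocked per level (all coefficients of one
   animal/level jointly — better mixing than scalar updates). The
   additive block of animal *i* uses prior precision `A^-1_ii * G0^-1`
   and couples to relatives through the off-diagonal `A^-1` entries and
   their current values;
2. `Rq`, `Rp` from `IW(nu + n_levels, Psi + S)` with `S` the coefficient
   cross-product matrix, and `G0` from `IW(nu + n_animals, Psi + S_A)`
   with `S_A = a' A^-1 a`;
3. each residual class variance from its scaled inverse chi-square
   conditional.

One seeded `numpy` generator drives every draw, so a seed fully
determines the retained samples. A sampled covariance that fails its
Cholesky would abort with iteration diagnostics rather than being
silently repaired. Chain defaults are desk-scale (20,000 cycles, 10,000
burn-in, thin 10); production national evaluations use 500,000 /
250,000 / 10, available through the same configuration.

The per-level sweeps are compiled with numba; a fit of 1,000 cows
(14,000 observations, 2,000 pedigree animals, order 2) runs at roughly
4 ms per iteration on one core.

## Model comparison

The deviance is the *conditional* Gaussian deviance given all location
effects, `D = sum_o [log(2 pi s2_c(o)) + e_o^2 / s2_c(o)]`. `pD` is
`mean(D) - D(at posterior means)` and `DIC = D(at means) + 2 pD`. A
negative `pD` is reported with a flag, never clipped. Posterior model
probabilities are `exp(-Delta/2)` normalized over models, with
`Delta = DIC - min DIC` (max-trick for overflow safety); the lowest-DIC
model always receives the highest probability. Because the conditional
(not marginal) likelihood defines the deviance, DIC magnitudes are not
comparable across software that integrates the location effects out;
orderings and PMP arithmetic are.

Convergence: a native Geweke z-score compares the first 10% of a chain
with the last 50%, standardized by spectral-density-at-zero standard
errors (Bartlett-windowed long-run variance, truncation ~ `2 n^(1/3)`).

## Derived genetic parameters

Age-scale covariances come from the congruence transform
`phi = T Rq T'`, `Sigma = T G0 T'`, `theta = T Rp T'` with `T` the
14 x (k+1) Legendre covariate matrix (block-diagonal per trait for
multi-trait fits). Heritability at age j is
`h2_j = s2a_j / (s2a_j + s2q_j + s2p_j + s2e_j)`; genetic correlations
are `sigma_a(j,j') / sqrt(s2a_j s2a_j')`, within and between traits.
Posterior SEs of h2 and correlations come from applying the transform
per retained draw and summarizing — not the delta method.

Averages over correlation tables exclude the diagonal (within-trait)
and use all block entries (between-trait); the "3 to 12 years" window
is inclusive on both ends. Summary averages are per-pair means followed
by a grand mean, which reproduces the published Angus grand means
(0.12/0.20 between culling reasons, 0.64/0.73 between definitions)
exactly from the printed cells.

## Selection metrics

`EBV = T a_hat` over ages; RBVs standardize sire EBVs at one age to
mean 100, SD 5 (sample SD). Top fractions rank eligible sires (strictly
more than 5 daughters with records) by EBV at the selection age and
take the ceiling of `fraction * n_eligible`, ties broken by sire id for
determinism. The commonly-selected proportion is `100 |A ∩ B| / |A|`.
EDL models regress an observed daughter metric (average culling age;
proportions with completed culling age >= 6, 9, 12) on RBV by ordinary
least squares; accuracy is the raw Pearson correlation of predicted and
observed values, unadjusted for EBV reliability. Top-vs-bottom
differences are expressed as `100 (top - bottom) / top`, consistent
with the published tables.

## Synthetic data

The simulator generates exactly the structure the model assumes, so
recovery tests are well-posed:

* a multi-generation pedigree under a repeat-mating rule (every female
  born so far produces one litter per generation by a random male;
  sexes alternate by birth order);
* additive coefficients `a ~ N(0, G0 ⊗ A)` by founder draws plus
  Mendelian sampling with variance `(0.5 - 0.25 (F_s + F_d)) G0`;
* iid permanent-environment and herd-year-season coefficients; fixed
  year-season curves around a declining mean survival curve; an
  embryo-transfer contrast (default 0.05, ~5% ET cows).

Default coefficient covariances are scaled identities
(`G0 = 0.03 I`, `Rp = 0.04 I`, `Rq = 0.02 I`, residual 0.12), giving
age-average variance shares of roughly 0.15/0.2/0.1/0.55 on a
phenotypic variance of ~0.2 — heritabilities in the low-to-moderate
range reported for longevity traits. The default culling-reason mix
(25% natural death, 4% structural, 1% disease, 26% fertility, 10%
performance, 34% miscellaneous) follows the distribution reported for
North American Angus.

Two modes: **gaussian** emits the continuous linear-model response
directly (used for exact recovery tests); **binary** thresholds the
latent value — a cow is culled at the first age whose latent value
falls below the threshold, calving events occur with probability
`logistic(1.5 + latent)`, the first calving age is uniform on 19–30
months, and culling reasons are drawn independently of the latent value
by default. The latent-threshold mechanism is a stand-in for an unknown
real culling process: fitted linear-on-binary models recover binary-mode
parameters only approximately (by design), so quantitative recovery
claims rest on gaussian mode. What passing tests show about real data
is therefore limited to the internal consistency of the method, not the
realism of the culling process.

## Test problem sizes

The heavier checks run at desk scale, chosen to keep a full test run on
one core in the tens of minutes:

* h2 recovery: 10 replicates of ~1,000 cows (2,000 pedigree animals),
  order-2 truth with h2 = 0.3 at every age via scaled-identity
  covariances and residuals proportional to `||t_j||^2`; chains of
  20,000 (10,000 burn-in, thin 10). Shorter chains are not adequate
  here: at 8,000 cycles the coefficient-covariance chains still show
  Geweke |z| > 3 and the under-dispersed draws narrow the credible
  bands.
* residual-structure selection: 5 seeds of ~240 cows with the residual
  variance doubled at ages 3–4; chains of 3,000.
* pedigree-algebra oracle: 200 random pedigrees up to 200 animals,
  sparse `A^-1` against the dense tabular `A`, tolerance 1e-8.
* fixed-variance Gibbs against a direct sparse mixed-model-equation
  solve, batch-means Monte-Carlo standard errors, 3-SE criterion.

## Known limitations

* Linear working likelihood on binary codes; no threshold model, no
  proportional-hazards comparison, no censored (still-alive) cows.
* Between-trait residual covariances are fixed at zero.
* The Heidelberger–Welch diagnostic is not implemented natively; only
  Geweke is. (An external diagnostics library can be applied to the
  stored chains.)
* No genomic information; pedigree-based evaluation only.
* Heritability and correlation estimates at the extreme ages (2 and
  >12) are the least stable, as expected for high-order polynomial
  bases at interval endpoints.
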