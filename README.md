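# herdlife

Genetic evaluation of cattle longevity with Bayesian random regression
animal models.

Longevity — how long a cow stays alive (and productive) in the herd
after her first calving — is one of the most economically important
traits in beef cattle, and one of the hardest to select for: the
phenotype is only complete at the end of life, and culling happens for
genetically different reasons (natural death, structural problems,
disease, fertility, performance). `herdlife` implements the full
evaluation pipeline for this problem, for quantitative geneticists and
breeding-program analysts:

* **trait construction** — 14 yearly binary records per cow (ages 2–15)
  under three definitions: traditional longevity (TL, alive/culled),
  and two functional variants requiring a calving at each age (FLa
  codes non-calving ages 0; FLb codes them missing while alive), plus
  quality control and culling-reason grouping;
* **pedigree machinery** — pruning to ancestors of phenotyped animals,
  inbreeding (Meuwissen–Luo), sparse `A^-1` by Henderson's rules;
* **model fitting** — single- and multiple-trait linear random
  regression animal models on normalized Legendre polynomials, fitted
  by a blocked Gibbs sampler with inverted-Wishart and scaled
  inverse-chi-square conjugate updates, homogeneous or 14-class
  heterogeneous residual variance;
* **model comparison** — DIC, effective parameters pD, posterior model
  probabilities, Geweke convergence diagnostics;
* **genetic parameters** — age-wise heritabilities and genetic
  correlations (within and between traits) from the covariance
  function `Sigma = T G0 T'`, with posterior SEs from per-draw
  transformation;
* **selection metrics** — EBV curves, relative breeding values (mean
  100, SD 5), expected daughter longevity regressions, top-sire
  overlap, prediction accuracy;
* **a synthetic-data generator** that produces pedigreed life histories
  with exactly the covariance structure the model assumes, so every
  stage is testable without proprietary data.

The model, in standard animal-breeding notation:

```
y = X b + H q + Z a + W p + e,      a ~ N(0, G0 ⊗ A)
```

with `q` (herd-year-season), `p` (permanent environment) iid random
regression curves, `b` fixed (embryo transfer + year-season curves),
and age-wise heritability `h2_j = s2a_j / (s2a_j + s2q_j + s2p_j + s2e_j)`.
See `docs/methods.md` for priors, conditionals, and conventions.

## Worked example

Simulate 400 cows, code FLb, fit an order-2 model with heterogeneous
residual variance, and summarize heritability over ages:

```python
from herdlife.simulate import SimulationConfig, simulate_dataset
from herdlife.records import apply_quality_control, build_longevity_panel
from herdlife.pedigree import prune_pedigree
from herdlife.rrm import ModelSpec, ChainConfig, build_design, gibbs_fit
from herdlife.genpar import posterior_genetic_parameters, average_correlation
from herdlife.basis import legendre_T

cfg = SimulationConfig(n_founders=200, n_generations=2, seed=7)
ped, truth, raw = simulate_dataset(cfg)
kept, report = apply_quality_control(raw)
panel = build_longevity_panel(kept, "FLb")
spec = ModelSpec(order=2, residual_structure="heterogeneous_by_age")
design = build_design(panel, kept, spec,
                      ped=prune_pedigree(ped, list(panel.cow_ids)))
draws = gibbs_fit(design, spec,
                  ChainConfig(length=5000, burn_in=2500, thin=5, seed=7))
gp = posterior_genetic_parameters(draws, legendre_T(2))
print(gp.h2_frame().round(3).head(6).to_string(index=False))
m, se = average_correlation(gp.corr_mean, "3..12")
print(f"mean genetic correlation (ages 3-12): {m:.2f} +/- {se:.2f}")
```

Output:

```
 age    h2    se  lower95  upper95
   2 0.144 0.027    0.098    0.204
   3 0.215 0.042    0.141    0.306
   4 0.141 0.030    0.091    0.203
   5 0.057 0.013    0.036    0.083
   6 0.028 0.006    0.018    0.042
   7 0.019 0.004    0.013    0.027
mean genetic correlation (ages 3-12): 0.73 +/- 0.04
```

Each row is the posterior mean heritability of the binary FLb code at
one age with its posterior SE and equal-tail 95% interval: on this
small simulated herd the trait is most heritable around ages 3–4 and
nearly exhausted after age 6 (few cows calve that long here), while
adjacent ages stay strongly genetically correlated — the typical
random-regression picture for stayability-type traits.

The same flow is available as a shell pipeline:

```sh
herdlife run -o my_run --seed 7          # simulate -> QC -> fit -> reports
herdlife simulate -o sim --seed 3        # data generation only
```

which writes pedigree/records/panels, QC and descriptive reports, the
posterior draws, heritability and correlation tables, and sire reports
as delimited text in the output directory.

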