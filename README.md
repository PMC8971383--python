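# paleobrain

Did a large brain, relative to body size, help mammals survive the Late
Quaternary megafauna extinctions?  `paleobrain` is a phylogenetic comparative
pipeline for answering that kind of question: it relates brain size (endocast
volume, the infill of the cranial cavity — the only brain-size proxy
available for fossils) to body mass and extinction status across a phylogeny
containing both extant species and fossil tips.

## What it computes

For a rooted, non-ultrametric phylogeny and a species trait table the
pipeline fits, compares by AIC, and cross-checks four model families:

1. **Allometric regressions** of log₁₀ endocast volume *EV* on log₁₀ body
   mass *M*, with extinction status as a parallel-intercept term and
   taxonomic order as an optional random intercept:
   log₁₀ *EV* = *a* + *b*·log₁₀ *M* + *s*·I(extinct) + u(order) + ε.
   The extant/extinct brain-size ratio is 100·10^(a_extant − a_extinct).
2. **PGLS** — the same regression with residual covariance σ²**C**, where
   **C**ᵢⱼ is the depth of the most recent common ancestor of tips *i*, *j*
   (Brownian motion).  Fossil tips just contribute smaller diagonal entries.
3. **Phylogenetic ridge regression** — tip phenotypes regressed on the
   branch-incidence matrix **L** (entry = branch length if the branch lies on
   the root-to-tip path), min ‖y − m·1 − **L**β‖² + λ‖β‖², giving one signed
   evolutionary rate per branch; λ by leave-one-out cross-validation.  The
   |rates| rescale the tree's branch lengths (total branch length held
   constant), relaxing the constant-rate Brownian assumption, and feed a
   randomization test for a rate difference between extinct and extant tips.
4. **Phylogenetic logistic mixed models** — extinction status (extinct = 1)
   as a Bernoulli response, logit p = β₀ + β_M·log₁₀M + β_EV·log₁₀EV + u,
   u ~ N(0, σ²_p **C̃** + σ²_o **ZZ**ᵀ), fitted at the joint penalized-IRLS
   mode with variance components maximizing a Laplace-approximate likelihood.
   A 3 predictor-sets × 3 trees grid (original, brain-rate-rescaled,
   body-size-corrected-rate-rescaled) is compared by AIC.

A seeded synthetic-data generator reproduces the statistical structure of the
study data (≈340 species, 10 orders, body masses 1.4–11,000 kg, allometric
endocast volumes with order grade shifts, ~15% extinct by a logistic model
with a positive body effect and a negative brain effect, extinct species as
fossil tips), so every estimator can be scored against known truth.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/02_allometry_tables.py
python analysis/03_rates_and_shift_test.py
python analysis/04_extinction_models.py
python analysis/05_sensitivity_same_specimen.py
```

The first script prints the generated study conditions:

```
340 species, 40 extinct (11.8%), body mass 0.7-15766 kg
```

`02` fits the eight allometric models.  On this dataset extant species carry
brains ~97% larger than extinct species of the same size by a single
regression line (ratio 196.7%), shrinking to ~17% once order grade shifts
absorb the clade-level part of the signal:

```
                       model  ratio_extant_extinct  status_p      r2       aic
          ols: body + status              196.7430    0.0000  0.8669   -4.2014
mixed: body + status + order              116.8401    0.0001  0.9761 -587.2141
```

`03` estimates branch rates of brain-size evolution (body-size corrected)
and finds no rate shift between extinct and extant species:

```
observed mean |rate| difference (extinct - extant): +0.0622
randomization p (two-tailed, 10000 permutations): 0.104
```

`04` fits the nine logistic models.  Brain size predicts survival beyond
body size on every tree — e.g. on the original tree the body+endocast model
(slopes +7.01 / −7.09) beats body-only by ~24 AIC points (185.7 vs 210.1) —
mirroring the generating coefficients +6 / −6:

```
        tree           predictors  slope_endocast  slope_body     aic
not rescaled          pglmm(body)             NaN       1.172 210.062
not rescaled pglmm(body+endocast)          -7.091       7.013 185.680
```

`05` reruns everything on the species whose body mass and endocast come from
the same specimen and reports side-by-side deltas.

All tables land under `results/`.

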