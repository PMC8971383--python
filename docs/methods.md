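# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees and the Brownian covariance

A `Phylogeny` is rooted with finite, non-negative branch lengths in time
units.  Extinct species are fossil tips: their root-to-tip depth is smaller
than the tree height, so trees need not be ultrametric and none of the
methods assume they are.  Polytomies are resolved deterministically
(ladderized by subtree size, ties by smallest tip label) with zero-length
internal branches; zero-length branches leave the Brownian covariance
unchanged, so the resolution is statistically neutral.

Under Brownian motion the trait covariance of tips *i* and *j* is
proportional to the depth of their MRCA.  The matrix is assembled as
**P** diag(ℓ) **P**ᵀ, where **P** is the 0/1 tips × branches incidence matrix
and ℓ the branch lengths; the test suite checks it against an exhaustive
pairwise MRCA-walking oracle.

### Rate rescaling

Branch lengths are multiplied by the absolute value of their estimated
evolutionary rate and then by one global constant.  "Total evolutionary
time" is interpreted as the **sum of branch lengths**: unlike tree height it
is well defined for non-ultrametric trees, and a single global multiplier
preserves it exactly (to < 1e-10 relative error, which the acceptance suite
checks at 1,000 tips).  Preserving tree height instead is available via
`preserve="height"`.  Zero-rate branches are floored at 1e-8 × the mean
rescaled branch length so downstream covariances stay positive definite.
Each branch is identified by its child node; rates and lengths share that
indexing everywhere.

## Trait table

Endocast volume (cm³) is the brain-size measure.  Extant species known only
from brain mass are converted via tissue density 1.036 g/cm³ and then the
log-log calibration log₁₀EV = −0.0015 + 1.0222·log₁₀BV (log base 10,
matching the global log₁₀ convention); a measured endocast always takes
precedence.  Inclusion rules: body mass ≥ 1.4 kg (the boundary species is
retained — "smaller than" excludes), and, where a landmass is recorded,
strictly > 50,000 km² ("larger than" excludes the boundary).  Specimen-level
rows collapse to species means **on the log scale** (geometric means),
because every downstream model is log-linear; arithmetic means remain
available behind a flag for sensitivity work.  Species names match tree tips
after space/underscore and case normalization; unmatched species are
reported and dropped from phylogenetic models only, with a hard-fail option.

## Allometric models

Status enters as a two-level intercept shift only (no status × slope
interaction).  Mixed models use a random intercept per taxonomic order:
coefficients and the status p-value come from the REML fit, the AIC from an
ML refit (REML AICs are not comparable across fixed-effect structures), with
the two variance parameters counted.  The headline mixed-model R² is
**conditional** ((fixed + random variance)/total); the marginal flavor is
reported alongside.  Status p-values in mixed models are Wald z tests — a
Satterthwaite degrees-of-freedom correction was considered and dropped as
out of proportion for a single balanced contrast at these sample sizes.

## PGLS

β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with σ² profiled analytically (ML: whitened RSS/n);
the AIC counts fixed effects + 1.  The Wald t-test for status uses the
unbiased residual variance (whitened RSS/(n−k)).  R² is 1 − whitened
RSS/whitened TSS against the GLS intercept-only model, and is optional
output.  No Pagel's λ or OU transform: the alternative to strict Brownian
motion here is the rate-rescaled tree.  Equivalence with a C^(−1/2)
whitening-then-OLS oracle (coefficients to 1e-8, log-likelihood to 1e-6) is
enforced over 100 random trees in the acceptance suite.

## Phylogenetic ridge regression

Tip values are modeled as the root state plus the signed sum of per-branch
changes along the root-to-tip path, penalizing only the branch coefficients:
min ‖y − m·1 − Lβ − γx‖² + λ‖β‖².  The optional tip-level predictor x
(body size) is unpenalized and its coefficient γ is reported but is not a
rate.  λ is selected on a 25-point log-spaced grid (10⁻⁴…10⁴) minimizing
leave-one-out cross-validated prediction error computed from the hat-matrix
diagonal.  This selection rule is this package's own design choice; exact
numerical agreement with other rate-estimation software is not a goal — the
estimator is pinned instead by its closed-form oracle (explicit-inverse
ridge at fixed λ, 1e-8) and by a rate-recovery simulation (a clade evolving
at 10× shows elevated mean |tip rate| in ≥ 90% of replicates).

### Rate-shift randomization test

The statistic is the difference in mean absolute **terminal-branch** rate,
extinct − extant (a per-species comparison; internal branches are estimated
but excluded).  The null permutes the status-label vector across tips, which
makes the two-tailed p exactly invariant to which level is called
"extinct"; the add-one correction (p = (1 + #{|null| ≥ |obs|})/(1 + N))
keeps p in (0, 1].  Default 10,000 permutations, seed mandatory.  Type-I
error at the 5% level is verified to land in 0.05 ± 0.02 under
exchangeable tip rates.

## Phylogenetic logistic mixed model

Status (extinct = 1) follows a Bernoulli-logit with linear predictor
Xβ + u, u ~ N(0, Σ(θ)), Σ = σ²_p C̃ + σ²_o ZZᵀ.  C̃ is the Brownian
covariance divided by its mean diagonal so variance components are
comparable across original and rescaled trees.

*Estimation.*  At fixed θ, (β, u) is the joint mode of the penalized
binomial log-likelihood, found by penalized IRLS (each sweep is one Newton
step; the working update is the V-form GLS with V = Σ + W⁻¹, so a singular
Σ — e.g. the rank-deficient order block — needs no inverse).  The
linearization point is clipped at |η| ≤ 15 and updates are step-halved when
the parameter change grows, which stabilizes ill-conditioned rescaled-tree
covariances.  θ maximizes the Laplace approximation of the marginal
likelihood at that mode, ℓ(θ) = ℓ_cond − ½uᵀΣ⁻¹u − ½log|I + W^½ΣW^½|
(computed entirely from V-form quantities), via bounded scalar optimization
for one component and Nelder-Mead for two, on the log-variance scale with
bounds e⁻¹⁰…e⁶.  A purely PQL variance step (Gaussian ML on the working
response) was tried first and abandoned: on ill-conditioned rescaled-tree
covariances its profile likelihood can push the variance to the boundary
and destabilize the fit, whereas the Laplace objective is bounded and also
makes the reported AIC internally consistent with the estimation.

*Reporting.*  AIC = −2·ℓ_Laplace + 2(p + #free variance components).
Predictors are centered/scaled internally; slopes and Wald SEs are
back-transformed to the log₁₀-trait scale.  Pinning all variances at zero
reduces the fit to ordinary logistic regression (verified to 1e-4 against
an independent GLM fit).  R² is the latent-scale binomial variant with
distribution-specific variance π²/3; both marginal and conditional values
are emitted and the conditional one is the headline, an explicit assumption
since comparison tables elsewhere rarely name their R² flavor.  Large slope
magnitudes under collinear log body/log brain predictors are expected and
left unshrunk.

## Synthetic data

The generator emulates the compiled study data: a birth-death tree (birth
1.0, death 0.3, height normalized to 1) of 340 species; 10 taxonomic orders
assigned as the 10 largest clades so taxonomy is phylogenetically coherent;
log₁₀ body mass as a Brownian realization affinely rescaled into
log₁₀(1.4)–log₁₀(11,000) kg (preserves the covariance structure up to
scale — a deliberate departure from a pure Brownian process); endocast
volume = 0.9 + 0.75·log₁₀M + order offset (SD 0.3 dex) + Brownian residual
(variance 0.02 over the tree height, optionally multiplied inside
designated clades); extinction status Bernoulli with logit
β₀ + 6·log₁₀M − 6·log₁₀EV, β₀ calibrated by root finding so the expected
extinct fraction is 15%.  18 species are flagged as literature-mean body
masses for the sensitivity rerun.  The allometric intercept 0.9 log₁₀ cm³
at 1 kg and the residual scales were chosen once as realistic mammalian
values (a 100 kg mammal gets ≈ 220 cm³, OLS R² lands in the high 0.8s).

Because the birth-death simulator stops exactly at the last birth (which
would leave zero-length cherry pendants and a singular covariance), every
surviving lineage is extended by the exponential waiting time to the next
event.

*Fossilization.*  Status is drawn from the logistic model, then each
extinct tip's pendant branch is truncated by a uniform 5–60% fraction and
the removed segment's Brownian increment is subtracted from both traits, so
the recorded fossil phenotype is the trait value at the truncation point
and per-branch rates stay calibrated (naively keeping the endpoint values
would inflate extinct tip rates by construction).  The status draw itself
uses the pre-truncation value — an incoherence of order √(σ²·removed
length) on the logit scale, small against slopes of ±6.  Extinct-status
body masses can therefore drift slightly outside the configured range.

*What passing tests do and do not show.*  The generator's extinction signal
is partly a clade-level effect (order grade shifts enter the logistic
through endocast volume), so phylogenetic models legitimately absorb part
of the status contrast that OLS sees — synthetic tests therefore assert the
status-model AIC advantage only where the generative model implies it.
Real data add everything the generator omits: measurement error, taxonomic
error, non-Brownian evolution, biased fossil sampling, and correlated
landmass/insularity effects.  Parameter-recovery results here show
estimator correctness under the generating model, not robustness to those.

## Problem sizes

Test and acceptance runs use the study scale where it matters (340-tip
datasets, 200 recovery replicates, 500 calibration replicates, 10,000
permutations for headline p-values, 1,000-tip conservation check) and
smaller trees (≤ 120 tips) for oracle and null-calibration loops, chosen so
the full suite completes in a few minutes on one CPU.

## Known limitations

- The ridge λ rule (grid LOOCV) is a documented stand-in for the reference
  rate-estimation software's internal optimization; per-branch rates agree
  with it qualitatively, not numerically.
- PQL-style mode estimation with a Laplace likelihood is approximate for
  binary responses; slopes can be mildly attenuated relative to the
  generating values at these sample sizes, and AICs are comparable within,
  not across, response definitions.
- The sensitivity rerun prunes the tree to the retained species; covariance
  entries below the pruned MRCA are unchanged, but the shared root-stem
  path is dropped, as in standard tip-dropping.
- Cross-family AIC comparisons in the allometry table (mixed vs PGLS rows)
  assume identical response data and ML fitting; the table mirrors that
  presentation deliberately.
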