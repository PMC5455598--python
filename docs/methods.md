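# Methods

## The latent nodal model

Every analysis in this package rests on one sampling model. A resected
patient carries a nodal population of fixed size `M` (`m_total`, default
40), of which `p ≥ 0` nodes are truly involved. Pathology examines `n`
nodes (`eln_count`), drawn without replacement, and reports `k` positive
(`positive_count`); `k` is therefore hypergeometric in `(p, M, n)`.
Declared N stage is what the sample shows: N0 exactly when `k = 0`.
Occult nodal disease means `p > k` — involvement the examination missed.

`M` is a single cohort-level constant rather than a per-patient random
quantity. Nothing in the inference identifies a per-patient `M` from
`(n, k)` pairs alone, and using one constant keeps the generator and the
inference model exactly matched; 40 is an upper-range figure for a
complete hilar plus mediastinal dissection. It is exposed as
configuration everywhere it appears.

## Synthetic registry generator (`elncut.registry`)

The generator makes stage migration and the survival benefit of thorough
examination *emerge from the mechanism* rather than being painted onto
the data:

- **Covariates.** Sex, histology (five categories), T stage, tumor
  location and operation type are drawn from fixed frequency tables; age
  is normal (mean 62, SD 10) truncated to [30, 90], a plausible surgical
  population.
- **Latent involvement.** Pr(p ≥ 1) is logistic in covariates (intercept
  −1.2 plus category log-odds, e.g. +1.0 for T3); given involvement, the
  burden is zero-truncated geometric with success parameter `q = 0.35`
  (mean ≈ 2.9 positive nodes), a right-skewed shape matching how positive
  counts concentrate near 1–3 with a long tail.
- **Examined count.** Negative binomial truncated to `[1, M]` by
  inverse-CDF sampling (deterministic per uniform draw, no resampling
  loop). Two styles: low-yield (mean 8.0, dispersion 1.7; median 7, IQR
  ≈ 4–12) and high-yield (mean 16.5, dispersion 3.7; median 15, IQR
  ≈ 10–22). The parameters were chosen by matching those target
  quantiles of the truncated pmf directly. A non-finite dispersion
  degenerates to a point mass (every patient fully examined) — useful
  for testing the exhaustive-sampling limit.
- **Survival.** Exponential proportional hazards: baseline rate
  0.05 / year times `exp` of covariate log-hazards (age +0.025/year over
  60, T-stage up to +1.0, ...), plus `occult_log_hazard` (default 0.3)
  per *undetected* positive node `p − k`. Censoring is exponential
  (0.05 / year) truncated at 10 years of administrative follow-up.
- **The configurable break.** Under hypergeometric sampling with latent
  involvement independent of `n`, the expected undetected count is
  exactly linear in `n` (`E[p](1 − n/M)`), so the occult penalty alone
  produces a smooth, kink-free hazard trend — it cannot place a
  structural break at a chosen threshold. The generator therefore adds a
  staging-adequacy term: `break_slope` (default 0.05) log hazard per
  examined node *short of* `break_eln`, and zero above it. This encodes
  the clinical reading that each node short of an adequate dissection
  leaves residual-disease risk, and makes the log-HR series piecewise
  linear with its kink exactly at `break_eln`. The default slope is
  strong enough for the kink to stand out of the series noise at the
  cohort sizes used here (tens of thousands).
- **N substage.** Among detected node-positive patients, N2 is assigned
  with probability `k/(k+2)` (more detected nodes, higher odds of
  mediastinal involvement), so N1/N2 subsets exist for subgroup
  analyses; the binary N0 vs N+ distinction is what the models use.

What the generator does **not** emulate: station-level node geography
(N1 vs N2 station counts), non-proportional hazards, informative
censoring, inter-institutional counting variation, and correlation
between ELN count and unmeasured prognosis (e.g. surgeon quality). Tests
passing on this generator therefore demonstrate the *statistical
machinery* — not that real registries satisfy these assumptions.

A second generator, `generate_parametric_cohort`, produces cohorts whose
declared node-positive status is directly Bernoulli-logistic in ELN count
and whose hazard is directly log-linear in ELN count. Its fitted models
are exactly the data-generating models, so the true coefficients are
known by construction; it exists for confidence-interval coverage and
calibration experiments, where the mechanistic generator's indirect ELN
effects have no closed-form "truth".

## Occult-disease inference (`elncut.detection`)

Hypergeometric probabilities come from `scipy.stats.hypergeom`
(log-gamma based, no factorial overflow); the pmf is renormalized only if
it deviates from 1 by more than 1e-12. The prior over `p` is the
empirical positive-count distribution among patients with
`eln_count ≥ min_eln` (default: the cohort's 90th ELN percentile),
treated as near-complete sampling — a pragmatic completeness proxy; no
deconvolution from partially sampled patients is attempted. A posterior
whose denominator is zero (an observation impossible under the prior)
raises an error rather than returning a silent 0.

## Effect series (`elncut.effects`)

Logistic models are fit with statsmodels GLM, Cox models with lifelines
(Efron tie handling). Adjusters follow the two model families: histology,
T stage, tumor location and operation type for stage migration; sex, age
(linear), histology, T stage and operation type for survival. Categories
are one-hot coded against their largest level.

The per-count series fits ELN as a categorical factor in a single joint
model (not repeated dichotomies), reference = the smallest retained
count. Sparse levels are pooled before fitting: counts above the 99th
percentile form a terminal bin, then any level with fewer than
`sparsity_floor` patients (default 20) merges with its nearest neighbour
(ties toward the lower level) until all levels meet the floor. Each
pooled level is plotted at its patient-weighted mean count, and the
pooling map is recorded in the output. The floor of 20 stabilizes
level-specific standard errors without erasing the series shape.

The mean-positive-vs-ELN regression is OLS on the per-level means (same
pooling), one point per retained level; a constant series has undefined
R² and is reported as NaN. Histology-interaction tests are joint Wald
tests of the ELN × group product terms.

## Break-point detection (`elncut.breakpoint`)

LOWESS uses statsmodels' implementation (tricube weights, local linear,
3 robustness iterations by default, bandwidth 2/3 — the classic
default); an independently coded tricube local-linear reference in the
test suite pins the numerics. The Chow scan fits segment lines on either
side of each candidate `c` (left segment `x ≤ c`) and compares against
the pooled line with `F = ((RSS_p − RSS₁ − RSS₂)/2)/((RSS₁+RSS₂)/(n−4))`
referred to F(2, n−4). Numerical guards: a pooled RSS at machine-zero
scale reports F = 0, p = 1 (the series is already one line); segment RSS
at machine zero with nonzero pooled RSS reports F = ∞, p = 0. On
noiseless piecewise-linear input the kink point lies on both segment
lines, so candidates `c−1` and `c` tie at F = ∞; ties resolve to the
larger candidate, which is the construction point.

The scan is applied to the LOWESS-fitted values (smooth first, then
test); the raw-series scan is also computed and reported. Candidates
default to the range that leaves `min_segment` (default 3) points per
side; candidates inside an explicit user range that violate this are
skipped and recorded. Segment regressions are unweighted: inverse-
variance weighting of the series points is available to callers but not
default, since the per-level standard errors are themselves estimates.

Two statistical caveats are deliberate and documented rather than
corrected: (i) reported p-values are nominal fixed-candidate Chow
p-values, and selecting the maximal F inflates the type-I error (the
test suite measures this inflation and asserts it is present);
(ii) LOWESS at bandwidth 2/3 smears the kink over its neighbourhood, and
together with the residual occult-penalty slope above the threshold this
biases the detected break ≈ 1 node low at the default settings — the
end-to-end recovery experiments bound the miss at ±2.

Cut-point selection is survival-priority: the survival-series break is
returned, with a concordance report (min–max spread) across the other
series and a warning when the spread exceeds 6 nodes.

## Cut-point validation (`elncut.validation`)

The dichotomized model is Cox PH with an `eln ≥ threshold` indicator plus
the survival adjusters, on the declared node-negative subset by default
(threshold default 16). Adjusted curves are the fitted model's predicted
survival at one reference covariate profile (mean age, modal categories)
with the indicator switched off/on — a deliberate choice over averaging
the covariate distribution, because it shows the pure threshold contrast;
the profile is recorded in the output. Validation on an independent
cohort re-runs the same fit; independence is checked only via provenance
metadata (a warning on identical tags, nothing stronger).

## Pipeline and problem sizes

`run_pipeline` persists every intermediate as TSV/JSON so each stage can
be re-run standalone, and the report validates against
`report_schema.json` (a small built-in checker covers the schema subset
used: types, required keys, items). Reports contain no timestamps, so a
fixed seed yields byte-identical output.

Default study sizes: the analysis scripts use 20,000 patients per cohort
and the acceptance script 40,000 — large enough that per-level series
standard errors (≈ 0.1 on the log scale) are well below the configured
break signal, small enough to keep a full pipeline run under half a
minute. Coverage experiments use 50 replicates of 30,000; end-to-end
break recovery uses 20 replicates of 40,000.

## Known limitations

- The prior-completeness proxy (top-decile ELN patients) retains some
  occult disease; the estimated prior is slightly light in its tail, and
  occult probabilities are correspondingly mildly conservative.
- Break-location inference carries the ≈ 1-node smoothing bias noted
  above and reports no confidence interval (single-break Chow scan only;
  no multiple-break detection).
- The max-F selection p-value inflation is reported, not corrected.
- Adjusted curves at a reference profile are not marginal (population-
  averaged) curves; with strong covariate effects the two differ.
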