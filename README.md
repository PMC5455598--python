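# elncut

How many lymph nodes must be examined after lung cancer resection before a
"node-negative" label can be trusted — and does more thorough examination
translate into longer survival?

`elncut` is an analysis pipeline for that question. It targets resected
non–small-cell lung cancer (NSCLC) registry data: one row per patient with
the examined-lymph-node (ELN) count, the number of positive nodes found,
declared N stage, covariates and follow-up. Because large population
registries of this kind are access-restricted, the package ships a
mechanistic synthetic-registry generator so the entire analysis is
reproducible end-to-end from first principles.

## The model

**Detection is a sampling problem.** A patient harbors `p` truly involved
nodes among a nodal population of `M`; pathology examines `n` of them
without replacement, so the observed positive count `k` is hypergeometric,

    Pr(k | p, M, n) = C(p, k) C(M−p, n−k) / C(M, n).

With a prior `π(p)` over the true positive count (estimated empirically
from the most thoroughly examined patients), Bayes' theorem gives the
probability that a declared node-negative patient has occult disease:

    Pr(p > 0 | k = 0, n) = Σ_{p>0} π(p) Pr(0|p,M,n) / Σ_p π(p) Pr(0|p,M,n),

which falls monotonically in `n` and is exactly 0 at `n = M`.

**Stage migration and survival.** The per-node association with declared
node-positive status is estimated by adjusted binary logistic regression
(OR per additional examined node), and the association with overall
survival by adjusted Cox proportional-hazards regression (HR per node,
Efron ties). Fitting ELN as a categorical factor against a reference of
one examined node yields per-count OR/HR series.

**Cut point.** Each series (OR, HR, mean positive nodes, occult
probability) is smoothed with a LOWESS smoother (bandwidth 2/3) and
scanned for a structural break with the Chow F test,

    F = ((RSS_pooled − RSS₁ − RSS₂)/k) / ((RSS₁ + RSS₂)/(n − 2k)),  k = 2.

The survival-series break is the selected cut point; it is then evaluated
by dichotomizing ELN at the threshold (adjusted HR, at-or-above vs below)
on derivation and independent validation cohorts, with covariate-adjusted
survival curves.

**Synthetic registry.** Each simulated patient carries a latent positive
count (logistic in covariates; zero-truncated geometric burden), an ELN
count (truncated negative binomial, low-yield or high-yield style), a
hypergeometric observed positive count, and exponential proportional-
hazards survival with a mortality penalty per undetected positive node
plus a configurable kink that places the survival break at a chosen ELN
threshold. See `docs/methods.md` for every parameter and default.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end:

```bash
python analysis/01_simulate_cohorts.py      # derivation / validation / high-yield
python analysis/02_occult_probability.py
python analysis/03_effect_series.py
python analysis/04_breakpoints.py
python analysis/05_validate_cutpoint.py
```

With the default settings (n = 20,000 per cohort, seed 17) this prints,
among other things:

```
derivation: n=20000, deaths=12268, median ELN=7 (IQR 3-11), node-negative 86.6%
high_yield: n=20000, deaths=10652, median ELN=15 (IQR 9-21), node-negative 78.9%

  declared node-negative after  7 nodes examined: P(occult disease) = 0.206
  declared node-negative after 16 nodes examined: P(occult disease) = 0.135
  declared node-negative after 40 nodes examined: P(occult disease) = 0.000

  stage-migration OR: 1.083 (95% CI 1.077-1.089, p=1.5e-176)
  OS HR, node-negative: 0.951 (95% CI 0.948-0.955, p=3.2e-163)

  survival: break at 15 (F=538.5, nominal p=6.9e-22)
selected cut point (survival priority): 15 examined nodes

  derivation: HR 0.531 (95% CI 0.498-0.566, ...)
  validation: HR 0.574 (95% CI 0.539-0.612, ...)
```

Reading: examining more nodes shifts patients from declared node-negative
to node-positive (OR > 1 per node — stage migration), reduces the
probability of occult nodal disease, and is associated with lower
mortality (HR < 1 per node). The survival benefit levels off at the
detected break (here 15, one node below the generator's configured kink
at 16 — the smoothing bias is characterized in `docs/methods.md`), and
patients at or above the threshold have markedly lower adjusted hazard.

The same stages are available as a CLI (`elncut simulate | occult |
effects | breakpoint | validate | run`) and as library functions
(`elncut.generate_cohort`, `elncut.occult_probability`,
`elncut.eln_effect_series`, `elncut.chow_scan`,
`elncut.dichotomize_and_fit`, `elncut.run_pipeline`).

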