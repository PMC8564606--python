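# impairfit

Effects of physical impairments on fitness correlates of wild small
mammals, estimated from long-term mark–recapture trapping data.

Wild white-footed mice (*Peromyscus leucopus*) are routinely recaptured
with missing or deformed tails, limbs and eyes. Whether such impairments
actually reduce fitness is an empirical question: on trapping grids one
can compare impaired and unimpaired mice on survival (persistence time),
body mass, home-range size and ectoparasite burden, taking care that the
comparisons are not poisoned by reverse causality or by the selection
biases inherent in observing impairment only at recapture. `impairfit`
implements that analysis battery as a tested, reusable pipeline, together
with an individual-based simulator of the trapping design whose known
ground truth backs every estimator with parameter-recovery tests.

## What it computes

* **Cohorts from capture tables** — long-format CSV, one row per capture
  (tag, plot, year/week/day, station coordinates, sex, pelage age class,
  mass, larval tick and bot fly counts, impairment codes); validation,
  per-individual histories, impairment classification (tail-snip
  exclusion, tail yields to rarer limb/eye types, permanent status from
  first coded capture, "future impaired" levels for pre-onset captures).
* **Survival** — persistence time $T$ = weeks between first and last
  capture; risk-set matching of each impaired case to all never-impaired
  controls sharing its age class and week of first capture and persisting
  at least to the case's first impaired capture; Kaplan–Meier curves,
  log-rank tests, and a matched-set-stratified Cox model (Efron ties)
  giving hazard ratios per impairment category.
* **Mass** — adult captures (11 g < mass ≤ 40 g) in a linear mixed model
  `mass ~ impairment + sex * season + (1|individual) + (1|plot) + (1|year)`
  fit by a sparse penalized-least-squares REML solver for crossed random
  intercepts (validated against lme4); effects also expressed as percent
  of mean adult mass. A matched conditional-logistic design tests whether
  mass predicts *becoming* impaired.
* **Movement** — centre of activity and mean squared distance (MSD, m²)
  per resident (≥3 captures in a plot–year–season), 15 m edge
  diagnostics, and a log-MSD mixed model with percent-scale translation
  $(e^{\beta}-1)\times100$.
* **Ectoparasites** — April–October tick window and per-year bot fly
  infestation windows with calendar-dichotomised season levels
  (August–September high, burden criteria recomputed as diagnostics);
  logistic and negative binomial mixed models (maximum likelihood with
  adaptive Gauss–Hermite quadrature over the individual random intercept,
  validated against glmmTMB), zero-truncated NB for infested mice, and
  AIC-corrected Vuong comparison against zero inflation.
* **Shared inference** — smallest-AIC model selection,
  change-in-estimate confounder screening (10% default), Pearson
  chi-squared and correlation descriptives.
* **Simulator** — six 150 m × 150 m plots with 11 × 11 stations at 15 m,
  sessions every 3–4 weeks (May–November, 2–3 days), imperfect capture,
  geometric lifetimes, weekly impairment hazards, and configurable
  ground-truth effects on survival, mass, movement and burdens.

## Worked example

```python
from impairfit import scenario_config, simulate_population, build_histories
from impairfit.mass import adult_mass_table, fit_lmm_mass, percent_effect

cfg = scenario_config()                    # published effect sizes as truth
events, truth = simulate_population(cfg, seed=7)
rows = adult_mass_table(build_histories(events))
fit = fit_lmm_mass(rows)
print(fit.summary())
```

prints (seed 7):

```
n_obs=5045  loglike=-13068.618  AIC=26152.05
                       estimate  ci_low  ci_high         p
intercept                 23.02   22.13    23.91         0
category[tail]            1.456   1.056    1.856 9.422e-13
category[limb]          -0.1327 -0.8391   0.5737    0.7127
category[eye]             2.396   1.667    3.125 1.191e-10
...
random effects:
          variance     sd
tag          8.743  2.957
plot             0      0
year        0.7365 0.8582
residual     6.993  2.644
```

The simulated truth put the tail-impairment mass shift at +1.44 g; the
model recovers 1.46 g (CI 1.06–1.86), about 7% of mean adult mass via
`percent_effect`. The `tag` variance component recovers the simulated
individual SD of 2.97 g.

A command-line interface wraps the same pipeline:

```sh
impairfit simulate --seed 3 --out sim/
impairfit validate sim/captures.csv
impairfit mass --captures sim/captures.csv --out out/
impairfit run --config run.yaml
```

## Layout

```
src/impairfit/
  records.py    capture-table IO, histories, impairment classification
  simulate.py   individual-based trapping-grid simulator + truth ledger
  survival.py   persistence, risk-set matching, KM / log-rank / Cox
  mass.py       adult mass LMM, percent effects, conditional logistic
  movement.py   centre of activity, MSD, residency/edge, log-MSD LMM
  parasites.py  windows, season levels, logistic/NB/ZTNB, Vuong
  stats.py      AIC selection, change-in-estimate, descriptives
  lmm.py        crossed random-intercept REML/ML solver
  glmm.py       adaptive Gauss-Hermite mixed logistic / NB
  pipeline.py   end-to-end orchestration;  cli.py  command line
docs/methods.md the model and design notes
```
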