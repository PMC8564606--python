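# Methods and design notes

## The estimation problem

Impairment status in a trapping study is observed only when a mouse is
caught, so every contrast between impaired and unimpaired animals is a
contrast between *selected* subsets of the population. The package
implements four analyses — persistence (survival proxy), adult body
mass, seasonal home range, and ectoparasite burden — each built so that
the selection mechanisms are either matched away or carried as explicit
covariate levels, and each backed by a generative simulator in which the
true effects are known.

Throughout, the exposure is a four-level factor (none / tail / limb /
eye) classified once per individual: tail damage explained by a tissue
snip is not an impairment; when tail and limb-or-eye codes co-occur the
rarer limb/eye category wins (a limb-vs-eye tie goes to the earlier
observed code, and is logged); status is permanent from the first coded
capture, with later code-free captures logged but not honoured. Captures
of a later-impaired mouse before its onset carry `future_<type>` labels,
which the model stages collapse as needed: folded into `none` for the
primary four-level fits, pooled into one `future_impaired` level for the
five-level mass and movement fits, or kept split by type for the bot fly
models where pre-onset burden is itself the question.

## Time axis and seasons

Study time is (year, week 1–52); durations are whole weeks on an
absolute 52-week-per-year axis; the day within a 2–3-day session only
disambiguates repeat captures. Calendar months come from the ISO week
midpoint, and the season map follows the trapping window: May–June
spring, July–August summer, September–November fall. The burden season
is dichotomised on the calendar (August–September high); the burden-based
criteria this rests on (mean larval tick load above 10; more than 10% of
mice carrying a bot fly larva) are recomputed from the data as
diagnostics rather than used to define the levels, since on synthetic
data they are configuration-dependent.

## Survival: persistence, matching, and what the matching must beat

Persistence — weeks from first to last capture on the (modal) plot — is
the survival proxy; mice spanning ≤1 week are excluded as non-residents
and records reaching the plot's final session of the last study year are
right-censored. Simulation exposed two selection mechanisms any matched
analysis of this design must address:

1. **Length-biased case selection.** With a roughly constant per-week
   impairment hazard, the probability of ever being seen impaired is
   proportional to time alive, so cases are drawn from the long-lived
   tail. Pooled (unstratified) comparisons of cases against matched
   controls are badly biased (simulated null hazard ratios near 0.5).
2. **The detection guarantee.** A case is, by construction, captured at
   least once after its pre-impairment period — possibly only at the
   next session the following spring, an overwinter gap of ~24 weeks.

Both are removed by (a) setting each control's eligibility bar at the
case's *first impaired capture* (the index event of the matched set):
controls must share the case's age class and (year, week) of first
capture and persist at least to that index week; and (b) fitting the Cox
model *stratified by matched set* (Efron ties), so every comparison is
between animals that cleared the same bar. Under all-null simulation at
the study's ~2% impairment prevalence this design is calibrated (null
hazard-ratio intervals cover 1). Two residual caveats are documented
rather than fixed, because they are properties of the observational
design itself: unadjusted Kaplan–Meier curves still show impaired mice
persisting longer (the selection artifact, reproduced by the simulator);
and at high impairment prevalence the never-impaired control pool is
progressively depleted of long-lived animals (they become cases), which
is why the survival scenarios keep prevalence in the 2–6% range while
the mass/movement/parasite power scenarios may raise it.

## Mass

Adult captures with 11 g < mass ≤ 40 g (strict lower, inclusive upper
bound) enter `mass ~ impairment + sex*season (+ future level) +
(1|individual) + (1|plot) + (1|year)`, fit by REML; reference levels are
impairment absent, female, fall. Percent effects divide the coefficient
by a baseline mass (the unimpaired adult mean) and are rounded to whole
percent for reporting. Reverse causality is probed by a matched
case-control design: each later-impaired mouse's final unimpaired
capture is matched exactly on (sex, age class, year-week, plot) to
unimpaired captures, falling back to the adjacent prior/following week
on a different plot when the same week has no candidate anywhere (the
field design trapped one plot per week, so same-week candidates are
plot-bound); conditional logistic regression then estimates the odds of
becoming impaired per gram. Under the null generator the matched odds
ratio sits at 1.00.

## Movement

The centre of activity is the mean capture coordinate of a resident
(≥3 captures in one plot-year-season); MSD is the mean squared distance
of captures from it (m²), an area-scale home-range index with the
closed-form oracle E[MSD] = 2σ²(n−1)/n for circular-normal movement with
spread σ. Station snapping matters: recorded locations are 15 m grid
stations, which adds roughly spacing²/12 per axis to small spreads and
*attenuates* multiplicative movement effects estimated from station
data relative to the continuous truth (at the default σ = 11.3 m a true
log-MSD shift of 0.29 is estimable as ≈0.20–0.26). This is a faithful
property of trapping data, not a bug; the simulator-based tests verify
the quantised expectation by numerical integration, and effect-recovery
is asserted through CI coverage, which absorbs the attenuation at
desk-scale precision. Zero-MSD residents (all captures at one station)
get a fixed 1 m² offset inside the log and are counted in the fit
metadata rather than dropped. Centres within 15 m of the grid boundary
are flagged as edge cases and reported diagnostically, not modelled.
The sex × season interaction is chosen by smallest AIC between the
with/without fits (AIC always computed from the ML criterion).

## Count models

Infestation (any parasite vs none) uses a logistic mixed model; load
uses a negative binomial (NB2, Var = μ + μ²/k) mixed model; both have a
single individual-level random intercept integrated by adaptive
Gauss–Hermite quadrature (9 nodes by default; the mode is found by a
damped, vectorised, warm-started Newton iteration, so one node
reproduces a Laplace fit — verified against glmmTMB to four decimals —
and the likelihood is node-converged by nine). Plot and year enter as
fixed effects: their level counts are small (6 and 4), so absorbing them
costs a few degrees of freedom while keeping the quadrature
one-dimensional; the choice is recorded in the fit metadata. Wald
intervals come from the inverse numerical Hessian. Load among infested
mice uses a zero-truncated NB (maximum likelihood on P(Y=y)/(1−P(Y=0))),
and the plain NB is compared against its zero-inflated version with an
AIC-corrected Vuong statistic — the correction is required because the
zero-inflated model nests the plain one, so its uncorrected pointwise
likelihood can never be smaller.

Ticks are analysed April–October with configurable excluded years (the
earliest study years lacked reliable counts); only larval counts from
head and ears are used, as these track true load. The bot fly window per
year spans the first to last week with any infested capture; a year with
no infestation is excluded. Mass is a fixed covariate in the parasite
models only.

## The simulator

The generator reproduces the study design: six 150 m plots, 11 × 11
stations at 15 m, nine sessions per year at 3–4-week cadence
(May–November), three days each, ~85 new individuals per plot-year over
four years (~2000 individuals — a 26-year programme at desk scale), and
per-day capture probability 0.25, uniform across individuals. Lifetimes
are geometric at weekly survival 0.96 (tuned so the simulated mean
persistence matches the field regime of ~17 weeks); emigration and death
are indistinct, matching the persistence proxy. Entry is uniform over
the season; age classes progress juvenile → subadult → adult on fixed
schedules. Mass is Gaussian with the field baselines (female fall adult
22.76 g; male −0.81; spring +0.50 / summer −1.91 with the corresponding
sex interactions) and crossed random intercepts (individual 2.97, plot
0.13, year 0.84, residual 2.6 g). Burdens are NB with low-season means
3 (ticks, active April–October, dispersion 0.8) and 0.05 (bot flies,
active July–October, dispersion 0.5), high-season (Aug–Sep) rate ratios
5 and 5.47, and log-normal individual/plot/year intercepts (0.55, 0.22,
0.80). Impairment hazards default to ~2% cumulative prevalence
(tail:limb:eye = 4:1:1); onset effects apply to subsequent draws only.
A single seed is split into per-plot-year streams, so identical
(config, seed) yield byte-identical tables.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: spatial habitat heterogeneity and trap
response (capture probability is uniform by design), age- or
injury-dependent impairment hazards (constant hazard is the default;
the prevalence-with-age pattern seen in the field arises here only
through exposure time), movement heterogeneity between individuals
(log-MSD random intercepts are genuinely zero in simulated data, and the
model correctly reports them as such), density dependence, reproduction,
and the free-text coding process that produced the field impairment
records.

### Scenarios

`null_config()` is the study conditions with all effects zero.
`scenario_config()` raises impairment hazards ~7.5× (cohorts of ~2000
then contain a few hundred impaired mice, enough for stable fits) and
sets the published effects as truth: mass +1.44 g (tail) / +1.09 g
(eye), log-MSD +0.29 (tail), tick IRR 1.11 (tail), bot fly IRR 2.09
(eye), tail hazard ratio 0.88. `survival_scenario_config()` keeps
hazards near the field regime (see the pool-depletion caveat above) with
the 0.88 tail hazard ratio.

## Numerical choices

* **Crossed-random-intercept LMM**: the variance ratios are profiled out
  via the penalized-least-squares representation; one sparse LU
  factorisation per evaluation; L-BFGS-B over the square-root ratios
  with a zero lower bound (a boundary solution is reported as variance 0
  with a singular-fit warning). REML for reporting, ML refit for AIC.
  Validated against lme4 to ~1e-4 on deviance and coefficients.
* **Ties**: Efron throughout the Cox stage (weekly grids tie heavily).
  Efron is only approximately invariant to duplicating a dataset
  (clone ties), so that property is asserted at 5e-3, not exactly.
* **Conditional logistic**: Newton with tight tolerance (closed-form
  instances reproduce to 1e-10); separation is detected structurally
  (the case is the strict extreme of every informative set) as well as
  from the Hessian.
* **AIC ties** break toward fewer parameters; candidates must share rows.
* **Change-in-estimate** threshold 0.10 relative; a zero base
  coefficient falls back to absolute change.
* **Degenerate inputs**: empty coordinate sets, <3 captures, all-zero or
  one-class outcomes, zero marginals and zero-variance series raise
  informative errors rather than returning numbers.

## Test sizing

Replicate-based checks are sized for a desk run: effect-recovery suites
use 6–12 replicates at ~2000 individuals with CI-coverage thresholds set
from binomial tail bounds for nominal 95% coverage (e.g. ≥9/12, ≥6/8);
calibration suites use 200 replicates with the acceptance band
[0.02, 0.09] for a 5% test. The full pytest suite runs in a few minutes
on one CPU; the acceptance script in about two.

## Known limitations

Persistence conflates death, emigration and trap avoidance; the matched
survival design is calibrated under the generator's assumptions but
cannot remove biases it does not model (e.g. behaviour change after
injury affecting capture probability). The station-quantisation
attenuation of movement effects means log-MSD coefficients from gridded
data underestimate continuous movement shifts. The GLMM absorbs plot and
year as fixed effects, so their variance components are not reported for
count models. p-values are reported raw; no multiple-testing correction
is applied across the battery, and output headers say so.
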