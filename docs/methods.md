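# Methods

## Scope and data model

`rxits` analyses monthly counts of patients prescribed a drug class in a
registered population, comparing observed post-interruption prescribing
with the path projected from pre-interruption trends. Everything is
anchored to a `StudyCalendar`: a contiguous run of calendar months indexed
0..T−1, two interruption points splitting the window into
pre-interruption / restrictions / recovery segments, and a set of
designated outlier months inside the restrictions segment. The shipped
default is the 60-month pandemic design (January 2018 – December 2022,
interruptions March 2020 and March 2021, outliers March and April 2020).

Patient-level inputs are two tables. Registration records carry a patient
id, a half-open month interval `[reg_start, reg_end)` (open end allowed)
and 0/1 subgroup flags. Prescription events carry a patient id, a month
index and a drug class in {ssri, tricyclic, maoi, other}. Months before
the analysis window have negative indices; on disk both are ISO "YYYY-MM"
strings.

## Cohort aggregation

**Prevalent prescribing** in month t counts distinct registered patients
with at least one issue in t; duplicate issues within a month never
inflate the numerator. The denominator is the registered population
carrying the subgroup flag.

**New (incident) prescribing** additionally requires no issue in the 24
calendar months strictly before t (the washout, a whole-month reading of
"no prescription in the previous two years"). Its default denominator is
the drug-naive registered population — patients passing the same washout —
with the all-registered alternative behind a switch. Aggregation refuses
to run when registration records reach back less than 24 months before the
window, since the washout would be silently undecidable at month 0; depth
of registration history is the observable proxy for event-capture depth.

**Disclosure control** is a pure transformation applied only to published
outputs: counts of five or fewer (including zero; configurable to 1–5) are
redacted, remaining counts are rounded to the nearest ten with ties away
from zero (configurable to round-half-even). The transformation is
idempotent, and the series handed to the model is always the unredacted,
unrounded one. Secondary (next-smallest-cell) suppression is not
implemented; the intended workflow excludes incomplete strata instead.

**Drug-class assignment** per patient-month merges MAOIs into "other",
then labels the month by the single remaining class or "multiple" when two
or more distinct classes were issued.

## The segmented Poisson model

Counts y_t are Poisson with log-linear mean

    log mu_t = b0 + b1*t + b2*s1_t + b3*r1_t + b4*s2_t + b5*r2_t
               + g1*sin(2*pi*t/12) + g2*cos(2*pi*t/12)
               + sum_m d_m*1[t=m] + log N_t

with steps s_k = 1[t >= T_k], slope-change terms r_k = max(0, t − T_k + 1),
one Fourier pair at period 12 anchored at the window start (the number of
pairs is configurable), outlier dummies d_m, and the log registered
population as offset. The slope coding makes the slope term equal 1 in the
interruption month itself, so the step coefficient is the level shift at
that month; the off-by-one alternative (`slope_starts_at_one=False`) is
config-selectable. A squared-time column is available behind
`include_quadratic_trend` but off by default — exploratory fits did not
justify the extra curvature and the default mirrors the linear-trend
design. Coefficients are reported as (exp(b) − 1) × 100, the percentage
change in the monthly rate.

**Fitting** is iteratively reweighted least squares (Fisher scoring, which
is exact Newton for the canonical log link), initialised at the
intercept-only MLE. Convergence is declared when the score max-norm drops
below 1e-8 (typically 4–6 iterations); after 100 iterations a
`ConvergenceError` carrying the score-norm trace is raised. Rank
deficiency raises before iteration starts. Linear predictors are clipped
at ±500 only to keep a diverging iteration finite enough to report.

**Uncertainty** is the Newey-West HAC sandwich V = B M B with bread
B = (X' diag(mu) X)^-1 and Bartlett-weighted meat

    M = sum_t u_t u_t' + sum_{j=1..L} (1 − j/(L+1)) sum_t (u_t u_{t−j}' + u_{t−j} u_t')

over score contributions u_t = x_t (y_t − mu_t), lag L = 2 by default.
Lag 0 reduces exactly to HC0. No small-sample degrees-of-freedom
correction or t-quantile adjustment is applied; intervals use ±1.96
normal quantiles throughout. Consequence, measured in this package's own
calibration study (200 replicates of the 60-month design with ten
regressors, two of them leverage-one outlier dummies): the lag-2 HAC 95%
CIs cover the generating coefficients at roughly 0.77–0.85, against
0.94–0.96 for model-based Fisher intervals on the same fits, and the null
average-RR interval covers 1.00 at ~0.875. This is the known downward
finite-sample bias of kernel HAC estimators at T = 60 (score residuals sum
to zero at the MLE, shrinking empirical lag covariances), not an
implementation defect — the fit itself is calibrated. Users wanting
nominal coverage at this series length need longer windows or a different
interval construction; the package deliberately reports the plain
estimator.

## Counterfactual and effect summaries

The no-interruption counterfactual re-evaluates the fitted model with all
step, slope-change and outlier columns set to zero, keeping intercept,
trend and seasonality. Because fitted and counterfactual predictors share
those terms, log RR_t = c_t' beta where c_t is x_t with only the
interruption columns retained — exactly 0 (RR = 1) for every
pre-interruption month, asserted on every fit.

The **average RR** over a window is the geometric mean of the monthly
ratios, i.e. exp of the arithmetic mean of log RRs: a linear functional
exp(dbar' beta). Its CI is exact normal theory,
exp(dbar' beta ± 1.96 sqrt(dbar' V dbar)) — the natural normal-theory
construction for a geometric-mean ratio CI; no resampling is involved.
The default window runs from the first interruption to the study end
("post-restriction"); because the literature is ambiguous about whether
such averages start at the restrictions or the recovery onset, the window
is an explicit parameter everywhere. Outlier months contribute their
dummies to c_t and are included in the average by default
(`exclude_outliers` drops them). RRs are reported to 2 decimals, rate
differences to 1, matching field convention.

The **rate difference** at month t is (mu_t − mu_cf_t)/N_t × 1000 =
1000(exp(x_t'b) − exp(x_cf'b)), nonlinear in beta, with a delta-method CI
from its exact gradient; tests verify agreement within 10% of a 2000-draw
parametric bootstrap from N(beta, V).

**Subgroups** are fitted as fully separate models per flag (no
interactions), with per-subgroup failures collected and reported without
aborting the remaining fits.

## The synthetic cohort generator

The generator emulates the source data's shape, not any patient's data. A
registered population follows a linear path (default ~23.9k at window
start growing ~27.8/month at 1/1000 scale, the 1.0687 endpoint ratio of a
national TPP-practice cohort), extended backwards through a burn-in of at
least 24 months so the washout is decidable at month 0 (default 30).
Subgroup labels reproduce the registered-population composition of such a
cohort in late 2022: mutually exclusive families (sex, age band, IMD
quintile, region, ethnicity, diagnosis group) drawn multinomially, plain
flags (learning disability, autism, care home) drawn independently so a
patient can carry both learning disability and autism.

Prescribing follows a two-state Bernoulli chain, the simplest process that
makes prevalent and incident prescribing genuinely different outcomes: a
patient not prescribed in month t−1 initiates with probability

    q_t = baseline_rate * trend^t * exp(seasonality + interruption terms) * modifier

(the same segmented log-linear form the model assumes, with per-subgroup
multiplicative modifiers on initiation), while a currently prescribed
patient repeats with constant probability `repeat_persistence`. Patients
present at the burn-in start draw their initial state from the chain's
stationary distribution (they carry prescribing history predating data
capture); later registrants start unprescribed. Configurations implying
q_t ≥ 1 anywhere are rejected with the offending month named.

`truth_expected_rate` is the generator's closed-form oracle: the exact
forward recursion pi_t = r*pi_{t−1} + q_t*(1 − pi_{t−1}) from the
stationary start, marginalised exactly over the distinct subgroup-modifier
combinations. It is exact for a constant population; under growth the
realised rate runs slightly below it because late registrants take ~2
years to reach steady state.

Two presets encode the study conditions. `overall_prescribing` (initiation
0.0029, persistence 0.962, trend 1.0033) puts stationary prevalence near
71 per 1000 at the window start with incident prescribing near 3.3 per
1000 naive patients — the two printed anchors that jointly pin down the
persistence; its interruption effects are the observed overall-prescribing
estimates (−3.4% step, +0.3%/month; +2.3%, −0.5%/month).
`new_prescribing` (initiation 0.0033, trend 1.001) carries the incident
estimates (−24.8%, +1.5%/month; +9.1%, −2.2%/month). The acute-month
outlier magnitudes are not published; −0.05/−0.03 (overall) and
−0.10/−0.25 (incident, April deeper) on the log scale were chosen once as
plausible acute-dip sizes consistent with reported first-prescription
collapses of ~25–36% in spring 2020.

One dynamic consequence matters for interpretation: interruption effects
act on *initiation*, so the prevalent outcome responds to a step with a
relaxation time of roughly 1/(1 − r + q) ≈ 24 months rather than
instantaneously — a fitted prevalent-outcome step underestimates the
generating initiation step. The incident outcome has no such damping: the
new-prescribing rate per naive patient equals q_t in expectation, so
incident analyses recover the generating effects directly. Parameter
recovery and calibration studies therefore use `simulate_count_series`,
which draws Poisson counts straight from the segmented log-linear rate —
the model's own generating process, where coefficients are directly
comparable with truth.

What the generator does not emulate: prescription durations beyond one
month, dispensing vs prescribing, dosage, mortality and within-month
registration churn, non-stationary subgroup composition, and any real
autocorrelation structure beyond what the chain induces. Passing tests
therefore certify the pipeline's arithmetic and the model's behaviour
under its own assumptions, not the epidemiology of any real cohort.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from the
truth's `seed` (population and event generation use separate child
streams, so each is reproducible independently). Pipeline runs write a
manifest with the config hash and library versions; identical configs
produce byte-identical artifacts.

Problem sizes were chosen so the whole suite runs interactively: replicate
studies use 200 series-level simulations at a registered population of
2×10^5; patient-level end-to-end runs use 1/250 to 1/1000 of the national
cohort scale; the brute-force cohort oracles run on 200–500-patient
fixtures. `scripts/acceptance.py` completes in a few seconds.

## Known limitations

* HAC interval undercoverage at 60 months, quantified above.
* The outlier dummies each absorb one observation entirely, so their
  coefficients have leverage one and the March/April step interpretation
  depends on the chosen slope coding (documented above).
* Redaction of the *next*-smallest cell after a redaction (secondary
  suppression) is out of scope.
* The washout is month-resolved; day-level washouts cannot be expressed.
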