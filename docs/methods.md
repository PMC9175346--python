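# Methods

## The screening problem

Given longitudinal claims data — dispensing records, diagnoses, procedures,
demographics — the package screens *every* health event observed after a
patient's first dispensing of a drug of interest for association with the
drug's exposure history, with no expert preselection of candidate adverse
reactions. The cohort is case-only: every patient is a new user of the drug.
Two self-controlled analyses are run per candidate code and compared.

## Weighted cumulative exposure (WCE) model

For candidate event code *c*, the hazard of the first occurrence in
follow-up month *t* is

    h(t | X, C) = h0(t) · exp( Σ_{v=1..T} w(v) · x(t−v+1) + γ'C )

where `x(u) ∈ {0,1}` indicates at least one dispensing of the drug of
interest in follow-up month `u` (month 1 = index month), `w(v)` is the
log-hazard contribution of a dose taken `v` months earlier, `T` is the
exposure window, and `C` are baseline covariates (age at index, sex, a
binary disease-severity flag). `w` is a cubic regression spline:
`w(v) = Σ_k θ_k B_k(v)` with `m` interior knots equally spaced over
`[1, T]` (the B-spline dimension is `m+4`, or `m+2` when the weight is
constrained to vanish smoothly at lag `T`). Substituting the spline turns
the weighted history sum into `K` artificial pseudo-covariates

    Z_k(t) = Σ_{u ≤ t, t−u+1 ≤ T} B_k(t−u+1) · x(u),

so `(θ, γ)` is estimated by an ordinary time-dependent Cox partial
likelihood on a person-period table: one row per patient-month, intervals
`(t−1, t]` closed on the right, first `Start = 0` at the index month, the
event indicator allowed only on a patient's last row.

Summaries: the weight function `ŵ = Bθ̂` (per-lag hazard ratios
`exp(ŵ(v))`) and the **window hazard ratio** `exp(Σ_v ŵ(v))`, comparing
continuous exposure over the whole window with no exposure.

### Estimation

Newton–Raphson with step-halving from `θ = γ = 0`, convergence when the
score max-norm falls below 1e−8, at most 100 iterations. Ties are handled
with the Efron approximation by default (month granularity makes ties
heavy); Breslow is available. A fit whose coefficients run beyond ±30 is
flagged non-converged (monotone likelihood / separation) and its code is
excluded downstream with a logged reason. When all intervals are unit
months — always true for tables this package builds — risk sets at distinct
event times are disjoint, and the score and observed information reduce to
grouped sums evaluated with bincounts and two weighted Gram products; an
interval-generic path covers other data. The implementation is validated
against an independent Cox implementation (lifelines'
`CoxTimeVaryingFitter`) in the test suite, to 1e−6 relative agreement and
better.

Codes with fewer than 10 events (configurable) are reported as
"not evaluated" rather than fitted.

### Design choices where the design was open

- **Time zero** is the index month (first dispensing), because the exposure
  window is anchored to drug introduction.
- **Lag convention** `v = t−u+1`: a dose in the current month acts through
  `w(1)`.
- **Incident events only**: a patient whose first occurrence of a code is at
  or before the index month is excluded for that code — month resolution
  cannot order within-month occurrences, and initiation is the event of
  interest.
- **New-user rule**: the first in-study dispensing must have 12 fully
  observed months of history with no dispensing; patients whose lookback
  window extends before the data start are excluded (avoids immortal-time
  misclassification at the data boundary).
- **Censoring**: earliest of death month, end of study, and the last month
  with any claims record for the patient.
- **Knot placement**: equally spaced interior knots; the default window/knot
  configuration is T = 24, m = 1.
- **Age** enters fixed at its index-month value.

## Bootstrap association test

The WCE model was built to estimate a known risk function, not to test
association, so the screen tests each code with a nonparametric
patient-level bootstrap: patients are resampled with replacement (all of a
patient's rows move together), the model is refitted per replicate
(warm-started at the original optimum, which cannot change the optimum),
and the log window HR `Σ_v ŵ(v)` is collected. With `B` replicates and
level `α` (defaults 1,000 and 0.05):

- **Percentile CI**: the 1-based order statistics at ranks
  `j = ⌊α/2 · B⌋` (clamped to ≥ 1) and `k = ⌊(1−α/2) · B⌋`.
- **p-value**: the paper trail for this pipeline names p-values without
  defining them; here `p = 2·min(#{r ≤ 0}, #{r ≥ 0})/B`, clipped to
  `[1/B, 1]`, which is coherent with the CI decision up to rank rounding.
- **Failures**: non-converged replicates are excluded and counted; if more
  than 20% fail, the code is flagged unreliable and reported
  "not evaluated" (silently imputing failed tails would bias the interval).
- A code is **significant** when the CI for the log window HR excludes 0.
  No multiple-testing correction is applied by default (the screen is
  exploratory); Benjamini–Hochberg adjusted p-values are available.

Per-code seeds are derived deterministically from the master seed and the
code string, so results are identical regardless of screening order.

## Case-crossover comparator

For each case, exposure in the risk period `(e−L, e]` (the `L` months up to
and including the event month) is compared with three control periods of
the same length, each separated by a 1-month washout:
`(e−2L−1, e−L−1]`, `(e−3L−2, e−2L−2]`, `(e−4L−3, e−3L−3]`. Month ranges are
half-open (lower open, upper closed) to mirror the person-period
convention. The layout needs `4L+3` observed months before the event; cases
without them are excluded and counted. Periods earlier than the index are
legitimate unexposed time. The odds ratio is conditional-logistic maximum
likelihood on the 1:3 matched sets (scalar Newton on the closed-form
binary-exposure likelihood), with Wald confidence intervals; concordant
sets are uninformative, and complete separation (all informative cases
exposed, or none) is reported non-estimable. Period length is varied over
3/6/9 months as a sensitivity analysis.

## Synthetic claims generator

Real claims for this kind of study are access-restricted, so the generator
emulates the structure the pipeline assumes, with known ground truth:

- **Cohort**: every patient initiates the drug in-study (case-only), at a
  month ≥ 12 so the lookback year is fully observed; initiation is a
  truncated geometric with per-month probability 0.02 by default.
- **Exposure**: monthly two-state Markov chain — persistence 0.9/month
  after initiation (mean episode ≈ 10 months, matching the ~9.5-month mean
  exposure of the motivating cohort), re-initiation 0 by default (one
  episode). Positive re-initiation produces the intermittent dispensing
  patterns needed to identify a full lag-weight function in recovery
  experiments.
- **Covariates**: age ~ N(54.8, 16.2) clipped to [18, 95], P(female) = 0.78,
  P(severe) = 0.35, matching the motivating cohort's descriptives. Severity
  shifts the monthly persistence log-odds (+1.5 by default), so severe
  patients accumulate more exposure — exactly the confounding structure the
  severity covariate is meant to absorb. Severe patients carry a
  certification record dated before the index.
- **Events**: discrete-time hazard with complementary log-log link,
  `p(t) = 1 − exp(−λ0 · m_c · exp(Σ_v w_c(v)x(t−v+1) + γ_c'C))`, first
  event only; baseline λ0 = 0.01/month. This makes the fitted Cox model
  correctly specified, so parameter recovery is a clean end-to-end check.
- **Routine contacts**: each patient emits visit records at mean 3-month
  gaps from index to end of study. Real claims are dense with such
  contacts; without them "last record" censoring would be informative
  (non-event patients' last record would be their last dispensing).
- **Truth catalog** (defaults): one acute code (exponentially decaying
  weight, total HR 3), one delayed/cumulative code (weight rising with lag,
  total HR 2.5), one severity-confounded null (zero weight, severity
  log-HR 0.8), and 20 pure nulls across the three code systems.
- Calendar dates are month offsets from a fixed origin (2008-01);
  identical config + seed reproduces byte-identical tables.

### What the generator does not emulate

No real coding dialects, reimbursement amounts, dosing strengths, pharmacy
stockpiling, inter-scheme transfers, or recurrent (non-first) events.
Passing recovery and calibration tests therefore shows the pipeline is
correct under its own assumptions (binary monthly dose, correctly specified
hazard, non-informative censoring), not that those assumptions hold in any
particular real database.

## Simulation study sizes

Chosen once as the package's standing verification experiments:

- **Weight recovery**: 2,000 patients, T = 12, exponential-decay truth with
  total HR 3, intermittent exposure (persistence 0.5, re-initiation 0.5),
  baseline 0.02, 48 study months, right-constrained basis (the truth decays
  to ~0 at lag T), 10 seeded repeats. Intermittent exposure is what makes
  all lags of the weight function identifiable; with single-episode
  exposure the late-lag weights are ill-determined at this sample size.
  Performance is summarized across repeats (mean correlation, geometric
  mean window HR): a single repeat's window HR has Monte-Carlo standard
  deviation ≈ 0.2 on the log scale at ~900 events.
- **Null calibration**: 200 independent null codes on one 500-patient
  cohort, 36 study months, initiation 0.3 (≈ 100 events per code — enough
  that resample separation is rare and the test actually runs), B = 200.
- **Denoising**: severity-confounded null (severity event log-HR 1.0,
  persistence shift +2.5), 400 patients, 48 study months, B = 100, 100
  repeats, screened with and without the severity covariate.

### Comparator caveat

The case-crossover design assumes exposure is intermittent with no
systematic within-person time trend. A new-user cohort with single-episode
exposure violates this: exposure probability declines monotonically from
the index, so for events occurring soon after initiation the risk period is
systematically more exposed than the earlier control periods, and the
comparator is biased away from the null even for truly null codes
(simulations in the test suite measure OR ≈ 1.4 at L = 3 in that regime).
The self-control property — immunity to time-invariant confounders such as
disease severity — holds once exposure is stationary over the compared
periods. This is a property of the design, not of the implementation, and
is one reason the WCE and case-crossover arms select different codes.

## Known limitations

- Binary monthly dose only; no continuous dose-intensity.
- Death is treated as censoring, not a competing risk.
- The bootstrap refits can fail on very sparse codes; such codes are
  surfaced as "not evaluated" rather than silently dropped.
- No knot-selection loop: the window and knot count are fixed per screen.
- The case-crossover arm requires full observability of all four periods;
  truncated control periods are not used.
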