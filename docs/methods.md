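# Methods

This note records the scientific and numerical choices behind the
package, what the synthetic data do and do not emulate, and the known
limitations.

## Model

All equations are parametric Weibull proportional-hazards models,

    h(t | x) = exp(LP(x, t)) · p · t^(p−1),
    H(t0, t1 | x) = ∫ h(t | x) dt,
    risk(t0, t1 | x) = 1 − exp(−H(t0, t1 | x)),

with one equation per (event type, order) pair — AMI, HF, stroke and
NAIHD, each for the first event after type 2 diabetes diagnosis and for
the second event of the same type.  Recurrence is handled in the
Prentice–Williams–Peterson gap-time form: event order defines strata
with separate baseline hazards (separate equations), and second-event
equations run on the time since the first event of that type, starting
at zero.  First-event equations run on time since diagnosis, with
delayed entry at the patient's current diabetes duration.

The linear predictor combines:

- a constant (the log relative hazard at the centering point);
- per-unit coefficients on mean-centred continuous covariates and on
  0/1 indicators (sex, smoking, albuminuria grade, pre-diagnosis event
  history, and time-varying "event X occurred after diagnosis" flags);
- linear splines `min(x, k)` / `max(x − k, 0)` for covariates with a
  documented non-linearity (HbA1c and systolic BP for first HF, HbA1c
  for first stroke, diastolic BP for first NAIHD).  Spline pieces enter
  **uncentred**: the source describes mean-centring for *linear*
  continuous covariates only, and uncentred pieces are the only reading
  under which the constants reproduce the published event rates (with
  centred pieces the implied first-HF rate at covariate means would be
  ~40× the observed incidence);
- covariate×covariate interactions (female×LDL for second AMI,
  female×macroalbuminuria for second NAIHD), built from centred values;
- covariate×time interactions, either continuous products (e.g.
  female×time-since-diagnosis in first HF) or step indicators (e.g. the
  large drop in second-HF baseline hazard after gap year 1).

### Centering constants

Absolute risks depend on the centering constants of the original
estimation sample.  The AMI constants are recoverable from the published
worked example and ship in the default config.  The remaining constants
were published only in supplementary material not redistributed here;
they ship as explicit nulls, and evaluating an absolute risk without
them raises a configuration error instead of silently assuming zero
(hazard ratios and all shape-driven properties are
centering-independent and always work).  `centering_from_cohort` fills
missing constants with a user-supplied cohort's means, which is the
documented prerequisite for absolute-risk work with the non-AMI
equations; results then depend on that cohort choice.

### Numerical evaluation

- With no time interactions, `H` has the closed form
  `exp(LP)·(t1^p − t0^p)`.  Step-form time terms make `LP` piecewise
  constant in time; the interval is split at thresholds and each panel
  uses the closed form (hazard additivity then holds to ~1e−12).
- Continuous covariate-by-time products leave no elementary
  antiderivative (`exp(γt)·t^(p−1)`).  These integrals use adaptive
  quadrature after the substitution `u = t^p`, which removes the
  `t^(p−1)` singularity at zero for `p < 1`; tolerances are 1e−9
  absolute / 1e−10 relative, and tests check agreement with independent
  quadrature of the hazard to 1e−6 relative.
- Event-time inversion (`H(t0, t) = target`) is closed-form per panel in
  the piecewise case and Brent root-finding (tolerance 1e−12) in the
  quadrature case.
- Hazard ratios for plain terms are `exp(coef·Δ)`.  For
  interaction-bearing covariates the log-ratio is assembled
  structurally; the only centering constant that enters is that of the
  *partner* covariate in an interaction, which is why the second-AMI
  female ratio is reported "at centred LDL".

## Synthetic cohort generator

The generator reproduces the published baseline table of the register
training sample: per-sex means/SDs for age at diagnosis, diabetes
duration, HbA1c, BMI, systolic/diastolic BP, TC/HDL and LDL; per-sex
prevalences of smoking; and albuminuria drawn as a single three-level
categorical (none/micro/macro), so the two indicators are mutually
exclusive by construction.

Continuous covariates are **moment-matched truncated normals**: the
underlying normal parameters are solved (per covariate and sex) so that
the distribution truncated to physiologic bounds has exactly the target
mean and SD.  Naive truncation would, e.g., inflate the mean diabetes
duration by ~1.5 years because the target mean sits only 1.2 SD above
the lower bound.  An optional Gaussian copula imposes user-supplied
correlations; the default is independence because only marginals were
published.  Pre-diagnosis event-history prevalences default to zero
(not published) and are configurable.

What the generator does *not* emulate: covariate correlations of the
real register, skewness (duration is right-skewed in reality),
registry missingness and its last-observation-carried-forward
imputation, secular treatment trends, or mortality.  Tests that pass on
these cohorts therefore demonstrate internal consistency of engine,
simulator, estimator and validator — not transportability to register
data.

Annual covariate updates support random-walk and AR(1) drift per
covariate, clipped to physiologic bounds; sex, age at diagnosis,
baseline duration and pre-diagnosis history are immutable.

## Microsimulator

Each patient runs four parallel first-event processes (one per event
type) plus, after a first event of type X, a gap-time second-event
process for X.  Processes interact only through the time-varying
history indicators, mirroring the estimation structure: when a first HF
occurs, `hf_since_diagnosis` flips to 1 in the AMI and stroke equations
from that instant onward.  Whether patients remain at risk of other
first events after a first event of one type was left open in the
source; this implementation keeps them at risk (the source recorded
other events occurring before "the first event in question", which
implies continued observation).

Event times are sampled exactly: each process draws one Exp(1)
threshold, cumulative hazard is accrued over segments (year boundaries,
other events, censoring), and the crossing time is inverted in closed
form or by Brent.  This avoids discretisation bias entirely while
honouring annual covariate updates; simulated incidence matches the
analytic interval risk to Monte Carlo error by construction, which the
tests verify at n = 100,000.  Administrative censoring occurs at the
horizon; optional exponential dropout can shorten follow-up.

Counting-process exports use half-open `[entry, exit)` intervals in
years, split at year boundaries and covariate changes, the event flag on
the terminal interval only, 6-decimal formatting.

## Estimation

The log-likelihood is the standard parametric counting-process form:
an interval `[t0, t1)` with covariates `x` contributes
`δ·[log p + (p−1)·log t1 + x'β] − exp(x'β)·(t1^p − t0^p)`, which handles
left truncation (entry > 0), right censoring, and annually-updated
covariates in one expression.  The shape is parameterised as `log p`
for unconstrained optimisation.  BFGS with the analytic score runs
first; because BFGS stalls around score norms of ~1e−4 on large
datasets, a few Newton steps with the observed information polish the
optimum below the 1e−6 tolerance.  The intercept starts at the
exponential-rate MLE so the first quasi-Newton step stays in a sane
region.  Standard errors come from the inverse observed information
(central-difference Hessian of the analytic score); the shape SE uses
the delta method from the log scale.  Rank deficiency is detected up
front and reported with the collinear column names.

Supported model structures: linear terms, splines, covariate
interactions, and step-form time terms (data intervals must not
straddle a threshold; the annual splits produced by the simulator never
do).  Continuous covariate-by-time products are not estimable with this
closed-form likelihood and are rejected explicitly — the risk engine
evaluates such equations, but refitting them would require per-interval
quadrature inside the objective, which no acceptance path needs.

Backward elimination by likelihood-ratio tests (5% level) is available
as an optional utility, off by default; trial fits that fail to
converge are skipped rather than compared.

## Validation

- **Harrell's C**: pairs are comparable when the subject with the
  shorter follow-up had an event (tied times comparable when exactly
  one member had an event); score ties count ½.  Computed in row blocks
  so memory stays O(block·n).  Comparison times should be *time on
  study* (exit − entry) when entries are heterogeneous; using the
  absolute since-diagnosis scale degrades discrimination because early
  entrants are compared with late entrants at incomparable risk sets.
  The CI uses a leave-one-out jackknife of the pair-sum ratio (a
  Noether-type U-statistic variance); the method is recorded in the
  report because the source does not state one.
- **Expected events** follow the Gronnesby–Borgan identity: observed
  minus martingale residual equals the model cumulative hazard over the
  subject's at-risk intervals, so expected counts are simple sums of
  per-interval `ΔH` and are invariant to interval splitting.
- **Modified Hosmer–Lemeshow**: subjects are grouped into ten
  near-equal groups by predicted risk score (stable sort, so score ties
  break by input order); `X² = Σ (O_g − E_g)²/E_g`; groups with zero
  expected events merge upward.  Degrees of freedom are a convention,
  reported with the result: `g − 2` (default, the D'Agostino choice for
  a model fitted to the evaluated data), `g − 1` (conservative), or `g`
  ("external") for a model specified independently of the evaluated
  data.  The external convention is the calibrated one under a known
  true model — each group's `(O−E)²/E` then contributes ≈1 degree of
  freedom, and simulations in the test suite confirm ~5% rejection at
  α = 0.05, whereas `g − 2` would reject ~11% in that setting.

## Problem sizes used in the test suite

Marginal-recovery checks run at n = 100,000 cohort draws;
engine–simulator consistency at 100,000 simulated patients;
parameter-recovery coverage over 200 replicates of 20,000 patients
(~1,500 events each); HL type-I error over 500 replicates of a fixed
4,000-patient design.  These sizes give Monte Carlo error comfortably
inside the asserted 4-SE/2.5-pp bands while keeping the whole suite in
a few minutes.

## Known limitations

- Absolute risks for non-AMI equations depend on user-supplied
  centering constants (see above); shipped defaults refuse to guess.
- The simulator treats the four first-event processes as conditionally
  independent given covariates and history flags — no shared frailty,
  no fatal-event absorption (mortality is out of scope; the source
  censored at withdrawal).
- Covariates are piecewise-constant within years; the engine's "annual
  values" convention is inherited from the source.
- The estimation module's spline centering and the engine's uncentred
  spline convention must match when round-tripping fitted equations;
  `ModelSpec.from_equation`/`FitResult.to_equation` preserve this
  automatically.
- Second-event validation uses each process's own gap-time scale for
  pair comparability; whether the original analysis did the same is
  not stated.
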