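# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort model with a 1-year cycle and six
mutually exclusive health states: *no CVD*, *post-stroke*, *post-CHD*,
*post-heart-failure*, *post-cancer-recurrence* and *dead* (absorbing). The
cohort — women who completed curative-intent treatment for early-stage
endometrial cancer — starts 100% in *no CVD* at the rounded mean cohort age
(64). Key structural assumptions:

- **Mutually exclusive chronic states.** A woman who has had a first CVD
  event or a recurrence stays in that state until death; post-event states
  carry no further recurrence or CVD risk. This mirrors the state diagram
  the model is built around and keeps the six states exhaustive.
- **Competing risks, simultaneous.** Within a cycle the exits from *no CVD*
  (first CVD event, recurrence, background death) act as independent
  constant rates: each annual probability is moved to the rate scale
  (r = −ln(1−p)), rates add, the total exit probability is 1 − e^(−R), and
  exits are allocated proportionally to rates. This is order-independent, in
  contrast to sequential tree orderings.
- **Constant hazard for multi-year inputs.** Cumulative probabilities over
  a 14-year follow-up (first CVD event 0.158; recurrence 0.240) and 5-year
  survival fractions (post-stroke 0.731, post-CHD 0.859, post-heart-failure
  0.705, post-recurrence 0.625) are annualized under an exponential
  assumption: p₁ = 1 − (1−p_T)^(1/T) and q = 1 − S^(1/5). The printed
  inputs support no richer time structure.
- **Exercise effect.** Hazard ratios (CVD 0.77, recurrence 0.33) multiply
  the corresponding rates — equivalently p → 1 − (1−p)^HR — and are assumed
  sustained over the whole horizon, reflecting the program's
  self-efficacy intention. Standard care has both HRs at 1.
- **Case fatality.** A fixed fraction of each first event is fatal within
  the cycle (stroke 0.478; CHD and heart failure 0.424); survivors enter the
  post-event state.
- **Background mortality** applies in every alive state, combined with
  disease-specific mortality multiplicatively on the survival scale.

## Rewards, discounting, half-cycle correction

State rewards per cycle: the age-specific baseline utility in *no CVD*;
absolute published utilities in the post-event states (0.651 / 0.720 /
0.789); baseline minus the 0.112 recurrence disutility (floored at 0) in
*post-recurrence*. Annual costs: cancer surveillance ($1,601) in every alive
non-recurrence state, post-event follow-up on top ($5,662 / $3,348 /
$4,101), and recurrence follow-up care ($4,880, replacing surveillance).
One-time rewards attach to transition flows, so they are paid exactly once
on entry: acute treatment costs ($12,215 / $10,177 / $10,270), recurrence
treatment ($13,126) and event disutilities (0.075 / 0.15 / 0.07). The flow
*no CVD → dead* carries the cause-weighted expected acute cost of fatal
events (background deaths in that flow cost nothing); a flat override is
exposed for users with an external fatal-event cost estimate. The exercise
program cost ($1,381; plus $2,700 = 36 × $75 in the extended-supervision
scenario) is a first-cycle state cost in *no CVD*.

Discounting is cycle-end at 5%/year: cycle *t* outcomes are multiplied by
1.05^(−t). Half-cycle correction is the within-cycle trapezoid: cycle *t*'s
state rewards are weighted by the mean of the start- and end-of-cycle
occupancy. At a zero discount rate this reduces exactly to the classic
half-weighting of the first and final trace rows; for a cohort with no
deaths and utility 1 it yields the 5-year annuity value 4.3295 discounted
QALYs. Transition rewards are instantaneous and never half-weighted. The
correction applies to costs and QALYs alike.

## Parameter calibration

Each published row (mean, 95% CI, family) becomes a samplable distribution:

| family | rule |
|---|---|
| normal | sd = (hi − lo) / (2·1.96) |
| lognormal | log-sd = (ln hi − ln lo) / (2·1.96); log-mean = ln(mean) − log-sd²/2 so the arithmetic mean is exact |
| beta | α = m·ν, β = (1−m)·ν; ν found by least squares on the 2.5/97.5% quantiles vs the CI |
| gamma | shape k, scale mean/k; k found the same way |
| dirichlet | concentration αᵢ = meanᵢ · N_eff, N_eff = 100 (configurable) |

The exact-mean constraint preserves the deterministic base case; the
quantile fit approximates the stated uncertainty (verified in tests: every
calibrated 95% interval endpoint lies within 10% of the published interval
width). The lognormal log-mean carries the −σ²/2 correction because with
wide intervals (the recurrence HR has σ ≈ 0.34) the naive ln(mean) would
inflate the arithmetic mean by ~6%. N_eff = 100 encodes moderate uncertainty
for the stroke/CHD/heart-failure shares, which are published as bare means
from a single cohort. Sampled probabilities are clipped to [0,1] and costs
and disutilities to [0,∞) against heavy-tail draws; the sampled cohort age
is rounded to an integer for table lookups (and, in vectorized PSA, clipped
to the age range the tables cover).

## Synthetic age-indexed inputs

Two inputs are published only as citations, not numbers, and are generated
as synthetic stand-ins (clearly swappable via the `age,value` CSV slots):

- **Life table**: Gompertz–Makeham, qₓ = 1 − exp(−(a + b·cˣ)) with a = 2e−4,
  b = 1.2e−5, c = 1.105, closed at age 110. This gives q₆₄ ≈ 0.007,
  q₈₅ ≈ 0.057 and a period life expectancy at 64 of ≈ 23.3 years —
  consistent with a contemporary high-income-country female table.
- **Baseline utility**: u(age) = clamp(0.81 − 0.03·(age−60)/10, 0, 1), the
  magnitude and slope of published population EQ-5D-3L norms for older
  women.

What the stand-ins do *not* capture: the exact level and curvature of the
real national tables. Background mortality and the utility level mostly
cancel in the increments (both arms share them), so tests that pass on the
stand-ins validate the machinery and the direction and rough scale of the
results, not exact reproduction of the originally published numbers. The
deterministic increments on the stand-ins (ΔC ≈ $141, ΔQ ≈ 0.033,
ICER ≈ $4,300/QALY) are smaller than the originally reported ΔC = $358,
ΔQ = 0.0789, ICER = $5,184, though the cost-effectiveness conclusion is
unchanged. The residual gap traces mainly to annualization conventions for
the 5-year survival inputs rather than to the stand-in tables: applying the
5-year post-recurrence survival directly as an annual probability — a
shortcut some decision-tree implementations use — approximately reproduces
the published increments, but this package deliberately keeps the
constant-hazard conversion as the defensible reading of the inputs.

## Analyses

- **Base case**: both arms at the published means; ΔC, ΔQ, ICER, iNMB.
- **PSA**: 10,000 iterations by default; one joint draw per iteration drives
  both arms (common random parameters), vectorized through the engine.
  Summary ICER is the ratio of mean increments; the deterministic base-case
  ICER is reported alongside (a mean of per-iteration ratios is unstable
  when ΔQ crosses zero). Percentile (2.5/97.5) intervals accompany all
  summaries; the ICER interval is over per-iteration ratios restricted to
  ΔQ > 0 and is a descriptive net-benefit-plane summary.
- **CEAC**: fraction of iterations with λ·ΔQᵢ − ΔCᵢ > 0 over λ = 0 to
  100,000 in steps of 1,000.
- **Tornado**: each parameter with a published CI set to its bounds, one at
  a time (the only published ranges are the 95% CIs); bars sorted by ICER
  swing. Parameters without CIs (dirichlet shares, table inputs) are skipped
  with a logged notice.
- **Horizon sweep**: base case re-run for 1–10-year horizons; reports the
  first horizon with ICER < λ and the first with dominance (ΔC < 0, ΔQ > 0).
- **Extended supervision**: +$2,700 first-cycle cost, all else unchanged.

## Numerical choices and degenerate inputs

- Transition-matrix rows are renormalized to sum to 1 (closing
  machine-epsilon leakage); any negative computed probability raises an
  error naming the cell. Validation enforces row-stochasticity and an
  absorbing death row.
- p = 1 in probability→rate conversion raises (infinite rate); survival 0
  returns annual death probability 1 with a warning; hazard ratios must be
  positive.
- Beta/gamma calibration searches the log of the free parameter over a
  bounded interval with scipy's bounded scalar minimizer; non-convergence
  raises a calibration error naming the row.
- Ties in the tornado sort are stable (input order); the CEAC grid and the
  WTP threshold are plain floats, no interpolation.
- Problem sizes used in the shipped checks — 10,000 PSA iterations, 100,000
  calibration-recovery samples, a 100,000-individual microsimulation oracle
  on a three-state toy — were chosen to make Monte Carlo error negligible
  relative to the tolerances tested (a few seconds of compute in total).

## Known limitations

- No CVD risk after recurrence and no recurrence after CVD (structural).
- Single annualized surveillance cost rather than the 6-monthly-then-annual
  schedule; one recurrence treatment mix.
- The fatal-event acute cost defaults to the event's treatment cost; the
  original used an unpublished emergency-services figure.
- Constant hazards within and across cycles; no parametric survival fitting.
- Synthetic stand-ins for the life table and age-utility norms (see above);
  exact reproduction of the published numbers additionally depends on
  unpublished implementation conventions of the original software, notably
  the annualization of 5-year survival inputs.
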