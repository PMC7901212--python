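# Methods

## The measurement problem

ED crowding is operationalized here as perceived staff workload: a
timepoint is *crowded* when the mean staff rating on a 1–6 Likert scale
(1 = no workload, 6 = very high) is **4.5 or higher**. The package
computes, from a timestamped visit log, indices intended to predict that
state, and provides the machinery to derive such indices (regression on
mean ratings) and to validate them (discrimination against the
dichotomized outcome).

Two threshold conventions coexist deliberately: the workload outcome is
*inclusive* at 4.5 (mean rating ≥ 4.5 is crowded) while the mSEAL
score's own crowding flag is *strict* (score > 4.5, the top quartile of
the scale). Both follow their instrument definitions; the constants are
asserted equal once in `instruments.yaml`.

## Census metrics

All indices are built from per-timepoint metrics over the visit log:

* Presence intervals are **half-open** `[arrival, departure)`: a patient
  departing exactly at the query time is not present. This avoids double
  counting at boundaries; the convention matters only on exact minute
  ties and is fixed here because event logs are minute-resolution.
* Timestamps are timezone-naive local clock times at minute resolution,
  matching EHR exports.
* A missing departure means the patient was still in the ED at the end
  of the log; such visits contribute to the census up to the end of the
  observation window (right-censoring must not silently shed load).
* **Patient hours** with window *w* equals the integral of the census
  over `[t−w, t)` (default w = 1 h). The raw value (hours) is always
  reported; the model input is the normalized form
  `raw / (treatment_beds × w)`. Normalization is adopted because the
  printed mSEAL coefficient (9.72) with a 1–6 score range is only
  dimensionally coherent if the predictor lives on a ~[0, 1.5] scale; at
  a 40-bed ED raw trailing-hour patient-hours are an order of magnitude
  larger. The convention is configurable and the raw value travels
  alongside in every panel.
* **Time to MD** aggregates per-patient waits (registration to first
  physician contact, hours) over patients present at *t* plus patients
  whose contact occurred in the trailing window. Present-but-unseen
  patients contribute the censored elapsed wait `t − arrival`, so the
  metric cannot improve while waits worsen; departed patients with no
  recorded contact are excluded (their wait is undefined, not zero). The
  metric is 0 for an empty contributing set.
* **High-acuity fraction** is the share of present patients at triage
  levels 1–2 of 5; 0 when the ED is empty.
* NEDOCS/sICMED inputs: waiting count (present, no contact yet),
  boarding count (present with an admission requested), and the longest
  admit and waiting-room waits in hours (0 when the group is empty).

## Scores

* **mSEAL** `= 1.49 + 9.72·PH + 0.18·TTMD`, clamped into [1, 6].
  Clamping (not rescaling) enforces the published range: the linear form
  exceeds 6 under extreme load and no saturation rule is published.
* **Occupancy Rate** `= census / treatment_beds`, not clamped.
* **Modified NEDOCS**: the published linear instrument
  (−20 + 85.8·occupancy + 600·boarders/hospital beds + 0.93·longest
  admit wait [h] + 5.64·longest waiting-room wait [h]), with the
  occupied-ventilator/trauma-bay term omitted, floored at 0. The
  coefficients are external instrument constants transcribed into
  `instruments.yaml`; they are versioned and swappable without touching
  logic.
* **Modified sICMED**: a count of satisfied binary criteria. The five
  default items (occupancy ≥ 1; a boarder waiting ≥ 2 h; someone
  waiting ≥ 1 h to be seen; unseen patients ≥ 20% of beds; mean time to
  MD ≥ 1 h) are documented, configurable defaults expressed over the
  metric vector — the instrument's published cutoffs are not reproduced
  here — with the left-without-being-seen and ambulance-offload items
  excluded. The score is discrete by construction (values 0–5).

## Derivation

`stepwise_backward` fits OLS of mean rating on candidate metrics and
repeatedly removes the single term with the largest two-sided p-value
while any p ≥ α (default α = 0.05, the conventional two-tailed
significance level), refitting after each removal. Ties on p are broken
by smaller |standardized coefficient|, then lexicographically, making
the procedure deterministic and column-order invariant. If everything is
eliminated, the intercept-only fit is returned and flagged. The outcome
is the unweighted mean rating across all raters at a timepoint — no
rater-role weighting and no adjustment for clustered raters or repeated
timepoints, a known simplification mirroring how such instruments are
usually derived. Derivation pools sites by default; per-site fits are
available by flag.

## Validation

ROC curves place a threshold at every distinct score value; AUC is the
trapezoidal area and equals the tie-corrected Mann–Whitney U statistic
divided by `n_pos·n_neg` (ties contribute ½). Confidence intervals use a
**stratified percentile bootstrap** (positives and negatives resampled
separately, so every replicate retains both classes; default B = 2000,
seed mandatory); the reported interval is widened, if necessary, to
bracket the point estimate. The operating cutoff maximizes the Youden
index J = sensitivity + specificity − 1, ties broken toward higher
specificity and then the higher cutoff. Timepoints missing either the
score or any rating are dropped listwise and counted in the report.

No analytic (DeLong) CI, partial AUC or calibration analysis is
implemented.

## The synthetic ED

The generator emulates a multi-site validation study:

* **Arrivals** — nonhomogeneous Poisson with piecewise-constant hourly
  intensity on a diurnal curve (mid-day peak, shallow overnight trough).
* **Stays** — lognormal, disposition-specific means (admitted 5 h,
  discharged 3 h, other 2 h), log-sd 0.45, capped at 12 h: ED stays are
  administratively bounded, and an uncapped lognormal tail produces
  census pileups far outside anything the 1–6 rating instrument can
  express.
* **Physician delay** — `0.4 h × (1 + 6 × occupancy-at-arrival)`,
  deterministic given occupancy: waits of ~25 min at an empty ED rising
  to ~2.5 h when full, so the premise that waits track crowding holds by
  construction.
* **Admissions** — 25% of visits, with the inpatient-bed request placed
  60% of the way through the stay (drives the boarding metrics).
* **Ratings** — latent workload `a0 + a1·PH + a2·TTMD` computed from the
  simulated log with the same census machinery used for scoring
  (defaults: the mSEAL coefficients); each rater reports latent +
  N(0, 0.5²), rounded and clipped to {1..6}. Seven raters per timepoint
  (2 doctors, 3 nurses, 2 enrolled nurses). Whole-timepoint missingness
  is configurable, optionally higher under high load (rating sheets not
  collected when staff are too busy).

All randomness flows from one integer seed through a documented
splitting scheme keyed by (seed, site index, stage), so datasets are
byte-reproducible.

**Calibration.** Default daily arrivals are 0.75 per treatment bed at
the academic sites and 0.5 at the community site (which runs at lower
per-bed utilisation — and whose 16-bed census otherwise has enough
per-bed Poisson volatility to saturate the rating scale). This keeps the
latent workload within the rating instrument's effectively linear zone
(~1.9–5.3): below ~1.9 the floor of the scale inflates ratings, above
~5.3 the ceiling deflates them, and outside that zone linear-model
recovery of the link coefficients is biased by construction. Under these
defaults crowding (mean rating ≥ 4.5) occurs at roughly 1–2% of
timepoints — rarer than in a deliberately crowding-enriched field study
— which is the accepted cost of keeping the recovery experiment
unbiased. Studies of discrimination at higher prevalence simply pass a
link intercept nearer 4.5 (see `examples/validate_scores.py`).

**What the simulator does not model.** No bed-blocking queueing, staff
scheduling, ambulance diversion, seasonal or weekday effects;
arrival counts are independent across hours given the intensity; the
physician delay has no idiosyncratic noise; rater noise is homoscedastic
and role-free. Passing recovery and discrimination tests on this
generator therefore shows the analysis machinery is correct and
well-calibrated under the stated model — not that real EHR data meet
those assumptions.

## Problem sizes and numerical choices

Simulation-based checks use 4 sites × 90 days × 5 daily timepoints
(≈ 1 800 panel rows, ≈ 23 000 visits) per replicate, 20 replicates for
recovery/discrimination, and 500 binormal datasets (n = 150, B = 500)
for bootstrap-coverage assessment — sizes chosen to keep the full suite
comfortably reproducible on a laptop. Degenerate inputs are defined, not
errors: empty ED → census 0, occupancy 0, patient hours 0, time-to-MD 0,
high-acuity fraction 0, mSEAL = intercept. A constant score has
undefined correlation and is reported missing; single-class outcomes
make the ROC undefined and raise. Rounding of ratings uses banker's
rounding on latent + noise (ties have measure zero under Gaussian
noise).

## Known limitations

* The normalization of Patient Hours and the aggregation window for
  Time to MD are this package's documented conventions; other
  conventions are configurable but change the meaning of the printed
  coefficients.
* NEDOCS coefficients and sICMED item cutoffs are transcriptions /
  stand-ins for external instruments, isolated in `instruments.yaml`.
* The derivation deliberately ignores rater clustering and temporal
  autocorrelation; standard errors on real repeated-measures data will
  be optimistic.
* The bootstrap CI is percentile-based; for very small samples it
  undercovers slightly (observed ~93% for nominal 95% at n = 150).
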