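# Methods

This note records the models and procedures `sepsikit` implements, the
parameters that matter, and the design decisions taken where the published
timing rules leave room. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Sepsis-III onset labeling

### Suspicion of infection

Antibiotic dose events are grouped per `(stay, drug)` into *courses*:
consecutive doses at most 48 h apart belong to one course ("within two
days"); only the first dose of a course can anchor a suspicion. A course
start `s` *qualifies* only if at least two doses of any antibiotic (pooled
across drugs for the stay) fall in `[s, s + 96 h]`, which removes one-off
prophylaxis. A qualifying start `t_abx` pairs with a culture at `t_cult`
when

- antibiotic first: `t_cult − t_abx ≤ 24 h`, or
- culture first: `t_abx − t_cult ≤ 72 h`,

and the episode's `t_suspicion = min(t_abx, t_cult)`. A stay's suspicion
time is its earliest episode.

Decisions where the rules are silent: every boundary is inclusive (48, 24,
72, 96 h) for determinism; the 96-h qualifying window is anchored at the
course start (the only anchor the rule references); simultaneous antibiotic
and culture count as antibiotic-first (arbitrary, fixed); only the earliest
episode defines onset (the task targets first onset). Cultures are blood
specimens unless `include_other_specimens` is set (the sensitivity
variant).

### Hourly SOFA and `t_sofa`

Observations are floored onto an hourly grid (hours `0 … ceil(LOS) − 1`;
within an hour the latest observation wins) and forward-filled with no
staleness limit — forward-fill is the only imputation anywhere in the
package. A variable never observed up to hour `h` is absent and its organ
contributes 0: an unmeasured organ cannot be scored.

Subscores follow the standard SOFA bands: respiration from PaO2/FiO2
(< 400 → 1, < 300 → 2, < 200 → 3 and < 100 → 4 with the ventilation flag;
capped at 2 unventilated); coagulation from platelets (×10³/µL: < 150, 100,
50, 20); liver from bilirubin (mg/dL: ≥ 1.2, 2, 6, 12); cardiovascular from
MAP < 70 and vasopressor dose bands (dopamine/dobutamine → 2; dopamine > 5
or norepinephrine/epinephrine ≤ 0.1 µg/kg/min → 3; above those → 4); CNS
from GCS (13–14, 10–12, 6–9, < 6); renal as the worse of the creatinine
band (≥ 1.2, 2.0, 3.5, 5.0 mg/dL) and the rolling-24-h urine-output band
(< 500 → 3, < 200 → 4), where the urine band requires a full 24 h of data
before it contributes — preventing spurious scores in the first day.

`t_sofa` is the first hour in `[t_suspicion − x, t_suspicion + y]`
(intersected with the stay) whose total is ≥ 2 above the total at the
*first hour of that restricted window*. The rules do not say which hour
provides the "initial value"; window-start is the default here (and the
common reading), with the consequence that enlarging `x` can move the
initial hour to a higher baseline and lose a detection. The monotonicity
that does hold — and that the tests assert — is: enlarging `y` with `x`
fixed never removes and never delays a detection.

### Definitions, exclusions, split, labels

`H1 = t_sofa`, `H2 = t_suspicion`, `H3 = min` — each defined only when both
events exist, so the three definitions agree on who is septic and differ
only in when. Exclusions run in a fixed order so flow counts are
reproducible: (1) pre-ICU antibiotics, (2) excluded care unit
(cardiothoracic surgical), (3) elective surgical, (4) LOS outside
[4 h, 480 h], (5) no vital signs at all, (6) onset within 4 h of admission
(inclusive; under `strict_h3_grace` the H3 onset is used for every
definition, isolating definition effects from cohort effects), (7) one stay
per patient (earliest kept). Each excluded stay carries exactly the first
reason that fired. A stay with suspicion but no in-window SOFA rise is a
control, not an exclusion (configurable).

The 85/15 train/test split is drawn *before* exclusions, stratified on
sex × age quartile × LOS quartile × ever-ventilated. Train counts use
largest-remainder allocation: each stratum gets `floor(0.85 n)` and the
largest fractional remainders absorb the slots needed to reach the global
`round(0.85 N)` — every stratum is within one patient of the target and
small cohorts still receive a test set (naive per-stratum rounding sends
nearly everything to train when strata are small). Singleton strata go to
train.

Hourly labels: onset is floored to the grid; a septic stay contributes
hours strictly before the grid onset, labeled 1 when onset lies in the
half-open lookahead `(h, h + T]` — so the positive count per septic stay is
exactly `min(T, floor(t_sepsis))`; controls contribute every in-stay hour
labeled 0. Training never sees at- or post-onset rows, keeping the task
predictive rather than re-derivation of the label.

## 2. Features

The default specification has 113 columns: 38 raw (34 observed clinical
variables + age, sex, hour since ICU admission, pre-ICU hospital hours) and
75 derived (8-h rolling max/min/mean for 15 core vitals/labs; raw
measurement counts over 8 h for 10 variables; 8-h deltas for 8 variables;
and the 12 depth-2 coefficients of the time-augmented signature of the
(heart rate, MAP) pair over an 8-h backward window). The derived set is a
configurable, non-authoritative default of the same shape and style as
published sepsis early-warning pipelines. End-tidal CO2 is not used.

Signatures are computed exactly for piecewise-linear paths: a segment's
signature is the truncated tensor exponential of its increment and segments
combine by Chen's identity; the rolling depth-2 case uses a vectorized
closed form verified against the general routine. Hours before a variable's
first observation are filled with a fixed per-variable reference value
(scorers need finite inputs; the fill is constant, so causality is
preserved). Every feature at hour `h` depends only on data at or before `h`
— asserted by a pipeline-wide truncation test.

## 3. Risk scorers

All scorers expose `fit(X, y, groups)` / `score(X)` on patient-hour rows
and are deterministic given their seed.

- **GBM** — a LightGBM binary classifier on independent patient-hour rows.
  Defaults: 31 leaves, learning rate 0.1, 100 trees, `min_child_samples
  60`, `colsample_bytree 0.8`, single-threaded deterministic mode. The
  extra regularization matters: with only a few hundred positive hours in
  ~20k rows, looser settings memorize noise. No class reweighting by
  default (a flag is available). LightGBM's probabilities are
  overconfident on this data, so a threshold set at 85% *training*
  sensitivity can transfer poorly to test sensitivity — visible in the
  worked example; AUROC, being threshold-free, is unaffected.
- **LSTM** — a single-layer LSTM (default 24 hidden units) over each
  stay's standardized hourly sequence with a per-hour sigmoid readout,
  trained with masked binary cross-entropy and Adam (8 epochs, batch 64
  stays, lr 5e-3) via hand-written backpropagation through time, all in
  NumPy; gradients are verified against finite differences in the test
  suite. Sequences are end-padded per minibatch, so padded steps never
  touch the loss. Single-threaded NumPy makes training bit-reproducible
  under a fixed seed.
- **CoxPHM** — a proportional-hazards model with time-varying covariates
  (each patient-hour is one `[h, h+1)` interval; a septic stay is an event
  at its grid onset; controls are censored at discharge), fitted by
  lifelines with ridge penalizer 0.1 after dropping near-constant columns
  and standardizing. The hourly risk is the T-hour event probability
  `r(t) = 1 − exp(−[H0(t+T) − H0(t)] · exp(βᵀx_t))` with the Breslow
  baseline cumulative hazard. The Breslow estimate is a step function over
  ~n_events jump times, so a 6-h horizon frequently contains no jump and
  the raw step estimate would zero the risk irrespective of covariates;
  H0 is therefore linearly interpolated between event times. This
  horizon-risk formulation is one reasonable reading of a "modified"
  survival scorer; the interface allows substitution.

Hyperparameters can be selected by patient-grouped 5-fold CV (mean pooled
patient-hour AUROC across folds; winner refitted on all training data) over
small documented grids; the experiment runner uses fixed defaults unless
`tune=True`, keeping the full grid at desk scale.

## 4. Evaluation

AUROC is pooled over patient-hours, not averaged per patient, matching the
"all patients and observation times" framing; ties count ½. Confidence
intervals are percentile bootstrap over 100 resamples with the *patient* as
the resampling unit (respecting within-stay correlation; percentile rather
than BCa because 100 resamples are too few for BCa stability); resamples on
which the metric is undefined are redrawn and counted. The alert threshold
is the largest score achieving ≥ 85% sensitivity on training patient-hours
(the ⌈0.85 P⌉-th highest positive score); sensitivity/specificity/accuracy
are then computed over test patient-hours (patient-hour rather than
per-patient, configurable). The experiment runner evaluates every
`{definition, model, window, horizon, exclusion-variant}` cell, emits
summary tables and ROC point sets, and flags the cross-definition inversion
(best-model-on-worst-definition vs worst-model-on-best-definition) when it
occurs. On the strict-exclusion variant, H3 equals the main H3 run by
construction — its own criteria are the strict ones.

## 5. The synthetic cohort generator

The generator emulates the statistical structure the labeling and
prediction stages assume — not any specific database's schemas or
distributions (no public distributional facts were available to calibrate
against; baselines are textbook stable-ICU physiology).

Per stay: LOS is lognormal (median 60 h, σ = 0.6) clipped to the 4–480 h
inclusion band; ~34 variables are sampled as per-patient baselines plus
white measurement noise at realistic cadences (vitals ~0.7/h, labs every
6–24 h), with baselines placed ~3σ inside the zero band of every SOFA
threshold. Septic stays (default 30%) carry a latent infection time τ
(uniform in 15–55% of the stay) and a two-phase deterioration, as in
clinical sepsis:

- *SIRS phase*: heart rate (+45 bpm), respiratory rate (+14), temperature
  (+2.2 °C), WBC (+12), lactate (+4.5 mmol/L) and SpO2 (−6%) ramp from τ
  over 8 h with septic-shock effect sizes;
- *organ phase*: after an organ lag of 1–4 h, MAP (−20 mmHg), platelets
  (−160), bilirubin (+2.3), creatinine (+1.7), GCS (−4), urine output
  (−55 mL/h) and the PaO2/FiO2 ratio (−240) follow, with ventilation (50%)
  and norepinephrine (60%) onset for a fraction of septic stays. The
  platelet, creatinine, bilirubin and GCS shifts each cross at least one
  SOFA band on their own, so the total score rises by ≥ 2 once the ramp
  completes — the deterioration is detectable by construction.
- *recognition*: the blood culture (τ + 6–16 h) and first antibiotic dose
  (τ + 8–20 h, then 3–6 doses 4–12 h apart) follow visible deterioration,
  as clinicians order them in response to it. This ordering is what gives
  the hours *before* H2/H3 onsets predictive signal; with recognition at or
  before the physiology, no model could beat chance on pre-suspicion hours.

Background antibiotic doses (mean 0.1/stay) and cultures (0.2/stay) occur
decoupled from any infection in all stays, exercising the pairing engine's
rejection paths; 15% of infection cultures are non-blood specimens,
exercising the specimen filter. The ground-truth table records τ, the true
first antibiotic/culture times, the organ-deterioration time, and a
`rule_conforming` flag: the infection events satisfy the pairing rules
*and* no earlier background event could form an earlier episode
(conservative — a background event preceding the infection pair may
legitimately produce an earlier `t_suspicion`, in which case the engine is
right and the ground-truth "first infection events" are simply not the
earliest episode). Output tables are a pure function of the configuration,
which includes the seed.

What passing tests on this generator do and do not show: they verify the
timing rules, the labeling algebra, leakage-freedom, and that the scorers
recover a planted signal of realistic shape; they say nothing about
performance on real ICU data, where missingness is informative, drifts are
heterogeneous and non-monotone, documentation practices vary by unit, and
the 38-variable set interacts with billing-driven measurement patterns.

## 6. Numerical and protocol choices

- Time is hours since ICU admission, continuous for events, floored to the
  grid only for SOFA and features. Grid hours are `0 … ceil(LOS) − 1`.
- Onset hours are floored to the grid before labels, so the label-count
  closed form is exact.
- Acceptance-scale measurements of held-out skill use grouped 5-fold CV
  *pooled* out-of-fold AUROC on the 500-patient study cohort: the 85/15
  protocol split leaves only ~15 septic test stays, whose single-split
  AUROC carries sampling error of ±0.1 or more, while pooled CV scores
  every patient-hour out-of-fold. The experiment runner itself keeps the
  85/15 protocol.
- Study sizes were chosen for desk scale: 500 patients for the end-to-end
  checks, 40 patients × 20 seeds for null calibration, 300 for the worked
  examples. Bootstrap resamples: 100.
- Stage caching in the pipeline is keyed by content hashes of configuration
  and upstream manifests, never timestamps.

## 7. Known limitations

- Forward-fill with no expiry is the only imputation; stale values carry
  indefinitely.
- The exact identity of the 75 derived features and the signature channel
  groups is a documented default, not an authoritative reconstruction.
- The horizon-risk CoxPHM is one interpretation of a modified survival
  scorer; alternatives (e.g. discrete-time hazards) would fit the same
  interface.
- The generator's drifts are monotone ramps with independent noise; real
  septic trajectories relapse, remit, and interact with treatment.
- GBM probability overconfidence makes train-calibrated thresholds
  transfer poorly on synthetic data; threshold-free metrics are unaffected.
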