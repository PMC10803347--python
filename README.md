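# sepsikit

Sepsis-III onset phenotyping and real-time sepsis prediction on ICU event
tables — with a synthetic cohort generator that makes the whole chain
verifiable without access to a credentialed EHR database.

## The problem

The sepsis-III consensus defines sepsis as life-threatening organ
dysfunction (a rise of the SOFA score by ≥ 2 points) in the presence of
suspected infection, but it does not define a unique *onset time*. Working
from timestamped EHR events, three readings coexist in the literature:

- **H1**: `t_sepsis = t_sofa` — onset at the organ-dysfunction time;
- **H2**: `t_sepsis = t_suspicion` — onset at suspicion of infection;
- **H3**: `t_sepsis = min(t_sofa, t_suspicion)` — the earlier of the two;

where `t_suspicion` is the earlier member of a qualifying antibiotic-start /
culture pair (antibiotic first → culture within 24 h; culture first →
antibiotic within 72 h; a course groups doses ≤ 48 h apart; a start counts
only with ≥ 2 doses of any antibiotic within 96 h), and `t_sofa` is the
first hour inside the SOFA window `{x, y}` around `t_suspicion` at which the
hourly total SOFA is ≥ 2 above its window-initial value.

Prediction models trained against these subtly different targets are *not*
comparable: the definition can move measured AUROC more than the choice of
model. `sepsikit` implements the complete labeling chain, the patient-hour
prediction task (label 1 iff onset falls within the next `T` hours), three
interchangeable risk scorers (LightGBM trees, a NumPy LSTM, a
horizon-risk Cox model with time-varying covariates), and an evaluation
harness that quantifies the definition effect — plus a synthetic ICU cohort
generator with known ground-truth infection times, so every stage is
testable at desk scale.

It is intended for methods researchers studying label-definition
sensitivity in early-warning models, and as a tested reference
implementation of the sepsis-III timing rules for anyone who needs them on
their own (long-format) ICU extracts.

## Worked example

`examples/05_definition_sensitivity.py` runs the headline experiment on a
300-patient synthetic cohort (30% septic), SOFA window `{24,12}`, horizon
`T = 6` h:

```text
definition  model  window_x  window_y  horizon            auroc_ci  specificity  sensitivity  accuracy
        H1    gbm        24        12        6 0.892 [0.830,0.970]     1.000000     0.000000  0.989116
        H1   lstm        24        12        6 0.773 [0.620,0.909]     0.475470     0.833333  0.479365
        H1 coxphm        24        12        6 0.794 [0.579,0.882]     0.664833     0.708333  0.665306
        H2    gbm        24        12        6 0.956 [0.884,0.999]     0.999545     0.000000  0.988759
        H2   lstm        24        12        6 0.905 [0.758,0.996]     0.915909     0.875000  0.915468
        H2 coxphm        24        12        6 0.940 [0.867,0.996]     0.882273     0.875000  0.882194
        H3    gbm        24        12        6 0.853 [0.754,0.966]     1.000000     0.000000  0.989116
        H3   lstm        24        12        6 0.768 [0.616,0.910]     0.469509     0.833333  0.473469
        H3 coxphm        24        12        6 0.817 [0.747,0.859]     0.519486     1.000000  0.524717

best model on worst definition: gbm on H3 (AUROC 0.853); worst model on
best definition: lstm on H2 (AUROC 0.905). Cross-definition inversion: the
best model under the worst definition underperforms the worst model under
the best definition — model rankings are not comparable across onset
definitions.
```

Each row is one `{definition, model}` cell: pooled patient-hour AUROC on
the held-out 15% of patients with a 50-resample patient-level bootstrap CI,
and sensitivity/specificity/accuracy at the threshold calibrated to 85%
sensitivity on the training split. The inversion in the note is the point:
the *best* scorer under H3 scores below the *worst* scorer under H2, so a
cross-paper comparison that ignores the label definition would pick the
wrong model. (The tree model's test sensitivity of 0 at that threshold is
the flip side of its overconfident probabilities — see
`docs/methods.md`.)

The other examples are smaller single-capability walkthroughs:
`01_generate_cohort.py` (the generator and its ground truth),
`02_onset_labeling.py` (suspicion pairing, hourly SOFA, exclusion flow),
`03_signature_features.py` (path signatures and the 38 raw + 75 derived =
113-column design matrix), `04_train_and_evaluate.py` (one scorer, threshold
calibration, bootstrap CI).

A thin CLI mirrors the pipeline stages:

```bash
sepsikit run-all --seed 1 --output-dir runs/demo   # generate → … → evaluate
sepsikit report --output-dir runs/demo
```

Stages cache their outputs by content hash; a rerun with the same
configuration is a no-op, and deleting an intermediate recomputes only the
stages downstream of it.

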