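# comfortfuse

Personal comfort sensing from consumer wearables in free-living conditions.

People registering discomfort — thermal, acoustic, or otherwise — show
autonomic responses before they consciously notice anything. `comfortfuse`
is a pipeline for testing how much of that signal consumer hardware can
recover outside the lab: an ECG chest strap streaming RR intervals through
a sports watch, the watch's own 1 Hz record stream (heart rate, wrist skin
temperature, barometrics, a packed 25 Hz wrist accelerometer), and a
smartphone logging inertial, magnetic, acoustic and light sensors at
~10 Hz from a trouser pocket. Comfort is self-labelled in the moment with
the watch's lap button: even lap indices mean *comfortable*, odd mean
*uncomfortable*, and a session starts comfortable.

The package is aimed at researchers building or auditing free-living
physiological classification pipelines: everything between raw
device exports and a cross-validated classifier is implemented, tested and
inspectable, and a forward simulator generates full multi-device cohorts
with known ground truth so every stage can be verified without access to
any private recording.

## What the pipeline does

1. **Ingestion** (`streams`) — five plain-text per-session streams with
   strict parsing: phone log, RR intervals, wrist records (local-time
   strings with a midnight crossover guard; packed accelerometer bursts),
   lap timeline, session log. Missing files are an exclusion signal.
2. **Synchronisation and windowing** (`sync`) — the two device clocks are
   aligned through a shared three-arm-swing gesture: with anchor times
   t_G,sync and t_P,sync on the watch and phone, phone timestamps shift by
   (t_G,sync − t_P,sync). An automatic spike detector proposes anchors;
   ambiguous sessions fall back to manual entry. Sessions are gated on the
   first phone inter-sample gap over 5 s, trimmed with 90 s of boundary
   padding (start-only when a gap truncates the session), and cut into
   non-overlapping 60 s windows labelled from the lap timeline by
   majority overlap.
3. **HRV features** (`hrv`) — RR artifacts outside 333–1500 ms removed;
   beat times rebuilt by cumulative summation from the usable-window
   start; per-window mean RR, SDNN, RMSSD, SDSD, pNN50, mean HR;
   Lomb–Scargle LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) band powers on
   the irregular beat times; Poincaré SD1/SD2; sample entropy
   (m = 2, r = 0.2·SD). Windows with under 30 beats are discarded.
4. **Context features** (`context`) — phone accelerometer magnitude and
   per-axis statistics, jerk, gyroscope, sound level (absolute dB),
   magnetometer magnitude; watch HR statistics and heart-rate reserve
   (HR − HR_rest)/(HR_max − HR_rest)×100, wrist temperature mean/SD/rate
   of change, unpacked 25 Hz wrist-accelerometer statistics.
5. **Feature table** (`features`) — a fixed 55-feature schema across nine
   layers; within-session z-scoring everywhere except the acoustic
   features, which stay absolute; an audited exclusion ledger for
   everything that proxies session identity (altitude, gravity
   components, per-axis magnetometer, luxometer, GPS speed, …).
6. **Evaluation** (`evaluate`) — leave-one-session-out cross-validation
   of Gaussian naive Bayes, RBF SVM, random forest and gradient-boosted
   trees, with class weights and SMOTE on training rows only; single-class
   held-out sessions are skipped as test folds but still train the
   others; pooled confusion matrices; Shapley-value feature and layer
   importance (in-repo permutation estimator).
7. **Simulation** (`synth`) — the forward model generating all five
   streams per session with configurable state-dependent RR, temperature,
   sound and activity levels, two clocks with a known offset, the sync
   gesture on both accelerometers, and optional data-loss gaps.

## Worked example

```python
from comfortfuse import SynthConfig, generate_cohort, evaluate as ev
from comfortfuse.pipeline import process_bundle, build_feature_matrix

cohort = generate_cohort(SynthConfig(seed=1))          # 18 sessions, 8 single-class
matrix = build_feature_matrix([process_bundle(b) for b, _ in cohort])
print(len(matrix))                                     # 411 labelled 60-s windows

folds = ev.loso_folds(matrix)
print(sum(f.valid for f in folds))                     # 10 valid of 18 folds

results, _ = ev.run_loso(matrix, ("random_forest",), smote=True, seed=1)
print(ev.summarise(results)[["model", "f1_macro_mean", "f1_macro_sd"]])
#            model  f1_macro_mean  f1_macro_sd
#    random_forest          0.984        0.025

cm = ev.combined_confusion(results["random_forest"])
print(cm.tp, cm.fp, cm.fn, cm.tn, round(cm.accuracy, 3))
# 102 0 4 118 0.982
```

The fold count is structural: 8 of the 18 sessions contain a single
comfort state, cannot yield binary test metrics, and are skipped as test
folds while still training the other 17 folds — leaving 10 valid folds.
The high F1 reflects the simulator's default conditions, where every
state-linked channel shifts at each transition; free-living recordings
are far harder (see `docs/methods.md`).

Layer importance on the same cohort (mean |Shapley value| per feature,
averaged within each layer):

```python
model, _ = ev.fit_full_model(matrix, "random_forest", seed=1)
imp = ev.shap_layer_importance(model, matrix, seed=1)
print(imp.per_layer.round(4))
# kinematic    0.0113
# hr_wrist     0.0078
# hrv          0.0056
# acoustic     0.0011
# magnetic     0.0004
```

## Command line

```bash
comfortfuse simulate --out sessions/ --seed 4          # write a synthetic cohort
comfortfuse process sessions/session-* --out features.csv
comfortfuse evaluate --matrix features.csv --models rf,svm,nb,xgb \
    --smote --seed 4 --out results/
```

Manual sync anchors and lap corrections go in a per-session
`options.yaml`:

```yaml
sync: {garmin_s: 8.0, oppo_s: 5.0}
lap_overrides: {0: uncomfortable}
insert_boundaries: [412.0]
```

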