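# icumotion

Decoding wearable accelerometry from critically ill patients with severe
brain injury. Multi-sensor triaxial accelerometry (six extremity sensors
and one bed sensor, 10 Hz) is turned into windowed time-, frequency- and
wavelet-domain motion features, and supervised low-rank logistic models
detect the patient's current motor responsiveness — the motor component
of the Glasgow Coma Scale (GCSm, 1–6) — and predict functional outcome on
the Glasgow Outcome Scale–Extended (GOSE, 1–8), with bias-corrected
cross-validated uncertainty. The package is aimed at researchers in
clinical neuro-monitoring and wearable-sensor analytics who want a tested,
reusable implementation of this analysis stack; since the underlying
clinical recordings cannot be shared, it ships a seeded synthetic cohort
generator so every stage runs and is verified end to end.

## The model

From each baseline-filtered (4th-order Butterworth high-pass, 0.2 Hz)
5-s window, seven features are extracted per sensor and RSS-levelled over
axes x, y, z: signal magnitude area (SMA), medians of 2.5 Hz high-/low-pass
filtered signal (HLF_h, HLF_l), median frequency (MFR), frequency-domain
entropy (FDE), 0.3–3.5 Hz band power (BPW) and db5 level-2–6 wavelet
energy (WVL); an eighth, the proportion of dynamic activity
(PDA = fraction of windows with SMA ≥ 0.135 g), summarizes each
observation window. For an observation window with T 5-s steps preceding
a clinical evaluation, the design row has 6·7·T + 6 columns. The fitted
model is

    normalize (per placement-feature combination, 48 statistics)
    → LOL projection to d ∈ [2, 20] dimensions
      (class-mean difference direction + leading principal directions)
    → element-wise Yeo-Johnson transform
    → logistic regression, P(endpoint > threshold | history)

evaluated with 5×5 repeated stratified cross-validation over the
(19 windows × 19 d) grid, m = 9 multiple imputations of missing features
(bootstrap-EM with lag/lead columns, Box-Cox scale), and bootstrap
bias-corrected cross-validation (BBC-CV, 1000 patient resamples) for
selection-optimism-free AUC, classification and calibration (ICI, E_max)
estimates. Feature-significance matrices (mean |LOL loading| × |β| per
sensor-feature cell) and a 10-min-step sliding monitor with transition
lead times support interpretation. See `docs/methods.md` for the full
account.

## Worked example

```python
from icumotion.synthetic import CohortConfig, generate_cohort
from icumotion.pipeline import run_grid

config = CohortConfig(n_patients=20, recording_hours=1.0,
                      gcsm_eval_rate=96.0, missing_fraction=0.0, seed=7)
cohort = generate_cohort(config)
results = run_grid(cohort, windows_s=[180, 540], d_grid=[2, 5],
                   thresholds=[4], endpoint="GCSm", seed=7)
print(results.summary(4, n_resamples=1000, seed=7))
```

prints

```
Endpoint GCSm > 4
Optimal configuration: window 3 min, d = 2 (pooled roc_auc = 1.000)
BBC-CV roc_auc: 1.000 [1.000-1.000] (1000 resamples, 0 dropped)
```

Reading this: among the tested configurations, a 3-min observation window
with a 2-dimensional projection best separates evaluations above and
below GCSm 4, and the patient-bootstrap estimate of out-of-fold AUC —
corrected for having selected that configuration — is 1.0 with a
degenerate interval. The default generator separates motor states
strongly (burst rates differ 120-fold between levels 1 and 6), so small
noiseless cohorts saturate; weaken `movement_rate_by_state` or add
missingness to see intermediate AUCs, or set `outcome_link_strength=0`
and an outcome endpoint to see the estimate collapse onto 0.5.

Lower-level objects follow the model/results pattern:

```python
from icumotion.model import ThresholdModel
res = ThresholdModel(observation_matrix, threshold=4, d=8).fit()
res.params; res.bse; print(res.summary()); res.predict(rows)
```

A thin CLI mirrors the pipeline stages:
`icumotion simulate | extract | impute | fit | evaluate | monitor`
(see `icumotion --help`).

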