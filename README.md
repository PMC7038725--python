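# stresspipe

Binary stress recognition from wrist-worn wearable signals — the kind of
data an Empatica E4 records: interbeat intervals (IBI) from PPG,
electrodermal activity (EDA, 4 Hz), skin temperature (4 Hz) and a 3-axis
accelerometer (32 Hz).  The package is aimed at researchers in
psychophysiology and digital health who want a tested, reproducible
implementation of the standard lab-to-field stress-detection workflow:

1. **Preprocessing** — non-overlapping 2-minute windows; RR-interval
   artifact screening with a 20% relative-deviation rule against the last
   clean beat, cubic-spline replacement of flagged beats, rejection of
   windows with more than 10% artifacts; rule-based EDA artifact
   screening per 5-s epoch (steep conductance change co-occurring with
   accelerometer motion, or implausible levels); zero-phase low-pass
   tonic/phasic EDA decomposition.
2. **Features** — 13 HRV features (mean RR, SDNN, RMSSD, pNN50,
   triangular index and TINN on a 1/128-s histogram, SDSD, and VLF/LF/HF
   band powers, LF/HF and band peaks from an FFT periodogram of the
   tachogram resampled at 4 Hz) plus 7 distribution/peak features for
   each of the phasic and tonic EDA components — 27 in total, averaged
   over a session's valid windows.
3. **Labeling** — the 5-item ambulatory Perceived Stress Scale,
   `PercStress = (7−H) + (7−C) + A + S + F`, binarized at 15; lab
   sessions additionally carry known-context labels (baseline = relaxed,
   stressor = stressed, recovery excluded).
4. **Modeling** — correlation-based feature selection, exact-balance
   random undersampling, min-max normalization, five classifiers (MLP
   2×5, random forest with 100 trees, 3-NN, RBF-SVM, logistic
   regression), evaluated by 10-fold CV, an 80/20 split and
   cross-environment transfer in the five-way matrix LLKC / LLSR / DDSR /
   LDKC / LDSR (environment × ground-truth family).

Because no suitable cohort is publicly deposited, the package ships a
first-class synthetic study generator (`stresspipe.synthetic_data`) whose
sessions carry the assumed signal structure — stress shortens mean RR,
damps HF power, raises LF/HF, raises tonic EDA and the SCR rate — plus
injectable artifacts with ground-truth masks and self-report label noise
that is larger in the field than in the lab.

## Worked example

```python
from stresspipe import StudyDesign, simulate_study, extract_session_records
from stresspipe.modeling import ModelSpec, build_datasets, evaluate_cv, evaluate_transfer

study = simulate_study(StudyDesign(), seed=1)          # 12 participants: lab + 4 daily sessions
records = extract_session_records(study)               # preprocess + featurize + aggregate
datasets = build_datasets(records)

spec = ModelSpec(classifier="rf", modality="combined")
llsr = evaluate_cv(datasets["lab_selfreport"], spec, seed=1, model_type="LLSR")
ddsr = evaluate_cv(datasets["daily_selfreport"], spec, seed=1, model_type="DDSR")
ldsr = evaluate_transfer(datasets["lab_selfreport"], datasets["daily_selfreport"],
                         spec, seed=1, model_type="LDSR")

print(f"LLSR 10-fold accuracy: {llsr.accuracy:.1f}% (fold SD {llsr.fold_sd:.1f})")
print(f"DDSR 10-fold accuracy: {ddsr.accuracy:.1f}% (fold SD {ddsr.fold_sd:.1f})")
print(f"LDSR transfer accuracy: {ldsr.accuracy:.1f}% on {ldsr.n_test} daily sessions")
print("top features:", ", ".join(ldsr.selected_features[:5]))
```

prints

```
LLSR 10-fold accuracy: 94.2% (fold SD 12.5)
DDSR 10-fold accuracy: 64.5% (fold SD 26.9)
LDSR transfer accuracy: 77.1% on 48 daily sessions
top features: hrv_hf_power, hrv_sdsd, hrv_rmssd, hrv_mean_rr, eda_tonic_p80
```

Within the controlled lab environment the self-report model is nearly
perfect; the daily-to-daily model suffers from its noisier field
self-report training labels; and training in the lab while testing in
the field (LDSR) recovers much of that loss — the central
cross-environment effect this pipeline is built to measure.  The
selected features are the expected physiology: vagally mediated HRV
measures and the tonic skin-conductance level.

The same flow is available from the shell:

```sh
stresspipe simulate --out study --seed 1
stresspipe extract study --out features.csv
stresspipe evaluate-matrix --features features.csv --seed 1 --out results/
```

which writes `results/results.csv` (one row per model type × eval mode ×
modality × classifier) and a `manifest.json` recording every default.

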