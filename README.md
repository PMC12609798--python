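# repforce

Force–time curve feature extraction and RPE (Rating of Perceived Exertion)
estimation for repeated isokinetic resistance-exercise sets, with a seeded
synthetic cohort simulator standing in for proprietary load-cell data.

The pipeline mirrors a complete fatigue-estimation analysis:

1. **synth** — generate a cohort of subjects (two limbs each) performing
   7 sets × 8 repetitions at 50 Hz, with per-set work declining geometrically
   at a subject-specific fatigue rate, an early force peak, force noise
   growing with fatigue, and integer 0–10 RPE labels rising with latent
   fatigue. Ground-truth repetition windows and per-set work are retained for
   oracle testing.
2. **preprocess** — zero-phase 4th-order Butterworth low-pass (20 Hz cutoff),
   repetition segmentation via relative-threshold hysteresis, and force
   normalization (allometric `F / m^0.67` by default, or plain per-mass).
3. **features** — per-repetition primary descriptors (peak, mean, RMS,
   variance/SD, skewness/kurtosis, work, time-to-peak, rate of force
   development), set-level aggregation, interaction composites (Work/SD,
   Peak × RMS, Δ × ratio), baseline- and previous-set-relative descriptors,
   log-transformed variants, and assembly into one learning table.
4. **model** — cleaning (constant / excess-missing column removal, median
   imputation), |r| ≥ 0.5 Pearson screening against the labels, three
   regressors (Random Forest with 400 estimators, HistGradientBoosting with
   depth 6 / 800 iterations / learning rate 0.04, Ridge α = 1.0 on
   standardized features), and median-based cut-point discretization with
   pool-adjacent-violators monotonicity repair.
5. **evaluate** — out-of-fold metrics under plain 5-fold or subject-grouped
   K-fold (both limbs of a participant always on one side of every split):
   R², MAE, RMSE, Pearson r, tolerance accuracies (|error| ≤ 0.5 / ≤ 1.0),
   confusion matrix, error buckets, and Bland–Altman limits of agreement.

## CLI

```bash
# full pipeline: simulate -> preprocess -> features -> train -> evaluate
repforce run-all --seed 7 --out runs/demo

# or stage by stage
repforce simulate --subjects 32 --seed 7 --out runs/cohort
repforce preprocess --cohort runs/cohort --out runs/pre
repforce features --cohort runs/cohort --out runs/feat
repforce train --table runs/feat/table.csv --out runs/models
repforce evaluate --table runs/feat/table.csv --scheme groupkfold --out runs/eval
```

Every command accepts `--config C.json` (a `RunConfig` document, see
`repforce.pipeline.RunConfig`) and `--seed` to override the config seed. A
single top-level seed fans out to independent per-stage streams, and the
`run-all` manifest records sha256 checksums of every artifact; re-running the
same config reproduces identical checksums.

## Acceptance

The acceptance criteria are property-based (formula oracles, analytic filter
response, exact segmentation recovery, cut-point monotonicity, a grouped-CV
leakage demonstration, signal recovery with/without engineered relative
features, model-family ordering, byte-identical reproducibility) and live in
`tests/test_acceptance.py`. The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a seeded end-to-end pipeline as an executability check and writes the
(empty) numeric-target map: the reference study's headline numbers were
measured on a proprietary dataset and are not reproducible offline, so no
numeric targets are reported.
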