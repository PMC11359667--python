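# emgpipe

A tested pipeline for surface-EMG hand-gesture analysis: seeded synthetic
eight-channel recordings at 200 Hz, a preprocessing chain (zero-phase
band-pass, per-channel normalization, rectification, moving-RMS envelope),
segmentation into labeled 150-sample windows, ten time-domain features per
channel (min, max, SD, zero crossings, RMS, average amplitude change,
amplitude of first burst, MAV, waveform length, Willison amplitude),
feature engineering (z-scoring, correlation audit, PCA with a cumulative
explained-variance target, one-hot labels), and a stratified five-fold
cross-validated benchmark of five classifiers (logistic regression, linear
and RBF SVMs, kNN, random forest) with per-class and overall
precision/recall/F1/accuracy and one-vs-rest ROC-AUC.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: dataset-composition
arithmetic, AUC contracts, brute-force oracle equivalence for all ten feature
operators and the confusion-matrix metrics, structure recovery on synthetic
data (separable profiles vs. the chance-level null), CV partition laws and
PCA contracts.

## CLI

```sh
emgpipe demo --seed 42 --out results/          # full pipeline on synthetic data
emgpipe demo --seed 42 --out quick/ --scale 0.01   # scaled-down quick run

emgpipe synth      --out rec.csv --seed 7
emgpipe preprocess --in rec.csv --out segments.csv
emgpipe features   --in segments.csv --out features.csv
emgpipe feateng    --in features.csv --retention 0.999 --out engineered.csv
emgpipe evaluate   --in features.csv --models lr,svm-linear,svm-rbf,knn,rf \
                   --folds 5 --seed 42 --out report/

emgpipe run --config pipeline.yaml             # fully configured run
emgpipe validate --config pipeline.yaml        # echo resolved defaults
```

Every stage accepts `--config cfg.yaml` (see `emgpipe.config.PipelineConfig`
for the schema); one global seed deterministically derives all stage seeds,
so reports are byte-identical across runs. Exit codes: 0 ok, 2 configuration
error, 3 data error.

By default evaluation refits the z-score and PCA inside each training fold
(no test-set leakage); `--paper-mode` fits them once on all data for
comparison.

## Layout

- `src/emgpipe/synth.py` — synthetic recording generator + CSV round trip
- `src/emgpipe/preprocess.py` — filtering/normalization/envelope/segmentation
- `src/emgpipe/features.py` — the ten feature operators and matrix assembly
- `src/emgpipe/feateng.py` — z-score, correlation audit, PCA, one-hot
- `src/emgpipe/evaluate.py` — stratified CV benchmark, metrics, tables
- `src/emgpipe/config.py`, `pipeline.py`, `cli.py` — orchestration and CLI
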