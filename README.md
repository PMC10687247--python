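# breathsound

Analysis pipeline for breathing sounds recorded at the entrance of
tracheostomy tubes. Breath sounds are classified per respiratory cycle
into three categories:

| label | meaning | acoustic signature | clinical action |
|-------|---------|--------------------|-----------------|
| `NS` | normal breathing sound | low energy concentrated ~1500–2000 Hz | none |
| `VS` | vibrant breathing sound (movable obstacle, e.g. sputum) | broadband 500–12 000 Hz bursts repeating ~100/s ("vertical lines" in the spectrogram) | suction |
| `SS` | sharp breathing sound (fixed obstacle, e.g. crust, clot) | sustained high-frequency spectral lines above 2 kHz ("horizontal lines") | suction or tube/inner-cannula change |

A cycle showing **both** VS and SS patterns is labeled **VS** (the
obstacle is still movable; suction is the faster, lower-risk first
intervention). The binary view maps `NS → normal` and `{VS, SS} →
abnormal`; *abnormal is the positive class by default* (flip with
`positive=` in `binary_metrics`/`roc_curve`).

Because the clinical recordings are not publicly deposited, the package
ships a first-class synthetic generator that reproduces the documented
acoustic structure of each class, with exact ground-truth labels and
cycle bounds. Every downstream stage is benchmarked against it.

## Modules

- `breathsound.synth` — labeled synthetic corpora: per-class
  cycle-duration distributions (NS 3.801±1.592 s, VS 3.033±0.949 s,
  SS 3.876±1.246 s), ~10.5 breaths/min assembly, band-limited
  background (<1 kHz) / event (<1.5 kHz) noise at exact SNR.
- `breathsound.preprocess` — linear-phase high-pass noise filter
  (default cutoff 1500 Hz, where recorded noise concentrates) and
  hysteresis energy-envelope segmentation into respiratory cycles.
- `breathsound.features` — STFT power spectrograms (Hann 25 ms / hop
  10 ms), MFCC(20)/MFCC(40) over a 48-filter mel bank spanning
  0–12 kHz, per-cycle pooled feature vectors, and the rule-classifier
  descriptors (band-energy fractions, amplitude-modulation peak,
  spectral-line persistence).
- `breathsound.rules` — deterministic three-category classifier with
  the VS-over-SS tie-break and per-cycle decision traces.
- `breathsound.ml` — SVM (3rd-degree polynomial or RBF) and kNN
  (k ∈ {3, 5, 7}) on MFCC vectors; a small pure-numpy CNN
  (`breathsound.cnn`) on 128×128 spectrogram images, batch size 32
  (iteration budget scaled down to a configurable 2 000 steps).
- `breathsound.evaluate` — stratified 80/20 splits; accuracy,
  sensitivity, specificity, PPV, NPV, ROC/AUC; three-class total
  accuracy and *accuracy in abnormal sounds* (VS-vs-SS accuracy over
  true-abnormal cycles); cohort summary tables.
- `breathsound.io` / `breathsound.config` / `breathsound.cli` — WAV and
  CSV dialects, strict YAML pipeline configuration, subcommand CLI.

## CLI

```bash
# synthesize a labeled recording (WAV + labels.csv + config.yaml)
breathsound generate --cycles NS=5,VS=3,SS=2 --seed 1 -o out/

# segment into cycles, extract features, classify
breathsound segment out/recording.wav -o out/cycles.csv
breathsound features out/recording.wav --cycles out/labels.csv --variant mfcc20 -o out/mfcc20.csv
breathsound classify-rules out/recording.wav --cycles out/labels.csv -o out/rules.csv

# train/predict/evaluate
breathsound train --features out/mfcc20.csv --labels out/labels.csv --model svm --kernel rbf -o out/model.joblib
breathsound predict --model out/model.joblib --features out/mfcc20.csv -o out/pred.csv
breathsound evaluate --truth out/labels.csv --pred out/rules.csv -o out/metrics/
breathsound report --labels out/labels.csv
```

File schemas: label tables are UTF-8 CSV
`cycle_id,start_s,end_s,label` (seconds, 3 decimals, half-open
intervals, labels exactly `NS|VS|SS`); audio is mono 16-bit PCM WAV at
44.1 kHz; metrics are emitted as CSV plus a plain-text report, ROC
points as `fpr,tpr` CSV.

## Caveats

- Train/test splitting is by sample (cycle), not grouped by patient,
  matching the original evaluation design; grouped splitting is out of
  scope.
- The mel filter bank is a documented stand-in (48 triangular filters,
  0–12 kHz); the originally used banks were not published in the main
  text. Extraction metadata records this.
- The CNN is a deliberately small stand-in for full-scale pretrained
  topologies; published headline accuracies on the clinical recordings
  are not reproducible without the data and are not targeted.
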