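# gaitattn

Decoding the attentional demands of gait from treadmill-walking EEG.

The package implements a complete, tested analysis pipeline for 32-channel
walking-EEG sessions in which subjects perform four one-minute attention
tasks per run (normal walking / mental arithmetic / video / following
marks) across 8 runs:

1. **Session model** (`gaitattn.session`, `gaitattn.montage`) — 10/10
   montage with position-derived adjacency, segment-annotated sessions in
   µV, a deterministic internal on-disk format (`.npy` + JSON sidecar) and
   an optional EDF importer (`gaitattn.edf`).
2. **Synthetic data** (`gaitattn.simulate`) — sessions with 1/f correlated
   background bounded within ±50 µV, 50 Hz line interference, stride-locked
   low-frequency motion artifacts, frontal blinks, an alternating motor
   alpha rhythm, and a configurable task-dependent band-power gain (the
   class signal), plus out-of-range "broken" channels on demand.
3. **Preprocessing** (`gaitattn.preprocess`) — zero-phase 0.5–100 Hz
   band-pass and 50 Hz notch, amplitude-based bad-channel detection,
   neighbor-mean reconstruction, and MV-threshold standardization (mean of
   per-epoch maxima, L = 1 s; every channel divided by the cross-channel
   mean threshold).
4. **Features** (`gaitattn.features`) — break removal, per-task 1 s epochs
   with 0.5 s step (120 epochs per 60 s task; 3840 per session), Burg
   maximum-entropy spectra at 1–100 Hz (order 16), and six band-power
   feature sets (δ, θ, α, β, γ_low, γ_high; 32 features each).
5. **Band selection** (`gaitattn.bands`) — Gaussian Bhattacharyya distances
   for all six task pairs per band (shrinkage-regularized covariances) and
   the inclusive ≥ 3.5 selection criterion.
6. **Classification** (`gaitattn.classify`) — RBF SVM (C=512, width 0.002),
   Gaussian naive Bayes, LDA, 30-NN and a decision tree, cross-validated
   run-wise (each of the 8 runs is one test fold).
7. **Evaluation** (`gaitattn.evaluation`) — adjusted-Wald finite-sample
   chance-level ranges, comparison of fold-wise success rates against
   chance vectors, and Bonferroni-corrected Wilcoxon rank-sum tables.

## CLI

```sh
gaitattn simulate --config sim.yaml --seed 1 --out session      # or --null
gaitattn preprocess --in session.json --out std --report rep.json
gaitattn features --in std.json --order 16 --out features.csv
gaitattn bdist --features features.csv --threshold 3.5 --out table.csv
gaitattn classify --features features.csv --out results.csv
gaitattn chance --n 960 --xbar 0.25 --alpha 0.05
gaitattn report --results results.csv --n 480 --out report_dir
```

`sim.yaml` mirrors `SimConfig`; `class_gain` is given per task as a list of
`{band, region, gain}` entries.

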