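# gaitgpm

Gait-phase related EEG power modulations (GPMs) from mobile recordings:
a tested, reusable pipeline for a 2×2 terrain × task overground-walking
design, exercisable end-to-end on synthetic data with known ground truth.

Stages:

1. **synthetic** — accelerometer + EEG study generation (planted gait
   events, gait-phase-locked band power, double-support EMG bursts, 50 Hz
   line noise, blinks, standing baseline) with a ground-truth manifest.
2. **gait** — step-marker / heel-strike / toe-off detection from foot-worn
   accelerometry, plausibility-filtered gait cycles, stride time and
   stride-time CV.
3. **preprocess** — resample + zero-phase FIR band-pass, bad-channel rules
   (flatline / neighbour correlation / line-noise ratio), spherical-spline
   interpolation, full-rank common average reference, sliding-window line
   noise removal, FastICA-based eye-component rejection. Burst correction
   is a pluggable hook.
4. **timefreq** — Morlet decomposition (2–60 Hz in 2 Hz steps), gait-cycle
   extraction with a 350 μV gate, linear warping to 100 phase bins, dB
   baselining against standing, and GPM derivation (zero mean across phase
   per frequency).
5. **spca** — spectral PCA: remove the single largest-eigenvalue spectral
   component from the subject's all-condition average ERSP; apply the same
   projector to condition ERSPs.
6. **footprint** — five-feature gait-artifact footprint (B–F) and the
   Euclidean distance between pre-/post-cleaning vectors.
7. **stats** — 2×2 within-subject ANOVA / Wilcoxon / paired Cohen's dz /
   Holm correction, and cluster-based dependent-samples permutation tests
   (main effects + interaction via paired differences).
8. **pipeline / cli** — orchestration with provenance and seeds.

## CLI

```bash
# generate a synthetic study (BrainVision triplets, accel TSVs, manifest)
gaitgpm simulate --spec spec.yaml --out study/ --seed 1

# gait events + stride metrics for every recording in a study directory
gaitgpm gait --in study/ --out gait_out/

# full pipeline from one YAML config
gaitgpm run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
out_root: results
seed: 1
analysis_channel: Cz
input_layout: synthetic      # or bids-like with input_dir: study/
study: {n_subjects: 6, walking_s: 60.0, standing_s: 60.0}
gait_params: {}
preproc_params: {}
tf_params: {}
stats_params: {n_permutations: 1000}
```

The results bundle contains `results.json` (cluster tests, ANOVAs,
footprint distances, per-stage provenance), `stride_metrics.csv` and
`footprint.csv`.

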