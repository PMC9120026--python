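# gaitsep

**Where does subject identity live in walking signals?**

People can be told apart by how they walk — but *which* components of a
walking signal actually carry that identity? `gaitsep` is a toolkit for
dissecting gait biometrics spectrally: it separates the contribution of a
signal's DC bias (body dimensions for marker trajectories, gravity for
accelerations), of the gait-cycle harmonic series (steps, flexion/extension
events), and of the intra-harmonic 6–10 Hz band (muscle vibration, impact
transients) to how separable individuals are, in both *identification*
(cluster subjects) and *verification* (decide whether two samples come from
the same person) setups.

It is aimed at gait-biometrics and biomechanics researchers who want an
interpretable, fully reproducible pipeline rather than an end-to-end
accuracy number.

## The model

A walking trial is a sampled signal `x[n] = X(nT)` whose vertical (z) axis
is modelled as a Fourier series plus identity-band components and noise:

```
z[n] = DC + Σ_m a_m cos(2π m F n/Fs + φ_m) + Σ_b c_b cos(2π f_b n/Fs + ψ_b) + ε[n]
```

with gait fundamental `F ≈ 1 Hz` (cycle rate), harmonics at `mF`, and
subject-specific components at `f_b ∈ [6, 10]` Hz. Per-frame features are
the unnormalized DFT magnitudes over nonnegative frequencies,

```
fv = ( |X[k]| )_{k=0..N/2},   X[k] = Σ_{n=0}^{N-1} x[n] e^{-i 2πkn/N},
```

computed on 256-sample windows with 75 % overlap. Verification combines
two frame features `a, b` into the order-independent pair vector
`(|a − b|, |a ⊙ b|)`, labelled *same* (cross-day, one subject) or
*different* (two subjects of the same fold), and a supervised UMAP fitted
on the training subjects places pairs of held-out subjects without refit.
Separability is scored with the silhouette coefficient and a
between/within centroid-distance ratio, both in the 2-D embedding and in
the original feature space.

The synthetic cohort generator (`gaitsep.synthetic`) injects identity into
three controllable channels — DC offset, harmonic magnitude profile, and
the 6–10 Hz band — so each claim can be tested with identity confined to a
known channel (`gaitsep.pipeline.fixture_cohort`).

## Worked example

Six synthetic subjects whose identity lives *only* in their DC offset
(marker height), projected with UMAP before and after the pole-zero DC
notch:

```bash
cat > example.yaml <<EOF
fixture: dc_identity
n_subjects: 6
trials_per_day: 2
duration: 15.0
filter_variants: [raw, notch]
modes: [identification]
seed: 42
EOF
gaitsep report --config example.yaml --out report/
```

prints

```
source filter           mode fold  n_points  silhouette  centroid_ratio  feature_silhouette
   fle    raw identification  all       600       0.433           2.507               0.921
   fle  notch identification  all       600      -0.085           0.713              -0.071
```

Read: with the DC bin present, the 600 frames cluster by subject
(feature-space silhouette 0.92; the 2-D embedding keeps silhouette 0.43
across six clusters). Removing the 0 Hz component with the notch erases
subject separability entirely (silhouette ≈ 0) — identification was riding
on body dimensions, not on gait dynamics. Scatter plots for each grid cell
are written next to `report/scores.csv`.

The same grid runs with `modes: [verification]` and the full filter
ablation (`lp3/lp6/lp10`, `hp3/hp6/hp10`, `bp6_10`); with identity
injected in the 6–10 Hz band, the band-pass cell scores highest on the
held-out fold.

## Library layout

| module | contents |
| --- | --- |
| `gaitsep.synthetic` | `SubjectProfile`, `make_cohort`, `synthesize_trial`, `write_dataset` |
| `gaitsep.signal_io` | session CSV dialect, `read_session`, `frame_signal` (256/75 %) |
| `gaitsep.spectral` | `dft_magnitudes`, `to_decibels`, `estimate_fundamental` (autocorrelation), `harmonic_features`, `feature_matrix` |
| `gaitsep.filters` | Butterworth 3/6/10 Hz grid, pole-zero DC notch, `filter_bank` |
| `gaitsep.pairing` | `make_pair`, `sample_pairs`, `split_subjects`, `verification_pairs` |
| `gaitsep.separability` | `project_unsupervised` / `project_supervised` (UMAP), `separability_score`, `run_experiment` |
| `gaitsep.pipeline` | `ExperimentConfig`, `fixture_cohort`, `benchmark_records`, `derive_frequency_bounds` |

A loader hook for real capture data exists: any directory of session CSV
files (one JSON metadata comment line, then `time_s,x,y,z` rows) can be fed
to the same grid via `dataset_dir` in the config; acquiring such data is up
to the user.

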