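# Methods

## Signal model and what the generator emulates

Each synthetic subject is a parameter bundle (`SubjectProfile`) from which
trials are rendered as

```
z[n] = DC + Σ_{m=1}^{M} a_m cos(2π m f0 (n/Fs + τ) + φ_m + ε_m)
     + Σ_b c_b cos(2π f_b n/Fs + ψ_b) + w[n]
```

* **DC** — trajectory offset in mm, drawn per subject from U(420, 560)
  (the span of a knee-height landmark across adults); for acceleration
  trials it is standard gravity (9.80665 m/s²) for *every* subject, so the
  acceleration DC deliberately carries no identity.
* **Fundamental `f0`** — per-subject mean from U(0.8, 1.2) Hz, hard-bounded
  to [0.5, 1.25] Hz (people step at up to ~2.5 Hz, so full gait cycles
  repeat at up to ~1.25 Hz). Each trial redraws `f0` with SD 0.02 Hz so
  same-subject material from different days is similar but never identical.
* **Harmonics** — M = 10 magnitudes `a_m = a_1 · 0.55^(m−1) · e^N(0, 0.15)`
  with `a_1 ~ N(30, 3)` mm, i.e. a ~60 mm peak-to-peak main cycle. The
  geometric ratio 0.55 was calibrated against the displacement ladder of
  real leg-marker trajectories: ≈60 mm for the full cycle, ≈20 mm of
  content above 3 Hz, only ≈4 mm above 6 Hz. (A ratio of 0.6 leaves ≈31 mm
  above 3 Hz and ≈7 mm above 6 Hz — too much residual gait-cycle energy at
  high frequencies.) The per-subject lognormal jitter makes the harmonic
  *profile* an identity channel. Phases are fixed per subject; each trial
  adds a random global time offset τ and small per-component phase jitter
  (SD 0.1 rad).
* **Identity band** — two components per subject at fixed frequencies
  drawn from U(6, 10) Hz with magnitudes U(1, 2) mm (~2–4 mm peak-to-peak),
  emulating the stable, subject-specific intra-harmonic content (muscle
  vibration, impact transients) that is unrelated to the gait-cycle series.
* **Noise** — white noise high-passed at 10 Hz (4th-order Butterworth),
  scaled to 0.5 mm SD for trajectories, emulating marker/calibration noise
  whose energy sits above the band of interest. Acceleration noise is 0.4
  of that value in m/s² (MCU accelerometers are noisier than optical
  capture). Acceleration amplitudes follow the second derivative of the
  displacement model: a cosine of amplitude A mm at f Hz contributes
  `A·(2πf)²/1000` m/s².

Sampling defaults to 120 Hz (a common optical-capture rate, comfortably
above twice the 10 Hz band edge); real capture systems vary and the rate is
configurable everywhere.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: joint kinematics and double-support timing,
within-trial cadence drift (harmonic peaks here are sharper than in real
spectra), occlusion/gap-fill artefacts, soft-tissue marker slip, cross-axis
coupling (x/y are low-amplitude correlates kept only for file-format
completeness), and population diversity beyond the parameter ranges above.
Directional conclusions transfer; absolute separability values do not.

## Processing pipeline

Filtering is applied to whole trials *before* framing, with causal
single-pass (`lfilter`) filters initialized at steady state for the first
sample's level; without that initialization the ~480 mm DC step at trial
start rings through the notch for several hundred samples and contaminates
the early frames of short trials. The ablation grid composes every
Butterworth variant (low/high-pass at 3, 6, 10 Hz; band-pass 6–10 Hz;
order 4, a common biomechanics choice) with the DC notch. The notch is a
first-order pole-zero design, zero at z = 1 and pole at r = 0.99,
normalized to unit gain at Nyquist; its response at 1 Hz is 0.982, so the
gait band is essentially untouched. A wider notch (r = 0.95) would already
cost ~28 % of a 1 Hz component's amplitude at 120 Hz, which is why r ≥ 0.99
is the default and the narrowness contract is asserted there.

Frames are 256 samples with 75 % overlap (hop 64); trailing samples that
do not fill a window are discarded, and windows never span trial
boundaries. Features are unnormalized half-spectrum DFT magnitudes (129
values per frame at N = 256); decibel views use 20·log10 with a 1e-12
floor and reference 1 source unit.

The fundamental-frequency estimator scans the mean-removed signal's
normalized autocorrelation over every lag inside the search band (default
0.5–2.5 Hz) and returns Fs/lag of the maximum. Every harmonic of a
periodic signal contributes positively at the full-period lag, so the scan
prefers the true period over a strong harmonic's shorter one; the biased
(taper-weighted) estimator breaks the tie between a period and its
multiples toward the shorter lag. Signals shorter than two periods of the
band's low edge are rejected, and a best correlation under the voicing
threshold (default 0.3) raises a no-periodicity error. Resolution is one
lag quantum, ≈ f0²/Fs ≈ 0.008 Hz near 1 Hz at 120 Hz. Harmonic feature
vectors are 11-dimensional — the fundamental followed by the magnitudes of
its first 10 harmonics, each read as the local maximum within ±1 bin of
`m·f0` to absorb off-bin leakage.

Verification pairs concatenate `|a − b|` and `|a ⊙ b|`; on nonnegative
magnitude features the modulus on the product changes nothing
(property-tested). Same-subject pairs cross acquisition days; different-
subject pairs combine frames only within one fold of the subject-disjoint
split (default 13 train / 12 test of a 25-subject cohort), so no fold's
pairs ever touch the other fold's subjects. Exhaustive pairing is
combinatorial, so experiments draw a seeded, duplicate-free subsample
(default cap 5000 per class; the bundled experiments use 400–1200).

Projections use UMAP with the library's documented defaults (15
neighbors, min_dist 0.1, Euclidean, fixed seed); supervised projections
fit on the training fold with the same/different target and place test
points by the fitted transform only. Separability is quantified (the
visual judgement of scatter plots made explicit) by the silhouette
coefficient plus a between/within centroid-distance ratio, computed both
in the embedding and in the original feature space; singleton classes are
excluded with a warning.

## Benchmark scale and interpretation of the generalization check

The default synthetic benchmark is 25 subjects × 2 days × 4 trials/day ×
20 s — the full experiment grid at this scale runs on one CPU in minutes;
the real protocol's 10 trials/day is a config switch. Fixture cohorts
(≤ 6 subjects, 2 trials/day) confine identity to a single channel
(`dc_identity`, `band_identity`, `harmonics_identity`, or the `null`
negative control).

One measurement subtlety is documented rather than hidden: in a
*supervised* embedding the training fold is warped by the label target
itself, so its silhouette is inflated by construction and the train-vs-test
embedding gap measures supervision strength as much as transfer. The
generalization check therefore compares the projection-free feature-space
silhouettes of the two folds (which agree to ~0.01 on the benchmark —
the pair structure genuinely transfers to held-out subjects) and
additionally requires the test fold of the band-pass embedding to stay
above the label-permutation floor. Relatedly, shuffling the *training*
labels cannot drive the test-fold score all the way to zero — the
transform is label-blind, so residual feature-space structure survives —
which is why the collapse-to-zero permutation control permutes the labels
used for *scoring*.

## Numerical choices and degenerate inputs

* DFT convention: unnormalized sums (no 1/N), guarded by a Parseval check
  and a brute-force O(N²) oracle at 1e-9.
* Peak scanning for worked examples ignores local maxima below 1e-6 of the
  spectrum's largest non-DC magnitude (the numerical noise floor of an
  otherwise clean spectrum).
* Session CSVs store 12 significant digits; write→read round trips agree
  to 1e-9 absolute. Malformed rows are rejected with the offending line
  number, never skipped.
* Filter stability is verified at design time (all poles strictly inside
  the unit circle); cutoffs at or above Nyquist are rejected.
* Constant signals raise a no-periodicity error in F0 estimation; empty
  trial plans write zero files; an empty experiment grid reports an empty
  table and exits successfully.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit keys (cohort seed; per-trial keys derived from subject, day,
  trial and source), so every artefact — cohorts, trials, splits, pair
  subsamples, embeddings — is reproducible bit-for-bit under a fixed seed.

## Known limitations

* The pure-cosine comb makes frame spectra hypersensitive to the fractional
  bin position of `f0`; real spectra have broader lobes. This raises
  intra-subject frame variability at harmonic bins relative to real data.
* Absolute silhouette values depend on cohort scale and pair caps; only
  directions and gaps are asserted.
* UMAP determinism holds for a fixed seed and library version; coordinates
  are not comparable across versions.
* The 6–10 Hz identity band is modelled as fixed discrete components;
  amplitude-modulated or stochastic band content would weaken band-pass
  verification below what these tests show.
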