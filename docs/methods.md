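# Methods

## The microstate model

Resting and task EEG topographies do not vary continuously: for stretches of
tens of milliseconds the scalp potential field keeps one quasi-stable spatial
configuration, then switches abruptly to another. Four canonical
configurations — A (diagonal left-posterior to right-anterior gradient), B
(its left–right mirror), C (anterior–posterior gradient), and D (radial
fronto-central maximum) — recur across subjects and paradigms. This package
segments multichannel EEG into such microstates and compares their temporal
statistics between experimental arms: an *imagery* arm with three conditions
(rest, left-side imagery, right-side imagery) and a *needling* arm with two
(rest, real needling).

The analysis chain is:

1. **Preprocessing** — zero-phase Hamming-window FIR band-pass (default
   1–45 Hz), optional ICA-based artifact removal, average reference,
   polyphase resampling (default 200 Hz).
2. **GFP-peak extraction** — global field power
   `GFP(t) = sqrt(sum_i (v_i(t) − v̄(t))² / n)` is the spatial SD of the
   average-referenced map; its strict local maxima are the highest-SNR
   topographies and form the clustering input.
3. **Polarity-invariant modified k-means** — map `x` is assigned to the
   template `m_k` maximising `(x·m_k)²` (a map and its negation are the same
   state); templates update to the dominant eigenvector of the within-class
   scatter `Σ x xᵀ`. The objective, global explained variance
   `GEV = Σ_t (x_t·m_{L(t)})² / Σ_t ‖x_t‖²`, is non-decreasing per iteration;
   the best of `n_restarts` seeded random initialisations is kept.
4. **Model order** — for each K in 4..8 the predictive-residual criterion
   `CV(K) = σ̂²·((C−1)/(C−1−K))²` with
   `σ̂² = Σ_t (x_t·x_t − (x_t·m_{L(t)})²)/(N(C−1))` is evaluated on the peak
   maps (C channels, N maps); the K with the lowest CV wins, ties to the
   smaller K.
5. **Canonical labelling** — a Hungarian assignment maximising total
   |spatial correlation| against analytic A–D reference maps.
6. **Backfitting** — every sample of the full record takes the class of
   largest |spatial correlation|; ties go to the incumbent label, flat
   samples inherit their predecessor.
7. **Temporal parameters** — per class: coverage (fraction of samples),
   occurrence (runs/s), mean duration (ms over interior runs; the censored
   first and last run of an epoch are excluded from duration but counted in
   coverage and occurrence), and the first-order transition matrix
   conditional on leaving (zero diagonal; rows without a successor are
   flagged undefined, never imputed).
8. **Group statistics** — within the imagery arm a one-way ANOVA across the
   three conditions with Tukey–Kramer post-hocs (run only when the omnibus
   rejects); within the needling arm paired t-tests; between arms a pooled
   two-sample t on OLS residuals after regressing out age, sex, and the
   subject's resting value of the same parameter (no group term in the
   regression, so a true group difference is not absorbed). Cohen's d
   accompanies every comparison; Benjamini–Hochberg FDR is applied within
   each comparison-block × parameter-panel family (coverage / occurrence /
   duration / transitions), and a sign summary reports ↗/↘/— per parameter
   at FDR < 0.05.

## Synthetic ground truth

Because every stage needs a known answer, the generator plants microstate
structure explicitly. Labels follow a semi-Markov chain: gamma segment
durations (shape 4, class mean default 80 ms — positive, right-skewed,
spanning the tens-of-ms regime) and a zero-diagonal row-stochastic transition
matrix (default uniform). Each segment renders as
`sign × envelope × template + noise`:

* `sign` is a per-segment Bernoulli(½) polarity flip, so polarity invariance
  is genuinely exercised;
* `envelope` is a rectified 10 Hz sine (alpha regime), giving GFP peaks
  roughly every 50 ms;
* `noise` is spatially smoothed (Gaussian kernel over the montage),
  band-limited (1–45 Hz) 1/f Gaussian noise, average-referenced and scaled so
  the realised signal-to-noise power ratio equals `snr_db` exactly (default
  10 dB). A 1/f spectrum was chosen over white noise because band-passed
  resting EEG concentrates power at low frequencies; temporally white noise
  at 200 Hz would put most power above 20 Hz and misrepresent the spectral
  structure every artifact classifier relies on.

Condition effects are parameterised, not hard-coded: per condition, duration
means can be scaled per class and incoming transition mass added toward a
class (rows renormalised). The bundled preset raises class-A duration
(×1.45 imagery, ×1.25 needling) and incoming-A transition mass (+0.12 /
+0.08), planting the qualitative pattern "class-A coverage and duration rise
under both imagery and needling, imagery slightly stronger". Subjects get
lognormal (σ = 0.05) per-class duration jitter; ages and sex ratios follow
the cohort demographics being emulated (imagery arm 21.7 ± 1.12 years,
11:19 m:f; needling arm 21.5 ± 2.40, 8:12). All randomness derives from one
master seed through `numpy` seed sequences, so a cohort is bit-reproducible.

What the generator does **not** emulate: biophysical forward modelling
(no head model or dipole sources), realistic ocular/myogenic waveforms
(artifact handling is tested with separately crafted contaminants),
non-stationarity, bad channels, or line noise. Passing tests therefore
demonstrate correctness of the algorithms under the planted model, not
performance on real recordings.

## Numerical choices

* **Clustering** operates on average-referenced peak maps without unit-norm
  scaling; with unit-norm templates the GEV above is algebraically the
  GFP²-weighted mean squared spatial correlation, so amplitude enters only
  through the standard GFP weighting. Empty clusters are re-seeded from the
  worst-fit map. Convergence: relative GEV change < 1e-7 (default), max 500
  iterations, 50 restarts.
* **Peak-map subsampling**: pooled cohorts yield tens of thousands of GFP
  peaks; fits subsample to `max_peak_maps` (default 4000) maps drawn from
  the run seed. The CV curve is insensitive to this at the sizes used.
* **GFP peak plateaus** count once, at their first sample. Backfit ties go
  to the previous sample's label (else the lowest class index); flat (zero
  variance) samples inherit the previous label, leading flats take the first
  non-flat label. Temporal smoothing is off by default
  (`smoothing_min_samples = 0`); when enabled, runs shorter than the minimum
  are absorbed into the neighbouring class with the higher mean correlation.
* **Filter design**: Hamming-window FIR, transition width 1 Hz (which sets
  the length, ~3.3·fs taps), applied forward–backward so segment boundaries
  are not delayed. Band edges must sit below Nyquist.
* **ICA artifact removal**: FastICA on the numerical-rank-truncated data
  (average-referenced EEG is rank n−1). The formal FastICA stopping rule
  rarely triggers on EEG-like data — any near-Gaussian subspace has no
  preferred rotation — so the iteration cap (2000) is the normal exit and
  only a degenerate (non-finite) decomposition is an error. Ocular
  components are flagged by Higuchi fractal dimension < 1.4 computed on the
  component decimated to ~25 Hz (at the raw rate, trace broadband leakage
  dominates the curve length of an otherwise smooth component) together with
  dominant < 3 Hz power; myogenic components by > 60% of power above 20 Hz.
  Flagged components are zeroed, not attenuated. Thresholds are
  config-exposed; `passthrough` is the default for synthetic pipelines.
* **Statistics**: pooled-variance two-sample t (the published demographic t
  matches the pooled form); chi-square without continuity correction (ditto
  the published 0.057); Tukey–Kramer via the studentized-range distribution
  in its unequal-n form. Cells with missing values (fully censored
  durations, undefined transition rows) are dropped from the affected
  comparison, never imputed as zero.

## Problem sizes used in validation

The automated checks run at sizes chosen to exercise the full chain with
comfortable statistical margins: cluster-number selection on cohorts of 6
subjects × 3 conditions × 60 s (10 seeds); parameter recovery on 4-minute
epochs (10 seeds); statistical calibration on 500 label-simulated null
cohorts of 6 + 5 subjects with 20-s epochs; directional recovery on 10 full
EEG cohorts of 8 + 8 subjects with 60 s per condition. The brute-force
clustering oracle enumerates all 2^19 polarity-invariant two-part partitions
of 20 maps.

## Known limitations

* Group-level clustering pools GFP peaks across *all* subjects and
  conditions and fits once; a per-subject clustering pass with map-level
  aggregation is not implemented (the group model is backfit to every
  subject).
* Sample-wise backfitting at moderate SNR fragments runs near the nulls of
  the GFP envelope, biasing raw durations downward; duration *contrasts*
  between conditions survive (the directional tests pass at 10 dB), but
  absolute backfit durations should be interpreted cautiously or smoothed.
* The within-imagery ANOVA treats the three conditions as independent
  groups, as specified for the study design it mirrors, although they are
  within-subject; with shared subject-level variation this is conservative.
* Transition probabilities are first-order and conditional on leaving;
  no higher-order syntax, entropy, or scale-free measures.
* EDF support covers reading (and a minimal 16-bit writer); no other vendor
  formats, no streaming, no channel interpolation, no source localisation.
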