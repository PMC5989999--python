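# Methods

`eegdyn` quantifies the *dynamics* of network states in short multichannel
EEG segments — how channel-to-channel correlation patterns and band-power
distributions switch, recur and persist over time — and uses those
quantities to test for nonstationarity and to separate electroclinical
phenotypes. This note documents the model, the tunable parameters, the
synthetic data, and the numerical choices, in the package's own terms.

## Dynamics matrices

A 10-s segment sampled at rate `fs` is average-referenced and band-filtered
into six bands (broadband 0.1–60 Hz, delta 1–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–60; zero-phase Butterworth of order 4 applied
forward–backward). A 2-s window slides from 0 to 8 s; with step `s` samples
there are `k = floor(8·fs/s) + 1` windows (both endpoints included; 4097 at
512 Hz and unit step).

For each window two vectors are formed:

- the **correlation pattern**: the `n(n−1)/2` upper-triangle entries
  (row-major) of the `n×n` Pearson correlation matrix of the channels
  within the window;
- the **power distribution**: the per-channel mean of the squared
  band-limited signal (time-domain band power, not PSD integration).

Correlating every pair of window vectors (zero-lag Pearson across the
vector elements) yields the `k×k` **correlation dynamics matrix (CDM)**
and **power dynamics matrix (PDM)**. Both are symmetric with unit diagonal
and entries in [−1, 1]. Blocks of high values away from the diagonal mean
the corresponding network state *recurs*; a matrix whose high values hug
the diagonal indicates no persistent states. The scalar
`mean(CDM − PDM)` summarizes whether correlation states (positive) or
power states (negative) recur more strongly.

Degenerate cases: a channel constant within a window, or a constant window
vector, has undefined correlations; these map to 0, are counted, and the
count is logged. Degeneracy is detected with a relative variance floor
(variance ≤ 1e−20 × raw energy) because exact-zero tests miss float
cancellation residue.

## Matrix measures

Each dynamics matrix `f(x, y)` is summarized by three image-style scalars:

- **mean** `Σ f / k²` (diagonal included);
- **contrast** `Σ (f(x,y) − f(x+1,y+1))²` over in-bounds pairs — the
  squared difference along the diagonal-neighbor direction;
- **sharpness** (Brenner operator)
  `Σ (f(x+2,y) − f(x,y))² + Σ (f(x,y+2) − f(x,y))²` — squared two-step
  differences along both axes, sensitive to how abruptly the matrix
  switches between correlated blocks.

Sums run over in-bounds indices only (no padding; an optional zero-padding
flag exists but is off by default), on raw matrix values without
per-matrix normalization. Contrast and sharpness are translation-invariant
and scale quadratically with amplitude; both are strongly suppressed by
smoothing, and respond to it non-proportionally. An optional
normalize-by-count flag divides by the number of summed terms for
mixed-`fs` cohorts, where `k` differs.

With 3 measures × 2 matrix kinds × 6 bands, each segment yields 36 named
values in a fixed canonical order (`cdm_sharpness_alpha`, …).

## Surrogate-based nonstationarity testing

The null hypothesis is that a measure reflects only stationary
fluctuations around the segment's average spectral and cross-correlation
composition. Surrogates are built by a multivariate iterative
amplitude-adjusted Fourier transform (IAAFT): the initial surrogate adds a
common random phase increment to every channel (preserving all
between-channel phase differences and hence the cross-spectrum exactly),
then iterations alternate per-channel rank-ordered amplitude restoration
with a spectral step. For the first 10 iterations the spectral step
rotates the original phase pattern by a common per-frequency angle (the
amplitude-weighted circular mean closest to the current phases), keeping
the cross-spectrum exact; afterwards per-channel phases refine freely from
that cross-spectrum-preserving solution, which lets the spectra converge
(relative spectral error ~0.2% on stationary inputs; tolerance 1e−4, cap
100 iterations, both configurable). Final step is always amplitude
restoration, so each surrogate preserves each channel's exact sample
multiset. On stationary controls the zero-lag cross-correlations are
reproduced within ~0.015.

Each of (by default) 100 surrogates per segment runs through the identical
windows + measures pipeline; the empirical measure is z-scored against the
ensemble mean and SD (ddof 1; zero SD flags the measure undefined rather
than returning ±inf). Values inside roughly [−1.96, 1.96] are consistent
with stationarity. The deviation test is two-sided: strongly *negative*
z-scores are equally incompatible with the stationary null. For
state-switching signals the CDM mean in particular deviates negatively —
a stationary surrogate carries the time-averaged ("blended") correlation
pattern in every window and therefore correlates window-to-window at
least as strongly as a process that genuinely switches between patterns;
the switching shows up instead as large positive contrast and sharpness
deviations together with the negative mean deviation.

Group statistics: a two-sided one-sample t test of mean-zero on sets of
z-scores, and a balanced split-plot (mixed between-within) ANOVA for group
differences with repeated segments per subject, reporting the
between-subjects F with (J−1, N_subjects−J) degrees of freedom. The ANOVA
is computed by `pingouin.mixed_anova` and cross-checked in the test suite
against the closed-form sums-of-squares for balanced designs. Unbalanced
designs and single-repeat designs are rejected explicitly.

## Phenotype clustering

Each of the 36 measures is scored by how well two thresholds `t1 ≤ t2`
(three half-open, lower-inclusive bins) partition the labeled segments,
measured by purity `P = (1/N) Σ_k max_j |ω_k ∩ c_j|`. The threshold pair
is optimized by simulated annealing: initialization at the 33rd/67th
percentiles, geometric cooling (T0 = 1, factor 0.95), 2000 iterations,
Metropolis acceptance `exp(Δ/T)`, and a proposal mixture of 70% local
Gaussian steps (σ = 0.1 × value range), 20% single-threshold jumps to a
random inter-value midpoint and 10% joint two-threshold jumps — purity is
piecewise constant with breakpoints at the data values, so midpoint jumps
let the chain reach any solution cell. Three chains run per measure (the
first from the percentile initialization, the rest from random pairs) and
the best pair ever visited is returned; on instances of ≤ 50 segments the
result matches exhaustive midpoint-grid search in all stress tests.

The 36 measures are ranked by achieved purity (ties broken by canonical
name order). For r = 1…20, k-means (squared Euclidean, per-column
standardized features, best of 100 seeded restarts) clusters the segments
on the top-r measures; each clustering is scored by purity and, after
mapping each cluster to its majority class (ties resolved toward
abnormal, logged), by the sensitivity and specificity of separating
normal from abnormal segments.

## Synthetic data

The generator produces the study conditions for every test; it emulates
qualitative electroclinical phenomenology, not biophysics. All signals are
1/f pink noise mixtures (spectral slope 1, flattened below 0.5 Hz),
scaled to a 20–60 µV RMS background, zero-mean per channel, written as
16-bit EDF with 10–20 labels. Everything is deterministic given a seed; a
separate `structure_seed` fixes subject-level architecture (pattern
libraries, channel gains) so that several segments of one simulated
subject share their latent structure.

- **stationary_control** — one fixed weak cross-covariance pattern
  (shared-source variance fraction 0.08, three shared sources),
  lognormal channel gains (σ = 0.25) giving the heterogeneous power
  profile needed for a realistic PDM. Strictly stationary: the reference
  condition for z-score calibration.
- **normal** — slowly drifting correlation states: four patterns drawn as
  perturbations of one base (drift 0.35), coupling 0.30, exponential
  dwells (mean 2.5 s) crossfaded over (1 − transition_sharpness) ×
  dwell-mean seconds (fades centered on state boundaries), gains σ = 0.5.
  Power states recur more than correlation states, so mean(CDM − PDM) is
  negative.
- **burst_suppression** — near-synchronous generalized discharges on a
  suppressed background (amplitude gain 4, suppression level 0.2, ~0.8
  bursts/s of ~1 s): each burst carries a common pink-noise transient
  with signed per-channel weights from one of four scalp polarity
  patterns, and bursts cycle the library in shuffled balanced order, so
  patterns recur across the segment while the time-averaged
  cross-correlation stays weak. Per-burst weight jitter (0.4) and slow
  per-channel amplitude modulation (lognormal σ = 0.35, < ~0.5 Hz)
  decorrelate the band-power vectors without disturbing within-window
  correlations, giving the positive CDM − PDM difference.
- **hypsarrhythmia** — persistent chaotic high-amplitude activity: four
  independent strong patterns (coupling 0.9), exponential dwells (mean
  2 s), base amplitude 60 µV, slow per-channel amplitude modulation
  (σ = 0.5).

What the generator does **not** contain: real spike/sharp-wave
morphology, sleep architecture, artifacts, volume conduction, focal
topographies, or any claim about the true spectral content of
hypsarrhythmia. Passing tests therefore demonstrate that the *method*
behaves as designed on signals with known state structure — not that the
clinical effect sizes of real recordings are reproduced.

## Problem sizes and runtime choices

The package's full-resolution profile follows the canonical analysis
(512 Hz, unit window step, 100 surrogates per segment). The test suite and
the acceptance script run a desk-scale version of the same computations:
256 Hz, 10-s segments, window step 16 samples (k = 129) for the surrogate
analyses and step 8 (k = 257) for the clustering stage, with 20
surrogates per segment. The measures are defined identically at any step;
coarser steps subsample the same dynamics matrix. Group recovery by
ranking + k-means benefits from the finer matrix texture, hence the finer
step there; surrogate deviations for burst suppression exceed |z| = 12
already at step 16.

## Known limitations

- Surrogate ensembles of 20 make the z-scores t-distributed rather than
  normal; the calibration criterion (≥ 90% of control z-scores inside
  ±1.96) accounts for this.
- The IAAFT spectral tolerance of 1e−4 is rarely reached within 100
  iterations; the practical plateau (~0.2% relative spectral error) is
  well inside the 1% contract verified by the tests.
- Purity is reported on the same labeled segments used to pick thresholds
  and feature subsets; as an intentionally in-sample description of class
  separation it must not be read as diagnostic accuracy. Subject ids are
  carried through the pipeline so leave-one-subject-out designs remain
  possible.
- Segments of one simulated subject share latent structure and are not
  independent samples, mirroring the repeated-measures structure of the
  underlying study design.
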