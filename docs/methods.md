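# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `tcdflow`.

## Beat preprocessing

**Segmentation.** Beats are cut at the foot of the systolic upstroke.
Candidate upstrokes are maxima of the first difference of a lightly smoothed
(~40 ms Hanning) copy of the signal, spaced at least 0.1 s apart and
exceeding 0.3× the 99th percentile of positive differences — a percentile
(not the maximum) so that a single 3× amplitude-spike artifact cannot raise
the threshold above genuine upstrokes.  Each candidate is walked back to the
local minimum preceding it (at most 0.25 s).  Two guards make the foot
detection robust to multi-peaked beats: a candidate whose signal value
exceeds a robust diastolic level (p5 + 0.35·(p95 − p5) of the smoothed
signal) is discarded — rises off inter-peak troughs start much higher than a
true foot — and candidate feet within one refractory period (0.3 s) merge to
the lowest-valued one.  Beats run from one onset to the next; the tail after
the last onset is kept as a final beat when at least 0.3 s long.  A constant
or pulseless recording yields zero beats and is skipped, not raised.

**Artifact rejection.** Iterated Tukey fences (`Q1 − 1.5·IQR,
Q3 + 1.5·IQR`) on two comparators: beat length, and the maximum over lags of
the normalized cross-correlation between each beat and the ensemble mean
(both end-padded to a common length and z-scored; a constant beat scores 0).
Rejection iterates to a fixed point and never shrinks the ensemble below 3
beats.  The fence half-width has a floor at the comparator's resolution —
0.01 in correlation, max(2 samples, 2% of the median) in length — because on
nearly homogeneous ensembles the IQR collapses to numerical noise and
unfloored fences cascade, discarding most of a perfectly good ensemble.  The
multiplier 1.5 and both floors are arguments of `reject_outliers`.

**Averaging and normalization.** Accepted beats are aligned at their onsets,
each end-padded with its own final value to the longest beat's length, and
averaged element-wise.  The average is then (1) polyphase-resampled
400 → 125 Hz when acquired at 400 Hz (ratio 5/16); (2) smoothed with a
unit-sum Hanning window of 90 ms at 125 Hz, rounded to the nearest odd
length (11 samples) so alignment is preserved, edges reflected; (3)
velocity-normalized by subtracting the minimum and dividing by the resulting
maximum; (4) time-normalized by cubic-spline resampling to exactly 100
samples.  Because a cubic spline can overshoot its data, the min–max rescale
is applied once more after step (4), so every normalized beat attains 0 and
1 exactly.  Recordings with fewer than 15 accepted beats are excluded, as
are all waveforms of subjects lacking at least one qualifying recording
(depth 45–60 mm, ≥15 beats) in *each* hemisphere.

## Morphological features

`onset` is the index of the waveform maximum (0-based, 0..99; ties go to the
earliest index, consistent with "onset of maximal velocity").  `canopy`
counts samples strictly above `x(t_0) + 0.25·(max − min)`; the first sample
is the baseline even though min-normalization may place the global minimum
elsewhere — the printed defining equation is followed verbatim.  `peaks`
uses the forward difference `d_k = x(t_k) − x(t_k−1)`.  True peaks/troughs
are canopy samples where `d_k` is non-zero and the next non-zero difference
has the opposite sign (the first sample of a plateau marks the plateau's
extremum); each counts 1.  Pseudo-peaks come from maximal runs of
consecutive canopy samples with `0 < |d_k| <` threshold (default 0.01):
each run containing no true-peak index contributes
`1 − min|d_k|/threshold`, evaluated at the run's smallest-magnitude
difference (earliest on ties).  Runs that contain a true peak are suppressed
to avoid counting the same structure twice, and pseudo-peaks are confined to
the canopy, mirroring the true-peak domain.  A zero difference is never a
pseudo-peak candidate: exact flatness belongs to the true-peak rule.  As the
threshold shrinks to 0, `peaks` converges to the discrete true-peak count.

**Known sensitivity.** The weighted count is not perfectly stable under
resampling: a marginal structure (a shallow P3 dip, or the sample adjacent
to a very sharp spike) can flip between a true-peak pair and a pseudo-peak
when the sampling grid changes, moving the feature by more than one pseudo
weight.  Onset and canopy are grid-stable to ±1 sample.

## Clustering and cluster-count selection

Features are z-scored per column (sample SD, ddof=1; a zero-variance column
is an error naming the column; means/SDs are stored so the transform
inverts exactly).  Clustering is normalized spectral clustering: RBF
affinity `exp(−γ·d²)` with γ = 1 on the z-scored features, symmetric
normalized Laplacian, the first k eigenvectors degree-rescaled and
row-normalized, then k-means with 10 restarts.  The implementation uses a
dense `scipy.linalg.eigh` eigensolver, which at the few-hundred-observation
scale of this analysis runs in tens of milliseconds per fit — essential
because the gap-statistic bootstrap clusters every reference sample at every
k.  It reproduces scikit-learn's `SpectralClustering` labels exactly on
separated data (asserted in the test-suite, where the scikit-learn
implementation serves as an independent cross-check).

Pooled dispersion is `W = Σ_r D_r/(2 n_r)` with `D_r` the sum of squared
Euclidean distances over ordered member pairs of cluster r — algebraically
equal to the within-cluster sum of squared distances to centroids, which the
tests use as an independent closed form.  Reference datasets follow the
covariance-respecting recipe: rotate the data into its right-singular basis,
draw uniformly over each rotated column's observed range, rotate back.  For
each k in 2..7 the observed data and each of B reference draws (default
B = 1000; tests use 50–100) are clustered with the same spectral algorithm;
`G_k = mean_b log W_ref(b,k) − log W_obs(k)` and
`S_k = sd_b(log W_ref)·sqrt(1 + 1/B)`.  The selected k is the smallest with
`G_k > G_{k+1} − S_{k+1}`; if no k in the range satisfies the rule the
largest k is returned with an explicit "no elbow" flag.  All randomness —
reference draws and k-means seeding — derives from a single seed.

Since the k-range starts at 2, a dataset with no cluster structure cannot
map to "one cluster"; in practice a featureless cloud produces a flat gap
curve and the rule fires immediately at the smallest k.

## Archetypes and composition

Distances for ranking are computed on the normalized 100-sample waveforms
(not the 3-feature vectors).  Each member's score is its mean squared
Euclidean distance to the *other* members (self excluded, denominator
n − 1); ties break by id.  The exemplar is the minimum-score member; the
archetype averages the five lowest-score members, or all members when a
cluster has fewer than five.  Composition reports, per cluster, the fraction
of member waveforms from each subject group, both raw and rounded to whole
percent.

## Synthetic waveform generator

Each beat is a sum of skewed-Gaussian bumps (one per peak, separate
left/right widths so upstrokes are faster than decays) plus a broad
diastolic runoff hump, defined on the dimensionless beat phase so shape
scales exactly with beat duration.  Four templates are frozen in
`FLOW_TYPES`:

| type | morphology        | onset phase | canopy | peaks (noise-free) |
|------|-------------------|-------------|--------|--------------------|
| I    | normal            | 0.17        | wide   | ~4–5 (P1>P2>P3)    |
| II   | late-onset        | 0.36        | wide   | ~4 (P2 dominant)   |
| III  | narrow-spike      | 0.18        | narrow | ~1                 |
| IV   | blunted           | 0.52        | wide   | 1                  |

Template parameters were chosen from a numerical analysis of the pipeline's
smoothing: the 90 ms window acts in absolute time, so features narrower than
~0.065 beat-phase units would make the normalized shape depend on heart rate
(a σ = 0.035 peak changes by 0.16 max-abs between 50 and 100 bpm; the
chosen widths keep all types within 0.05).  The type II (late-onset)
morphology is the least constrained by the literature and is this package's
own construction: a dominant mid-systolic peak with a preserved but smaller
P1.

Per-beat durations are i.i.d. truncated-normal from the heart-rate
distribution (default 75 ± 5 bpm, truncated to 40–140).  Per-recording
morphological jitter (peak positions sd 0.01 phase, amplitudes/widths ~5%,
runoff ~10%; `SimConfig.morph_jitter`, default 1) emulates inter-subject
anatomical variability — without it the within-type feature distribution is
quasi-discrete (integer onsets, constant peak counts), a degeneracy real
cohorts do not have.  Artifact beats (default rate 0.05) are flatlines at
the diastolic level (shape outliers) or 3× amplitude spikes (scale
outliers), exercising both rejection comparators.  Additive white noise
defaults to 0.03 of the systolic amplitude (~2.4 cm/s at 80 cm/s).  Default
group mixtures make LVO hemispheres mostly types III/IV and controls mostly
I/II, loosely mirroring reported cohort compositions.  Ground truth (onsets,
artifact flags, flow types) rides along in `RawRecording.ground_truth` and
is never visible to the analysis path.

**What the generator does not emulate.** No Doppler spectrogram or envelope
physics, no intra-recording drift, no respiratory modulation, no depth
dependence of morphology, and — most importantly for the clustering stage —
within-type dispersion driven by a handful of generative parameters rather
than the rich continuum of real physiology.  A consequence worth stating
plainly: on synthetic cohorts the gap statistic tends to *over*-partition,
because splitting the tight, structured within-type clusters keeps reducing
`log W` faster than the uniform reference predicts, so the smallest-k rule
often runs past the planted count.  Cluster-count selection is therefore
validated on its designed harness — isotropic Gaussian clusters
(`generate_feature_cloud`), where the 4-cluster optimum is recovered in
≥ 80% of seeds — while the planted-beat cohorts validate partition recovery
and archetype extraction at the planted cluster count.  Passing tests show
the pipeline's operations are correct; they do not show that real TCD
cohorts would yield exactly four clusters.

## Numerical choices and degenerate inputs

* Sample sizes in tests: 20–30 recordings per flow type, bootstrap B = 50–100,
  240-point feature clouds — chosen so the full suite exercises every path in
  a few minutes.
* Seeds: every stochastic function takes an explicit seed/Generator; the
  model derives stage seeds from one master seed via `SeedSequence`.
* Constant waveforms raise `DegenerateWaveformError` at normalization and
  are excluded with a log entry; constant recordings yield zero beats.
* `spectral_cluster` with k = n returns singletons directly; k-means ties
  are resolved by its seeded restarts.
* Pooled dispersion of a singleton cluster is 0; a cluster id with no
  members is an error.
* Exemplar/archetype ranking on a singleton cluster returns that member; a
  cluster smaller than five averages all members.
* Composition percentages are rounded to whole percent (raw fractions are
  also emitted); rounding may make a row sum to 99 or 101.

## Limitations

* Beat detection is a derivative-threshold foot detector adequate for clean
  and synthetic signals; heavily corrupted clinical recordings would need a
  more robust detector (the interface accepts any beat list).
* The cross-correlation comparator is a stand-in definition (max of
  z-scored, end-padded cross-correlation over all lags); the literature
  method it replaces is not public.
* The canopy baseline `x(t_0)` differs from the diastolic minimum whenever
  the minimum is not at the first sample; the defining equation is followed
  as printed.
* The `peaks` feature's grid sensitivity (above) means borderline
  morphologies can shift by ~1 unit between acquisitions at different heart
  rates.
* Gap-statistic behavior on synthetic cohorts over-partitions (above); the
  no-elbow flag is reported so downstream users can see when the rule never
  fired.
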