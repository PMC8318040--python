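# Methods

## Signal model and preprocessing

Recordings are `channels x samples` voltage matrices in µV with an explicit
sampling rate; samples are 0-based and intervals half-open `[start, end)`.
Preprocessing is deterministic: common-average referencing (an idempotent
linear projection that leaves GFP unchanged), a zero-phase order-4
Butterworth band-pass applied forward-backward (the band, typically
1–35 Hz, is the scientific choice; zero-phase application preserves
microstate timing), integer-factor decimation with an anti-alias FIR
(non-integer resampling is refused rather than silently interpolated, so
the sample-to-time mapping stays exact), and per-channel baseline
subtraction with optional cropping of the baseline interval. Independent
component artifact removal is an upstream responsibility; the toolkit
assumes clean input.

EDF files are read through `mne`; a minimal EDF writer (1-s records, 16-bit
quantization over the value range, µV physical dimension) provides
round-trip fixtures and interchange. Plain TSV matrices with a channel-name
header are the native text format.

## GFP peaks

GFP is the per-sample spatial standard deviation. Peaks are located on a
Gaussian-weighted moving average of the GFP (default window 50 samples,
kernel σ = window/6 so the window spans ±3σ; edge kernels are renormalized
rather than zero-padded to avoid attenuating edge values). The peak rule is
`v[t−1] < v[t] ≥ v[t+1]` with plateaus counted once at their first sample
and endpoints excluded. Maps are taken from the *unsmoothed* data at the
detected indices — smoothing stabilizes peak timing but must not distort
the topographies submitted to clustering. No minimum peak distance or
prominence is imposed by default.

## Dual-threshold AAHC

Peak maps are re-centered to zero channel mean and normalized to unit GFP
for the clustering geometry; their original GFP values are kept as weights,
entering GEV as GFP². Polarity is ignored by default (assignments and
merges use |correlation|, dissimilarity is min over a sign flip; a signed
mode implements the formulas literally), matching the spontaneous-EEG
convention in which a map and its inversion express the same generator
configuration.

Each pass performs: (i) merge of the cluster pair with maximum template
correlation; (ii) centroid recomputation (sign-aligned arithmetic mean,
iterated to a fixed point, re-centered); (iii) atomization of the
minimum-GEV cluster, each freed map re-assigned to the surviving cluster of
highest correlation; (iv) merging of any template pair with dissimilarity
below `th_gmd` (default 0.1). Two details matter for automatic selection of
the class count:

- **Candidate states.** Every sub-step — not only a completed pass — yields
  a candidate clustering. Since a pass removes at least two clusters, pass
  boundaries alone would skip every other value of K; tracking sub-states
  makes every cluster count on the way down a candidate.
- **Deferred recomputation.** Clusters that receive freed maps keep their
  template until the next pass's recompute step. Dissolving a genuine class
  therefore costs its full GEV share at once, producing the sharp drop that
  lets the GEV threshold pin the true class count; immediate re-optimization
  would smear the drop and bias K downward.

Reduction continues while total GEV ≥ `th_gev` (default 0.85) and stops at
the first candidate below it; the last candidate meeting the threshold is
returned, after a final duplicate-merge sweep so the returned templates
always respect `th_gmd`. Ties (equal maximum correlation, equal minimum
GEV) break toward the lowest cluster index: the algorithm is deterministic
and seed-free. A cap of 10 x n_maps iterations guards against
atomize/merge oscillation. Classes are reported in descending GEV order.
Clustering-time GEV is computed over the training peak maps only;
whole-recording GEV is a separate post-backfitting quantity.

A resolution limit is inherent to the design: once the model's GEV exceeds
the threshold by more than the smallest class's contribution, dissolving
that class still clears the threshold and K is under-estimated. The
threshold resolves classes contributing more than roughly
`total_GEV − th_gev`; balanced designs (equal dwell times, uniform
switching, recordings long enough for occupancies to equilibrate) keep
per-class shares above this margin.

## Backfitting and smoothing

Every sample is labeled with the template of highest |correlation|
(zero-GFP samples inherit the previous label). Smoothing rejects runs
shorter than `min_duration` samples (default 3): each such interior run is
relabeled sample-by-sample to the better-correlated flanking class, for up
to `max_passes` passes; because per-sample relabeling can split a run and
spawn new short runs, a final phase absorbs any remaining short interior
run wholly into its better-correlated flank, which strictly reduces the run
count and guarantees the no-short-interior-run postcondition. The exact
smoothing procedure is a documented design choice — a minimum-duration
run-rejection scheme with a single interpretable parameter — rather than a
penalty-based relabeling. Every sample receives a class; there is no
rejection label.

## Features, statistics, classification

Per class: mean segment duration (ms), occurrence (segments/s), coverage
(%), and GEV (%) over all samples. Coverage = occurrence x duration / 10
holds exactly because both statistics count boundary-truncated runs as
ordinary runs. Transitions are counted between consecutive *segments*
(diagonal 0, rows normalized); sample-level counting (diagonal included) is
available but self-transitions there only restate dwell times. Feature
vectors concatenate the 4K temporal entries (classes ascending; duration,
occurrence, coverage, GEV within class) and the K(K−1) off-diagonal
transition entries row-major. Windowing is non-overlapping by default
(stride = length), remainder dropped.

Groups are split at rating > 4.5 (high) vs ≤ 4.5 (low); the boundary value
goes to "low" for determinism. Rank-sum tests are two-sided: exact by
enumeration when the combined n ≤ 20 and tie-free (delegated to
scipy.stats.mannwhitneyu's exact method and cross-checked in the test suite
against full enumeration), otherwise the normal approximation with tie and
continuity corrections. No multiple-testing correction by default, with
Benjamini–Hochberg optional; trials are treated as independent
observations pooled across the dataset.

Classification uses fivefold cross-validation with folds dealt at the
*trial* level (windows of one trial never straddle folds), stratified by
label, features standardized with training-fold statistics only. Backends:
RBF-kernel SVM (C = 1, gamma = 'scale'), random forest (200 trees), and a
one-hidden-layer (64-unit) feed-forward network, all through scikit-learn
with recorded hyperparameters. Pooled accuracy over folds is the headline
number; per-fold mean ± SD is also reported.

## Synthetic generator

The generator emulates the microstate model directly: K zero-mean unit-GFP
topographies (random mutually orthogonal directions in the zero-mean
subspace, pairwise polarity-aware dissimilarity ≥ 0.8 by construction)
alternate as a first-order Markov segment process. Defaults: 32 channels,
500 Hz, mean dwell 100 ms (within the canonical 80–120 ms range; geometric
lengths by default — memoryless, consistent with the Markov process — gamma
optional), uniform off-diagonal switching, and a strength envelope
`0.1 + 0.9 |sin(2π · 10 Hz · t)|` that mimics alpha-band waxing and waning
— it makes GFP peaks meaningful while the floor keeps every sample
non-degenerate. Segment polarity flips at random so polarity-invariant
clustering is genuinely exercised. White sensor noise is scaled so that
(template signal power)/(noise power) equals the configured SNR (default
5). Per-class mean durations may be given as a vector, which is how planted
condition effects are expressed. Rated datasets share one template set
across conditions (dynamics, not topography, carry the effect) and derive
per-trial seeds from a master seed.

What the generator does *not* emulate: volume-conducted spatial noise
correlations, 1/f background spectra, realistic electrode geometry, or
non-Markov long-range dependence. Passing recovery tests therefore shows
the algorithms are correct under the model's own assumptions, not that any
particular real dataset satisfies them.

## Problem sizes and numerical choices

Recovery runs use 45-s recordings (~900 peak maps), long enough for class
occupancies to equilibrate so every class's GEV share exceeds the threshold
resolution margin; recovery is checked over K = 3..10 at SNR 5 across 20
seeded runs. Discrimination experiments use 100 trials per condition of 5 s
each; statistical calibration uses ~1080 null tests. Degenerate inputs
(zero-GFP maps, all-zero weights, empty clusters) raise explicit errors
rather than propagating NaNs; unit-norm divisions clamp at 1e-300 only
where inputs were already validated non-degenerate. All stochastic
components accept explicit seeds, and pipeline runs record config echo,
seeds, and output digests in a manifest from which any artifact can be
regenerated.

## Known limitations

- The GEV-threshold resolution limit above: very unbalanced class
  occupancies (a class covering ≲ total_GEV − th_gev of the variance) merge
  undetected.
- Smoothing guarantees its postcondition but the final absorption phase is
  a whole-run decision; on extremely noisy label sequences it may relabel
  samples their own correlations weakly contradict.
- The minimal EDF writer targets round-trip fidelity, not full annotation
  support (no events, one fixed record duration).
- Group-level clustering pools peak maps across trials and subjects in one
  pass; a two-stage per-subject mode exists but is off by default and less
  validated.
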