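# Methods

## Overview

`bandstates` implements a frequency-band-resolved EEG microstate
analysis: resting-state EEG is decomposed into the four canonical bands
(delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz), each band is
segmented into a small set of recurring quasi-stable scalp topographies
("microstates", conventionally labeled A–D), and the temporal behavior
of those states — mean duration, time coverage, occurrence rate, global
explained variance (GEV) and between-state transition probabilities —
is screened as a severity biomarker with group statistics, FDR-controlled
clinical correlations and cross-validated single-feature ROC analysis.

Because no patient data ship with the package, a synthetic generator
with fully planted microstate structure provides the study conditions;
every downstream stage is validated by parameter recovery against that
ground truth.

## Signal model and generator

The generator renders one narrowband component as

    x(t) = a · e(t) · T[s(t)] + n(t)

where `T` is a set of four average-referenced, unit-norm scalp maps,
`s(t)` a semi-Markov state sequence, `e(t)` the rectified magnitude of a
band-limited unit-variance Gaussian process in the component's band,
`a` an amplitude scale (default 15 µV), and `n(t)` spatially smooth
Gaussian sensor noise (squared-exponential spatial kernel, length 0.5
chord distance on the unit sphere) scaled so that signal RMS / noise
RMS equals the configured SNR (default 3). The rectified envelope makes
GFP maxima coincide with moments of high topographic SNR, matching the
assumption behind GFP-peak clustering.

Dwell times are gamma distributed with shape 4 and mean 80 ms, floored
at one sample — a right-skewed law covering the canonical 60–120 ms
stability range. Each segment's state is drawn from the transition row
of its predecessor, so consecutive segments always differ and the
planted matrix is a genuine segment-wise conditional law with zero
diagonal.

Templates are stylized analytic fields on the montage: two diagonal
dipolar gradients (A, B), an anterior–posterior gradient tilted toward
the vertex (C), and a frontal-midline focal bump (D), with a small
seeded random dipolar jitter per instantiation. On the default
52-channel spiral cap their pairwise |spatial correlation| stays below
0.5, so the four classes are well separated without being orthogonal.

Cohorts draw one transition matrix per subject and band: off-diagonal
rows come from a Dirichlet distribution around the group mean row,
with the concentration chosen in closed form to hit a target
between-subject SD (rows stay stochastic by construction). The shipped
cohort conditions plant the severity effect in the delta-band C→B
entry — moderate group mean 0.383 (SD 0.104), severe group mean 0.162
(SD 0.040), healthy controls uniform — and couple the VAS score
negatively (target Spearman magnitude 0.66) and the ABC score
positively (0.69) to that entry through a Gaussian latent; at coupling
noise zero the monotone map makes the rank correlation exactly ±1.
DHI is drawn uniformly inside group-defining ranges (HC < 15, moderate
20–60, severe > 60). All randomness descends from one master seed via
`numpy.random.SeedSequence` spawning (templates, then subjects in
order, then scores), so cohorts are bit-reproducible.

## Preprocessing

Filtering uses zero-phase (forward–backward) Hamming-window FIR
band-passes. The transition width at each edge is
`max(0.25·edge, min(2 Hz, edge))`: a strict fraction-of-edge rule at a
1 Hz delta edge would demand a ~13 s kernel, longer than the 10 s
analysis segments, so the width is floored the way practical EEG
filters do. The kernel length is set by the narrower transition
(≈ 3.3 / width cycles), recordings shorter than three kernel lengths
are rejected, and one kernel length at each end is flagged as edge
samples; peak picking skips them. Broadband conditioning (1–40 Hz)
resamples to 256 Hz with a polyphase anti-aliasing filter and applies
an average reference.

Quality control selects the earliest 10 s window, scanned at sample
resolution from the start, in which every channel stays within
±100 µV; a recording with no clean window is excluded (an outcome, not
an error).

## Segmentation

GFP is the population spatial standard deviation of the
average-referenced map. All strict local GFP maxima (plateaus count at
their left edge) are pruned to a minimum spacing of 10 samples —
taller peaks win — and up to 1000 surviving peak maps per subject are
drawn uniformly without replacement; if fewer exist, all are used and a
warning is logged (a 10 s delta segment at 256 Hz genuinely has fewer).

The modified K-means treats a map and its sign-flip as the same state:
maps are assigned to the template maximizing squared spatial
correlation, and each template is re-estimated as the dominant
eigenvector of its members' outer-product sum. Default 20 restarts,
300 iterations, relative explained-variance tolerance 1e-6; an emptied
cluster is re-seeded from the worst-fit map. K is scanned over 2–10 and
scored by the predictive-residual criterion
`CV(K) = σ²_K ((C−1)/(C−1−K))²` with `σ²_K` the mean unexplained map
variance; the four-state solution can be (and by default is) forced,
mirroring the field convention. Each K is additionally warm-started
from the previous K's solution plus one extra template, which makes
the explained-variance profile provably non-decreasing in K — plain
restarts do not guarantee that nesting. Group templates come from peak
maps pooled over all subjects per band, so every group is segmented
with the same maps, and a K=4 solution is relabeled A–D by exact
optimal assignment against the stylized canonical maps (polarity
ignored).

## Features

Back-fitting labels every sample with the template of highest
|spatial correlation| (ties to the lowest class index; zero-variance
samples inherit the previous label and are flagged). Peak extraction
uses the clean QC segment, but back-fitting covers the whole recording:
transition estimates from a single 10 s window are dominated by
segment-count noise (~125 segments at 80 ms dwells).

Temporal smoothing enforces a 30 ms minimum state duration:
iteratively, the shortest violating interior run (leftmost on ties) is
dissolved into its two flanking states, split contiguously at the point
maximizing the summed winning correlations. The contiguous split is
deliberate — relabeling each sample independently could mint new short
runs and break termination, whereas every dissolve here removes at
least one run, so the procedure provably terminates (a heap keeps it
near-linear). First and last runs are exempt because the window censors
their true extent.

Transition probabilities count ordered pairs of consecutive *distinct*
runs and normalize per row (diagonal fixed at zero; rows with no
outgoing transitions are reported undefined). Sample-pair counting is
available by flag, but segment-wise counting is the default: sample-wise
self-transitions would concentrate nearly all mass on the diagonal and
could not produce off-diagonal values of the magnitude the planted
conditions use (≈0.16–0.38). Per-class GEV is
`Σ_{t:label=k} (GFP(t)·corr(v_t,T_k))² / Σ_t GFP(t)²`.

Features are named `[Band]_TP_[From]-[To]` and
`[Band]_[Metric]_[State]` with metrics MD (mean duration, ms), COV
(coverage fraction), MO (occurrence per second), GEV (fraction); four
bands give 112 columns per subject, validated by a round-trip grammar.

## Inference

Standard machinery is delegated: Shapiro–Wilk, Welch/pooled t (with a
summary-statistics entry point so printed group tables can be checked),
Mann–Whitney U (exact when n₁·n₂ ≤ 400 and tie-free) and Spearman to
scipy; Holm–Šídák and Benjamini–Hochberg to statsmodels; the two-way
mixed (split-plot) ANOVA — group between, class within — to pingouin,
with Greenhouse–Geisser off by default and available by flag. The
pooled-vs-Welch choice in the automated path is gated by Levene's test
at α = 0.05; both variants remain callable directly. The clinical
screen restricts to patients, correlates every feature with VAS and ABC
(pairwise-complete), and applies BH within scale across the full
112-feature family (per-band families by flag); DHI is excluded from
the screen because it defines the severity groups.

The ROC stage evaluates one feature at a time: stratified five-fold
cross-validation in which the only trained quantity is the orientation
(sign of direction, fixed on the training folds by training AUC ≥ 0.5),
held-out AUC per fold with half-credit ties (the Mann–Whitney
U-statistic form), the mean over folds, and a 2.5th–97.5th percentile
interval of the five fold AUCs. That five-point percentile interval is
reported for fidelity to the protocol it mirrors; a 2000-replicate
bootstrap CI is available as a sounder alternative. The per-feature p
comes from a pooled-data Mann–Whitney test and is labeled as such.

## Validation and what it shows

Recovery tests run the pipeline against the generator's ground truth:
pooled clustering on a 10-subject, 60 s cohort at SNR 3 recovers the
planted templates with mean |spatial correlation| ≥ 0.95 (≥ 0.999
noiseless), and back-fitting plus smoothing on a 10-minute narrowband
recording at SNR 3 recovers the planted transition matrix to within
0.05 per entry. Order-statistic procedures (AUC, U, BH, Holm–Šídák,
canonical labeling, QC window search) are checked exactly against
brute-force definitional implementations. Calibration suites confirm
~5% type-I error for the two-group t path at n = 31/19 and
false-discovery control of the screen under a global null. The
cross-validated AUC of the severity biomarker is reproduced on a
surrogate that draws the two groups directly from their per-group
normal laws (n = 31 vs 19): the analytic separation of those laws is
Φ(0.221/√(0.104²+0.040²)) ≈ 0.98, and the five-fold mean AUC averaged
over 100 seeds lands at ≈ 0.977.

Problem sizes in the shipped tests (10 × 60 s cohorts, one 10-minute
recording, 100–2000 replicate calibration loops) were chosen as the
smallest at which the law-of-large-numbers bounds they assert are
comfortably away from their sampling noise.

## Known limitations

- **Narrowband switching is broadband.** A process that switches
  topographies every ~80 ms is not band-limited: the switching
  sidebands extend tens of Hz. Delta-band filtering therefore keeps
  only the slow spectral content of all components, and the planted
  delta-band *transition* structure is largely erased from recovered
  per-subject transition probabilities in the full cohort pipeline —
  the group effect resurfaces as cross-band coverage/GEV differences
  instead. The in-band recovery guarantees above hold when the dwell
  dynamics are resolvable by the band's filter (demonstrated in the
  alpha band). This is an identifiability limit of the semi-Markov
  stand-in generative model, which is a modeling convenience, not an
  inferred mechanism; passing recovery tests show the *estimator* is
  faithful, not that real narrowband EEG behaves this way.
- The generator omits artifacts (blinks, EMG), volume-conduction
  realism and non-stationarities, so QC exclusion paths are exercised
  only by constructed spikes.
- The percentile CI from five fold AUCs is crude by construction and
  is reported verbatim alongside the bootstrap alternative.
- Whether the ±100 µV rule applies pre- or post-filtering is applied
  post broadband conditioning, following the order in which the steps
  are described.
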