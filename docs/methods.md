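# Methods

`mstates` implements a microstate-based analysis of resting-state EEG:
polarity-invariant segmentation of the signal into a small number of
quasi-stable topographic states, state-specific phase-locking
connectivity, a signed network-based permutation framework for
edge-level group statistics, and an SVM stage for cohort discrimination.
This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Microstate model and segmentation

EEG microstates are ~100 ms epochs during which the scalp voltage
topography stays quasi-stable while its overall strength oscillates.
The topography and its negation express the same generator
configuration, so all similarity computations use the absolute spatial
Pearson correlation between average-referenced maps ("polarity
invariance"); template polarity is a gauge, and any template row may be
negated without changing any assignment, GEV, or selected model order.

Segmentation follows the standard three-level scheme:

1. **Per recording.** Global field power (GFP) is the per-sample
   population SD across channels; maps at GFP local maxima are the
   high-SNR representatives of the topography.  The lowest 15% of peaks
   by GFP are discarded (`floor(0.15 n)`, so never more than specified),
   and outlier peaks above `mean(GFP) + 3 SD(GFP)` (all-sample
   statistics) are removed.  The outlier rule is stated in the
   literature as "greater than three times the standard deviation"; read
   literally (`GFP > 3 SD`) it removes nearly all peaks on realistic
   recordings, because GFP is a positive quantity whose mean typically
   exceeds a few times its own SD.  We therefore center the cut at the
   mean by default; `sd_center="zero"` restores the literal reading.
   The surviving peak maps are clustered by a modified k-means
   (`ModifiedKMeans`): assignment by maximal |correlation|, template
   update as the dominant eigenvector of the cluster's map covariance
   (exactly sign-invariant, unlike a mean of sign-aligned maps), 100
   restarts by default, best restart by global explained variance
   (GEV).  Empty clusters are re-seeded from the worst-explained map.
2. **Per group.** Each recording contributes exactly k* templates; the
   pooled templates are re-clustered into k* group templates, so every
   participant has equal weight.
3. **Common templates.** The two groups' templates are pooled and
   clustered once more; the common set is back-fitted to everyone,
   avoiding systematic template differences between groups.  Templates
   are matched to a labeled reference by a Hungarian assignment on
   |correlation| (optimal, not greedy; exact ties fall to reference
   order) and sign-aligned to it.

**Model order.** The Krzanowski–Lai (KL) criterion is computed from the
within-cluster dispersion W(k) (sum over maps of the squared distance to
their sign-aligned unit template, i.e. `2 - 2|corr|` on normalized
maps): `DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k)`,
`KL(k) = |DIFF(k)/DIFF(k+1)|`, with p the channel count.  Each
recording's KL curve is divided by its own maximum before averaging
("normalized KL" is not defined precisely in the literature we follow;
max-normalization is this package's choice and is configurable), and the
argmax over interior k wins, ties to the smallest k.

## Back-fitting, smoothing, parameters

Common templates are fitted back to *every* sample of the 1–20 Hz
filtered, average-referenced recording, per artifact-free segment.
Zero-variance samples carry the previous label.  Runs shorter than
30 ms are iteratively relabeled to the runner-up class by spatial
correlation until none remain (pass cap 50, then remaining short runs
merge into their longer neighbor — relabeling can oscillate on noisy
evidence; the postcondition holds either way).

The first and last runs of each artifact-free segment are potentially
truncated and are excluded from **all** per-class parameters; coverage
and GEV are renormalized over the non-excluded samples so coverage still
sums to 100% (excluding truncated runs only from duration statistics is
available by configuration).  Parameters per class: GEV (%), mean
duration (ms), occurrence (1/s, denominator = non-excluded time), 
coverage (%), mean interval (ms, within segments only, between
consecutive non-truncated runs of the class), mean GFP.  The spatial
correlation matrix SC[X, Y] is the mean |corr| of template X with maps
labeled Y (not symmetric).  Transition probabilities are reported as
observed minus expected, where the expected probability of x→y is the
share of y's non-truncated run count among all classes except x
(`n_y / Σ_{z≠x} n_z`; the source literature cites this construction
without a formula, so the choice is explicit here and configurable).
Rows of the difference sum to zero; the diagonal is zero.

## Phase connectivity

Connectivity runs on a signal path parallel to segmentation: the raw
recording is spatially sharpened with a spherical-spline surface
Laplacian (spline order m=4, 50 Legendre terms, regularization 1e-5 —
the conventional CSD settings; linear in the input, zero on spatially
constant maps, and approximately multiplies a degree-n spherical
harmonic by n(n+1)), band-filtered to alpha (8–12 Hz), and
Hilbert-transformed per artifact-free segment.  10% of the phase
samples at each end of *each segment* are masked (the per-segment
reading protects every Hilbert boundary; per-recording discard is the
alternative reading).  Phase samples of one microstate class are pooled
across segments — only per-sample phase differences enter the
estimator, so pooling cannot create spurious jumps — and

    PLV_ij = | mean over class samples of exp(i (φ_j − φ_i)) |

is computed per channel pair.  Classes with fewer than 250 valid
samples (1 s at 250 Hz) are flagged unreliable rather than dropped.

## Signed network-based statistics

Edge-level tests (pooled-variance two-sample t, paired t, or Pearson r
with parametric p) are thresholded at a primary p_thr; suprathreshold
edges are split by statistic sign; connected components are formed per
sign on the electrode graph (edges connect when they share an
electrode); a component's size is the sum of its edge statistics.  Each
permutation (group labels shuffled / difference signs flipped / score
order shuffled) contributes its largest positive and most-negative
component sizes to two null distributions, and an observed component of
sign s is referred to the null of sign s:

    p = (2 · #{|S_null| > |s_obs|} + 1) / (N + 1),  clamped to 1.

The formula can exceed 1 for small components; clamping keeps it a
probability.  Permutation spaces smaller than N are enumerated exactly.
For scalar permutation tests the same doubled convention is used with a
*one-tailed* exceedance count matched to the observed sign — the exact
analogue of the sign-matched component null; doubling a two-tailed
count would make null p-values stochastically twice uniform.
Holm correction and BCa bootstrap intervals (percentile fallback on
degenerate bootstrap distributions) cover the scalar follow-ups, and
`mean_fcscc` reduces a significant component to a per-subject scalar
(mean connectivity over its edges).

## Classification

Nested leave-one-out SVM (linear or RBF): the outer loop holds out one
subject; inside each training fold a pipeline of standardization → PCA
retaining 95% variance → SVC is grid-searched by inner leave-one-out
accuracy.  No preprocessing statistic ever sees the held-out subject
(training-fold means are recorded for audit).  Grids default to
C ∈ 10^{−2..2}, γ ∈ 10^{−3..1}, ascending, so ties resolve to smaller
C then smaller γ.  Pooled outer-fold decision scores give one ROC/AUC.
Feature *selection* by group-difference tests happens before the CV, as
is common practice; outputs carry an explicit note that this is a
potential optimism source.  A second known artifact runs the other way:
under a true null, raw pooled leave-one-out decision scores are
*pessimistically* biased, because leaving a subject out tilts the
training class balance against its class, giving every fold a score
offset correlated with the held-out label.  Each fold's decision score
is therefore centered on its own training-score mean (a fold-local
statistic — no leakage) before pooling; with centering the null AUC is
chance-level (~0.49 at n = 30) and separable data still reach AUC 1.
The chance-level validation runs at cohort scale (n = 30).

## Synthetic data

The generator plants everything the pipeline later estimates:

* **States.** A semi-Markov chain: gamma dwell times, default shape 4 ×
  scale 25 ms (mean 100 ms, CV 0.5 — typical of empirical dwell
  variability, and with only ~3% of dwells below the 30 ms smoothing
  floor, so smoothing acts as denoising rather than redistribution);
  uniform off-diagonal transitions unless a matrix is given.
* **Topographies.** Random off-center dipoles inside a unit head
  sphere, sampled at quasi-uniform cap electrode positions (Fibonacci
  spiral; 59 channels is the reference layout), zero-meaned and
  unit-normed, rejection-sampled to a pairwise |corr| bound.
* **Carrier and coupling.** A 10 Hz carrier whose phase performs a
  random walk (diffusion 0.15 rad/√sample); each channel's phase is the
  carrier phase plus an independent von Mises(0, κ) jitter, giving the
  closed-form pairwise PLV r(κ_i)·r(κ_j) with r = I1(κ)/I0(κ).  Because
  coupling is controlled per channel, plantable edge sets are
  node-induced (a clique over a channel subset); group effects raise κ
  on the channels incident to the planted edges during a designated
  state.
* **Noise.** Spatially white Gaussian after average reference, scaled
  so state-signal RMS / noise RMS equals `snr` (default 2).

What the generator does **not** emulate: biophysical volume conduction
(templates are idealized dipole fields, not forward-model projections),
1/f background spectra, artifacts (blinks, EMG), non-stationary alpha
power, or spatially correlated noise.  Passing recovery tests therefore
show that the algorithms are correct and calibrated under the model's
own assumptions — not that real-EEG effect sizes will match.

A phase-level cohort generator (`simulate_plv_cohort`) produces subject
PLV matrices directly from the coupled-phase model, skipping amplitude
synthesis and back-fitting; repetition-heavy validation of the
statistics stage (type-I rate over hundreds of null cohorts) uses it so
the problem sizes stay desk-scale.

## Numerical choices and degenerate inputs

* Sample indices 0-based, intervals half-open; filtering, Hilbert
  transforms, and labels never cross artifact boundaries.
* Zero-phase filtering: 4th-order Butterworth, forward–backward;
  segments shorter than the filter pad length pass through unchanged
  with a warning.
* Minimum run length for "≥ 30 ms" is `ceil(30 fs / 1000)` samples.
* Argmax ties take the lowest class index; k-means restarts derive
  per-restart seeds from one root seed; recordings are processed in
  sorted-id order, so pipeline outputs are byte-reproducible.
* Edge discard counts floor per side; 15% peak discard floors.
* Zero-variance edges are excluded from thresholding; constant scalar
  data yields p = 1 with a warning; degenerate BCa intervals fall back
  to percentile with a warning.

## Validation problem sizes

`scripts/acceptance.py` recomputes the headline quantities with:
20 seeds × 4 minutes of 59-channel 250 Hz EEG at snr 2 (k-sweep with 5
restarts, k=5 fit with 20 restarts) for template/model-order/dwell
recovery; 500 null cohorts (16 channels, 10 subjects/group, 200
permutations, p_thr 0.01) for the family-wise error rate plus one
planted 5-node clique (15/group, κ effect 5, 2000 permutations) for
power; 10,000-sample phase series for PLV calibration; and 50 label
shuffles of a 16-subject feature matrix for the chance-level AUC.  The
test suite runs the same checks at smaller sizes with envelopes
recomputed from the sizes actually used (binomial/SEM formulas).
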