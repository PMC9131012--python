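# mstates

EEG microstate dynamics, microstate-specific phase-locking
connectivity, and signed network-based permutation statistics — for
researchers who analyze multichannel resting-state EEG and want the
whole chain, from topographic segmentation to cohort-level inference
and classification, reproducible and validated against synthetic data
with known ground truth.

## What it computes

Resting EEG passes through a sequence of quasi-stable scalp
topographies ("microstates", ~100 ms each).  `mstates` implements:

* **Segmentation** — global field power `GFP_t = SD over channels of
  V(t)`, peak-map extraction, and a polarity-invariant modified k-means
  (`ModifiedKMeans`, a scikit-learn estimator): maps are assigned to the
  template with the largest |spatial correlation|, and templates update
  as the dominant eigenvector of the cluster covariance.  Model order is
  chosen by the Krzanowski–Lai criterion; recording → group → common
  template levels are supported, with Hungarian label matching (classes
  A–E).
* **Dynamics** — back-fitting of templates to every sample, 30 ms
  temporal smoothing, and the parameter suite per class: GEV
  `= Σ(GFP_t·C_t)²/ΣGFP_t²`, mean duration, occurrence, coverage, mean
  interval, mean GFP, the spatial-correlation matrix SC, and
  observed-minus-expected transition probabilities TP.
* **Connectivity** — spherical-spline surface Laplacian, Hilbert phases
  in the alpha band, and per-class phase-locking values
  `PLV_ij = |mean_t exp(i(φ_j − φ_i))|` over the samples of each
  microstate class.
* **Statistics** — a signed network-based statistic: suprathreshold
  edges split by sign, connected components on the electrode graph,
  component size = sum of edge statistics, calibrated by permutation
  with `p = (2·#{|S_null| > |s_obs|} + 1)/(N + 1)`; plus scalar
  permutation tests, Holm correction, BCa bootstrap intervals, Cohen's
  d and Cramér's V.
* **Classification** — nested leave-one-out SVM (scaling + PCA at 95%
  variance inside every training fold) yielding a pooled ROC/AUC.
* **Synthetic data** — a semi-Markov generator with gamma dwell times,
  dipolar topographies, a diffusing alpha carrier, von Mises phase
  coupling with closed-form PLV `(I₁(κ)/I₀(κ))²`, and plantable group
  effects, so every stage can be checked against ground truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import mstates as ms

# five planted topographies, one minute of 59-channel EEG at snr 2
maps = ms.generate_templates(59, 5, min_separation=0.5, seed=1)
cfg = ms.SimulationConfig(duration_s=60, snr=2.0, seed=3, templates=maps)
rec, truth = ms.generate_microstate_eeg(cfg)

prep = ms.rereference_average(ms.bandpass_zero_phase(rec, 1, 20))
gfp = ms.global_field_power(prep)
peaks = ms.extract_gfp_peaks(gfp, prep.segments)
print(len(peaks))                    # 1030 peak maps survive the filters

run = ms.cluster_k_range(prep.data[:, peaks].T, range(2, 11),
                         n_repeats=5, seed=0)
print(ms.select_k_kl([run.dispersion], p=59))   # 5  <- planted model order

# align recovered templates to the planted ones before comparing labels
templates = ms.order_templates(run.templates[5],
                               ms.TemplateSet(maps=truth.templates))
seq = ms.smooth_sequence(ms.backfit(prep, templates))
print(round(float(np.mean(seq.labels == truth.labels)), 2))   # 0.91
table = ms.compute_parameters(seq, gfp).table
print(round(float(table["mean_duration"].mean())))            # 107 ms
```

The Krzanowski–Lai criterion recovers the planted five classes, 91% of
samples get the correct state label at snr 2, and the mean dwell
(planted 100 ms) comes back within ~7% — the residual inflation is the
30 ms smoothing absorbing sub-threshold dwells, quantified in the
methods note.

A full cohort run (simulate → templates → back-fit → parameters → PLV →
NBS → SVM) is driven by a YAML config:

```bash
mstates all config.yaml      # or: mstates simulate config.yaml, mstates nbs ...
```

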