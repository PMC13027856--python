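# Methods

This note records the models, numerical choices and limitations behind
`neurofuse`, at the level of detail a maintainer needs to modify it safely.

## Volume model and geometry

Volumes are dense (X, Y, Z[, T]) grids with a 4×4 voxel→world affine in mm.
Every NIfTI load reorients to canonical RAS axis order, fixing the plane
convention sagittal = x, coronal = y, axial = z (the axis convention is a
package choice; nothing downstream depends on scanner orientation). Rigid
transforms are extrinsic x-y-z rotations plus translation, applied about
the target-grid centre; resampling is trilinear with zero fill, which makes
integer-voxel shifts exact and affine-linear images exactly recoverable —
both used as tests. PNG export scales each slice min→max to 0–255; a
constant slice maps to zero (the convention avoids a 0/0).

## Synthetic cohort (what it emulates, what it does not)

The generator mirrors a single-site case/control resting-state study:
79 cases, 105 controls by default, so the subject-level 80/20 split
accounting is reproduced verbatim. Conditions are set once in
`PhantomSpec`; randomness is counter-based (Philox keyed by seed, subject
id and stream), so adding subjects never perturbs existing ones and all
outputs are bit-reproducible.

* **Structural phantoms** — an ellipsoidal brain (semi-axes 0.40 × grid,
  ±2 % per-subject axis jitter) with a cortical shell of thickness
  2 voxels for controls and 2 + `effect_size` for cases; interior 0.6,
  shell 1.0, Gaussian noise σ = 0.1 by default. At
  `morph_jitter = noise_sd = 0` the shell voxel count equals the analytic
  ellipsoid-difference count, an exact oracle.
* **Functional phantoms** — per-ROI unit-variance signals synthesised on
  in-band DFT bins (0.01–0.1 Hz at TR = 2 s), plus a 0.002 Hz drift and
  white noise. ROIs 1–2 share a latent component giving correlation
  min(0.9, `effect_size`) in cases, 0 in controls: planted functional
  connectivity with a closed-form target. The baseline image is an
  ellipsoid with radial intensity falloff — EPI-like tissue contrast,
  without which frame-to-frame motion would be unidentifiable by
  mutual information. Motion spikes are injected by resampling the
  affected frames; the returned motion trace is exact ground truth.
* **Registration phantom** — a sum of anisotropic Gaussian blobs; the
  cortical phantom is too close to spherical for rotations to be
  identifiable, so registration accuracy is assessed on this structured
  variant.
* **Atlas** — contiguous block parcellation of the brain mask (sorted
  voxel order split into near-equal slabs): disjoint, non-empty, covering.

Not emulated: hemodynamics, physiological noise spectra, scanner
artifacts, anatomical detail, site effects. Passing tests demonstrate the
pipeline's correctness and its ability to recover planted effects — not
clinical performance on real data.

## Preprocessing

* **Brain mask**: Otsu threshold on a 2 mm-smoothed volume, largest
  connected component. (Standard practice; the mask definition is a
  package choice.)
* **Z-scoring** uses the population SD of within-mask voxels — per-scan
  statistics — and errors on constant input.
* **Mutual information**: 32-bin joint histogram plug-in estimator in
  nats, no smoothing; cross-checked against an independent
  contingency-table implementation.
* **Registration**: derivative-free coordinate search with step halving
  (initial steps 4 mm / 0.1 rad, floor = initial/64) over a 2-3 level
  resolution pyramid, seeded by a coarse 5³ translation grid search; the
  identity is always a candidate so MI never decreases. Accuracy on the
  structured phantom: median ≤ 0.5 voxel / ≈0.5–2° depending on the
  phantom realization (orientation information varies with the blob
  layout).
* **Motion estimation** registers each frame to the reference with a
  lighter search, after smoothing both frames by 1 voxel — equalising the
  interpolation blur of moved and unmoved frames removes a sub-voxel bias.
  Reported parameters are the head motion (inverse of the realigning map).
* **FD** is computed on backward first differences of the trace with
  r = 50 mm; the default censoring threshold is 0.5 mm (exposed in
  config). **Order**: band-pass the full series first, then drop censored
  frames — an ideal Fourier filter on a gapped series is not defined.
* **Band-pass** is an exact ideal filter: rFFT, zero out-of-band bins
  (DC always removed), inverse rFFT. Idempotent and in-band
  energy-preserving by construction.
* **Connectivity**: Pearson over retained frames; Fisher z = atanh with r
  clipped to ±(1−1e−7); zero diagonal by convention.

## Network branches

All network code runs on an in-package vectorized reverse-mode autodiff
core over NumPy (`nn/autodiff.py`): broadcasting arithmetic, matmul,
elementwise nonlinearities, reductions, shape ops, gather and concat.
Convolution is im2col — a precomputed gather index plus one matmul — so its
gradient is exact; it is verified against a six-nested-loop oracle and by
finite differences.

* **Structural branch**: one shared-weight encoder applied per plane
  stack, embeddings concatenated (the minimal reading of "jointly
  modelled" planes; channel-stacking would be the alternative). Full-scale
  channel plan {32, 64, 128, 256} with kernels {3, 5} alternating and
  dilations {1, 2}; each block is conv → per-channel spatial-moment
  normalisation → ReLU with a 1×1×1-aligned residual branch and stride-2
  downsampling. Spectral normalisation rescales each kernel (reshaped to
  out-channels × rest) by its largest singular value; the forward pass
  uses a cold-start converged power iteration, keeping repeated evaluation
  bit-deterministic, and treats σ as a constant in the backward pass.
  Channel attention is a softmax projection of the pooled descriptor;
  spatial attention a 1-channel 1×1×1-conv sigmoid gate. The optional
  graph head pools the feature map into depth-slab nodes and applies
  H' = σ(A H W) with a chain adjacency. The embedding entropy penalty
  (softmax entropy, weight λ_ent = 1e−3) joins the loss.
* **Temporal branch**: linear projection of the T×R series to d_h,
  bidirectional LSTM (independent directions, gate order i, f, g, o, zero
  initial state), softmax attention pooling over time, ReLU transform to
  f_seq; the packed Fisher-z upper triangle is projected to the same
  width, interacts multiplicatively, and the concatenation
  [f_seq, f_fc, f_cross] uses the raw packed vector by default (a config
  switch substitutes the projected one).
* **Head**: LayerNorm → dense 256 (GELU) → dropout 0.5 (training only) →
  2 logits; softmax applied externally at evaluation. A single-logit
  sigmoid mode is available in the fusion utilities but the two-logit head
  is the default, being the more specific architecture description.
* **Fusion**: both embeddings projected to a common width; fused vector
  [proj_s, proj_f, proj_s ⊙ proj_f]. Single-modality use bypasses fusion.

Initialisation is seeded uniform fan-in scaling. Desk-scale presets
(channels (4, 8), d_h = 16, 16³ volumes, 8 slices per plane) keep
single-CPU experiments in seconds-to-minutes; they change capacity, not
architecture.

## Training and evaluation

Seeded Adam (lr 1e−3 in the desk-scale estimators, batch 16) over focal
loss (α_t = 0.25, γ = 2) or cross-entropy; Mixup (Beta(0.2, 0.2), seeded
permutation, soft labels) may co-occur with either loss. Given a seed the
whole trajectory — init, shuffling, dropout, Mixup — is deterministic.
Splits are always at the subject level (test = floor(0.2 n) per class,
the only rounding consistent with the published accounting); training
refuses to start if a subject appears in both splits. Metrics come per
slice and per subject (mean probability); undefined ratios are NaN with a
flag, never coerced to zero. ROC is a threshold sweep over unique scores
with trapezoid AUC (ties count one half), verified against Mann–Whitney
pair counting. Grad-CAM weights each channel of the captured
post-attention feature map by the spatial mean of the target-logit
gradient, rectifies the weighted sum and upsamples to the input grid.

## Numerical choices and degenerate inputs

Histogram MI returns max(·, 0); registration caps objective evaluations
and reports non-convergence in the result rather than raising. The
single-mid-slice index is floor(D/2) (the mid-coordinate convention); a
window of n ≥ 2 starts at floor((D−n)/2) — the two differ by at most one
slice. The all-zero kernel skips spectral normalisation with a warning.
Constant ROI columns name the offending ROI in the error. Mixup on a
batch of one is the identity. Focal loss is computed from logits via
log-softmax, so p_t = 0 never reaches a logarithm.

## Problem sizes

The test suite and the acceptance script use 16³ voxel grids (3 mm),
8-slice multi-view stacks at 16² pixels, 8 ROIs, T = 128–256 frames and
40 subjects per class for trainability runs, 30 epochs — sizes chosen so a
full verification pass completes on one CPU core in a few minutes while
every recovery target (planted shell effect, planted correlation, planted
motion) remains comfortably identifiable.

## Known limitations

* Rotation recovery precision varies with the registration phantom's blob
  layout (median 0.4–2°); translation recovery is uniformly ≤ 0.1 voxel.
* Spectral normalisation's backward pass ignores dσ/dW (the usual
  inexpensive approximation).
* The graph head's slab parcellation is a coarse stand-in for an
  anatomically meaningful node definition.
* Full-scale (224², 50-slice, {32…256}-channel) training is supported by
  the same code paths but is not CPU-practical; reported desk-scale
  accuracies characterise the synthetic task only.
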