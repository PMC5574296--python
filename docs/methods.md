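# Methods

This note records the models, conventions and numerical choices behind
`polypscan`, including the decisions that were genuinely open and the
limits of what the synthetic evaluation shows.

## Pipeline overview

A frame is cropped to its informative region, tiled into 227×227 windows,
and each window is classified polyp/nonpolyp from a fused feature vector:
144 color-wavelet texture statistics plus 4096 CNN fc2 activations, fed to
a z-scored linear SVM. Positive windows are aggregated into per-region
markers. The unit of classification is always the window; frames and
videos only enter through tiling and marker aggregation.

## Frame ingestion

- Coordinates are 0-based, `(x, y) = (column, row)`; rectangles half-open.
  Window centers are `origin + size/2`.
- Sliding stride is configurable, default **32 px**: dense enough that a
  ≥45 px-radius polyp is covered by several window centers, sparse enough
  for desk-scale runtime. The final window along each axis is clamped to
  the frame edge, so coverage is exact and no padding is invented.
- Auto-ROI removes contiguous border rows/columns whose mean intensity is
  below 10/255 — the black letterbox typical of endoscope output. The
  threshold is configurable; cropping below 227 px in either axis is an
  error rather than a silent upscale.
- Video I/O: AVI is read and written by a built-in lossless RIFF codec
  (uncompressed 24-bit DIB frames), which makes round-trip tests exact.
  MP4/WMV are dispatched to `imageio` and fail with a decode error naming
  the path when no suitable plugin is present. Directories of PNG/JPEG
  stills are read in lexicographic order.

## Color-wavelet features

- Per channel (r, g, b), a 3-level 2-D DWT (PyWavelets `wavedec2`).
  Subband numbering CL: level 1 (finest) → 1–3, level 2 → 4–6, level 3 →
  7–9; (horizontal, vertical, diagonal) within a level. The middle-scale
  subbands CL = 4, 5, 6 are used — fine scales are noise-dominated,
  coarse scales geometry-dominated.
- Wavelet family: **Daubechies-6** by default, configurable; boundary
  mode symmetric.
- GLCMs are computed on **signed** coefficients after per-subband min–max
  quantization to G = 32 levels (constant subbands map to all-zeros);
  distance d = 1; directions 0°, 45°, 90°, 135° with (row, col) offsets
  (0,+1), (−1,+1), (−1,0), (−1,−1); symmetrized by adding the transpose;
  normalized to sum 1. G, d and the quantization are standard GLCM
  practice; the package treats them as configuration, not science.
- Haralick statistics use entropy in bits with 0·log 0 := 0, and define
  correlation := 1 when a marginal variance vanishes (a constant image is
  perfectly correlated). This convention matters for constant windows and
  is asserted in tests.
- Feature layout: channel (r, g, b) × subband (4, 5, 6) × direction
  (0°, 45°, 90°, 135°) × statistic (correlation, energy, homogeneity,
  entropy) — 144 entries. Swapping the r and b channels of a window
  permutes the first and last 48-entry blocks and nothing else, which is
  used as a property test.

## CNN

- Fixed AlexNet-style architecture (see README). Conv3–5 use 3×3 kernels,
  stride 1, padding 1 — the standard geometry consistent with the stated
  filter counts 384/384/256.
- Implemented in NumPy: im2col convolutions, stride-tricks max-pooling
  with argmax routing, hand-derived backward passes. Every backward pass
  is verified against central finite differences in the test suite.
- Features are the **post-ReLU** activations of fc2, hence nonnegative.
- Preprocessing: pixels scaled to [0, 1], per-channel training-set means
  subtracted.
- Training: minibatch SGD, momentum 0.9, learning rate 1e-3, batch 16,
  cross-entropy, no dropout or augmentation. One integer seed drives
  initialization (He) and shuffling; training is bit-reproducible because
  all operations are deterministic for a fixed thread configuration.
- Default budget is 10 epochs; the packaged evaluations use **3 epochs on
  210 training windows**, the desk-scale setting at which the synthetic
  classes are fully learnable. Weights are float32; the CNN is trained
  first and then frozen as a feature extractor (the SVM is never
  backpropagated through).

## Fusion and SVM

- Fused vector = 144 CW features followed by 4096 CNN features (4240).
- Per-feature z-scoring precedes the SVM: the two blocks differ by orders
  of magnitude in scale and a margin classifier is scale-sensitive.
  Zero-variance features get unit scale.
- Linear SVM, squared hinge, C = 1.0, one-vs-rest for multiclass, seeded
  liblinear solver. The window score is the signed decision value
  w·x + b of the winning hyperplane in the scaled space.
- Evaluation reports a confusion matrix with sensitivity TP/(TP+FN),
  specificity TN/(TN+FP) and accuracy; for multiclass these are
  one-vs-rest with respect to a chosen positive class.

## Marker aggregation

- Positive detections of a frame are grouped by single linkage on window
  centers with link distance = one window size. "Higher-scoring" windows
  are defined relatively: score ≥ 0.8 × group maximum (scale-free, so it
  survives SVM rescaling); their centers are averaged into the marker.
  Both knobs are configurable. Markers are drawn as circles of half the
  window size.
- The marker center is a mean of centers, hence permutation-invariant and
  always inside the contributors' convex hull (both property-tested).

## Synthetic fixtures

The generator emulates the two properties the pipeline measures, not
endoscopy appearance: a smooth red-dominant background (Gaussian random
field, σ = 30 px, amplitude 18 gray levels, pixel noise σ = 6) and
elliptical polyps (semi-axes 45–80 px) carrying band-pass texture
(difference-of-Gaussians at 1.5 px, amplitude 20 with a per-window
multiplier in [0.5, 1.4]) plus a small brightness shift. Nonpolyp windows
are background, of which 40% contain a **margin polyp** — the same
textured ellipse placed so the window center falls outside it (the
labelling rule is center-based) — and 30% a coarse-scale (4 px) textured
fold with the same brightness shift. These distractors were chosen so
that neither brightness nor mere texture presence separates the classes:
a global texture summary (the CW family) is systematically confusable by
margin polyps, whereas the CNN can learn the spatial relation, which is
what makes fusion informative rather than redundant. Videos use a polyp
drifting by ≤ 5 px/frame.

What passing tests on these fixtures show: the numerical kernels are
exact, the training loops learn, the fused classifier is at least as good
as either family, markers localize a drifting target. What they do not
show: performance on real mucosa (specular highlights, motion blur,
fluids, camera distortion are all absent), robustness to class imbalance
beyond the fixed 1:2 ratio, or any clinical claim.

## Evaluation sizes

The packaged end-to-end evaluation uses 300 windows (100 polyp /
200 nonpolyp, the 1:2 ratio of the design), a stratified 70/30 split, a
3-epoch CNN budget, and a 10-frame localization video — sizes chosen so a
complete from-scratch run finishes in minutes on a single CPU while every
stage still has enough data to be meaningfully exercised.

## Known limitations

- The NumPy CNN is CPU-bound; it is sized for hundreds of windows, not
  the tens of thousands a clinical training set would need.
- Markers are per-frame; no temporal smoothing or tracking.
- One marker per detection group; overlapping polyps closer than the link
  distance merge.
- The MP4/WMV paths depend on an imageio plugin being available; the
  lossless AVI path is the only container guaranteed everywhere.
- Multiclass labels are supported mechanically (one-vs-rest SVM, CNN
  output width), but fixtures and evaluation are binary.
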