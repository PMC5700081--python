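# Methods

## The dream engine

### Model contract and the bundled toy network

The engine only needs a `LayerActivationModel`: forward activations at a
named layer, and the gradient of a scalar objective with respect to every
input pixel, with weights held fixed. The bundled toy network is three
convolution + rectifier blocks (3→8→16→16 channels, 3×3 kernels, stride 1,
'same' spatial output), weights drawn uniformly on
±0.5·fan_in^(−1/2)·`weight_scale` from a seeded generator, zero biases.
It is small enough that a 64×64 frame dreams in well under a second, yet
still shows layer-depth-dependent dream texture: clamping `relu1` produces
fine geometric structure, `relu3` coarser blob-like structure. The three
rectifier outputs are exposed as the `lower`/`middle`/`higher` presets.
Backpropagation is implemented directly (transposed convolution via a full
correlation with spatially flipped kernels; a scatter-add adjoint for the
padding); it agrees with central finite differences to ~1e−9 relative, far
inside the 1e−3 acceptance bound, because both sides are exact up to float
round-off. A `wrap` padding mode makes the network exactly equivariant to
cyclic shifts, which pairs with equirectangular frames and is used by the
shift-equivariance tests. Max-pooling is supported (gradient routed to the
arg-max, first occurrence on ties) but not used by the default
architecture.

An externally trained classification network can be adapted by satisfying
the same two-method contract; nothing in the pipeline assumes the toy
architecture.

### Objective and ascent

The ascent objective is half the sum of squared activations of the clamped
layer — "amplify what is already detected". A guided variant restricts the
sum to one channel. Each step draws a cyclic jitter shift uniform on
[−jitter, jitter]², shifts the image, adds `step_size · g / mean(|g|)`
(scale-free across layers; a uniformly zero gradient leaves the image
unchanged rather than dividing by zero), shifts back, and clamps to the
[0, 255] float working range. Per-step monotone increase of the objective
is only a first-order statement, so tests assert it at small steps and
assert strict end-to-end increase at the default step.

### Octave pyramid

Sizes are `round(base / scale^k)` for k = octaves−1 … 0, rounding half away
from zero (pinned so size arithmetic is exact and testable); any dimension
below 8 px is rejected. The standard detail-buffer loop carries dreamed
structure coarse-to-fine: at each octave the base image is resized to the
octave size, the accumulated detail is upsampled and added, the ascent
iterations run, and the new detail (result − resized base) is banked. All
resampling in the package — octave resizes, dream-zoom, flow warping — is
bilinear with half-pixel-centre alignment and edge clamping, one declared
convention instead of per-call choices.

### Defaults

octaves 3, octave scale 1.8, iterations 32, jitter 32, zoom 1 (disabled),
step size 1.5 — the parameter set used for published hallucination videos.
Dream-zoom (centre-crop to 1/zoom, resize back) is applied to a frame's
blended input before dreaming when enabled.

## Temporal coherence

Frame-by-frame dreaming flickers; inheritance fixes it. For frame t ≥ 1
the chain is: dense optical flow from raw frame t−1 to raw frame t;
backward-warp the previous *dreamed* frame along that flow; build a binary
ratio map (0.9 where flow magnitude exceeds 1 px, 0.1 elsewhere — the high
ratio keeps moving content coherent, the low ratio stops static regions
saturating under repeated blending); convexly blend the warped dreamed
frame into the raw frame; dream the blend.

Design choices that were genuinely open:

- **What is inherited.** The full previous dreamed frame (default),
  matching the video implementations this style of pipeline extends; a
  `carry="residual"` mode inherits only the dreamed-minus-raw residual.
- **Warp-then-blend vs blend-in-place.** Warping is the default
  (`warp=False` switches it off); inherited patterns then track scene
  motion rather than smearing.
- **Flow estimator.** Iterative Lucas–Kanade (`optical_flow_ilk`,
  radius 7, 10 warps, uniform window), chosen as a deterministic,
  dependency-light dense estimator; on the synthetic 3-px translation
  fixture it recovers the displacement with ~0.1 px median error, well
  inside the 0.5 px bound the tests require. The flow-threshold default of
  1 px is an exposed, pinned choice.
- **Warp convention.** Backward mapping `out(p) = image(p − flow(p))`,
  bilinear, edge-clamped; in equirect mode the horizontal axis wraps while
  the vertical axis (poles) clamps.

## Video pipeline

PNG frame sequences in lexicographic order are the canonical interchange
(8-bit on disk, float [0, 255] in memory; codec-free round trip is
bit-exact). Frame 0 is dreamed directly; later frames go through the
coherence chain. Equirectangular runs wrap-pad `wrap_pad` columns (default
16) onto each side before dreaming and crop after, which measurably reduces
the seam discontinuity between columns 0 and W−1; vertical edges are never
wrapped. Every run writes a manifest (full config, per-frame derived seeds,
objectives, timings); re-running from a manifest is bit-identical because
each frame's RNG stream is derived from (config seed, frame index) rather
than from a shared sequential stream — frames may therefore be dreamed
concurrently once their blended inputs exist. Frame-rate and source
resolution (16 fps, 4096 × 2048 for the original panoramic footage) are
carried as metadata only. Frames are dreamed whole; tiling very large
panoramas is future work.

## Statistics

**JZS Bayes factor.** Cauchy(0, r) prior on the standardized effect,
r = √½ (the conventional "0.707") by default. The marginal likelihood under
H1 is computed through the scale-mixture representation
δ | g ~ N(0, g r²), g ~ InvGamma(½, ½), giving a one-dimensional integral
over g; the integrand is evaluated in log space (shifted by the null
log-likelihood so the integral is the Bayes factor directly, which survives
very large t), transformed to (0, 1) by g = u/(1−u), and integrated with
adaptive quadrature at 1e−8 relative tolerance; non-convergence raises with
diagnostics rather than returning a number. The implementation is
cross-checked in tests against an antithetic Monte-Carlo integral over the
Cauchy prior (noncentral-t likelihood ratios), and against published values
recomputed from printed (t, n) pairs — all within the 1 % that rounding of
a printed t permits. BF10 is symmetric in the sign of t and strictly
increasing in |t|.

**Effect sizes.** d = t/√n (paired; identical to mean(diff)/sd(diff)) and
d = t·√(1/n₁+1/n₂) (independent, pooled). The pooled equal-variance design
is pinned by the published degrees of freedom (12 + 15 − 2 = 25).

**Bonferroni.** p·m capped at 1 by default; an uncapped mode exists because
some published tables print the raw product. The default multiplier is the
number of dimensions tested (17).

**Repeated-measures ANOVA.** Cell means per subject × factor-A ×
factor-B; the classical within-subject decomposition with a separate
subject-by-effect error stratum per effect. η² is reported as partial η²
(the common statistics-package default), with classical η² available in the
same result. Sums of squares are verified against a brute-force
mean-decomposition oracle and against an independent implementation
(pingouin), and total SS conservation holds to 1e−10 relative. Missing
cells are an error; no imputation.

**Screening rules.** Practice blocks pass when Pearson r(target, produced)
≥ 0.5 (zero-variance production fails with a reason). A participant whose
per-target means are not *strictly* increasing with target duration is
excluded as temporally inverted; ties are excluded under the conservative
reading.

## Synthetic data

- **Video:** a smoothed random background (cyclic smoothing, so frame edges
  are seam-continuous like panoramic footage) with a textured patch
  translated by an integer (dx, dy) per frame; ground-truth flow is exact by
  construction. It emulates locally translating texture only — no
  occlusion, lighting change, rolling shutter or non-rigid motion — so flow
  tests certify estimator behaviour in the easy regime the blending rules
  assume, not real-footage robustness.
- **Ratings:** per-dimension paired samples on a [0, 100] visual-analog
  scale (the scale bound is this package's assumption; conventional VAS)
  with a specified standardized effect δ on the difference distribution,
  clipped to bounds. Recovery tests use the Hedges-corrected estimate,
  since raw sample d at n = 12 carries the known ≈ 7.5 % small-sample bias.
- **Timing:** produced = target·(1+bias) + N(0, (w·target)²) truncated
  positive — scalar timing with Weber fraction w (defaults w = 0.15,
  bias = 0; targets 1/2/4 s cued by 220/440/1760 Hz tones, metadata only,
  no audio rendered). Defaults use 21 subjects to match the published
  design size.

All generators are pure functions of their spec (seed included).

## Problem sizes used in tests

Gradient checks run at 16×16, dreaming tests at 32–64 px with the full
default iteration count, and end-to-end runs at 8 frames of 64×64 — sizes
at which the complete suite exercises every default parameter while
remaining a desk-scale artifact. The statistics are exact-scale: they
reproduce the published analyses at the published n.

## Known limitations

- The toy network is untrained; dreamed imagery has hallucination-like
  *structure* (layer-dependent texture amplification) but not the semantic
  content a network trained on natural categories produces. Full-scale use
  requires an external pretrained model via the adapter contract.
- The flow estimator has no occlusion reasoning or bidirectional
  consistency masking.
- Bayesian model-averaged repeated-measures ANOVA (as produced by
  point-and-click Bayesian packages) is out of scope; the classical RM-ANOVA
  and the per-comparison JZS tests are provided.
- Published Bonferroni-corrected p-value columns that are not the product
  p·m for any single integer m cannot be — and are not — reproduced.
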