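# Methods

## The problem

Head motion during a line-by-line MR acquisition corrupts only the k-space
lines acquired after the movement. Reconstructing the mixed k-space
produces ghosting and streaking along the phase-encode direction.
Supervised artifact-reduction networks need large sets of *paired* images
(identical anatomy with and without artifact), which real scanners cannot
provide. This package manufactures such pairs by simulating the corruption
process on clean volumes.

## Motion-corruption model

For each slice `z` of a clean volume `V`:

1. A random schedule of `m ~ U{2..4}` rigid-motion events is drawn. Each
   event has an onset line `o_k` (uniform, without replacement, over the
   lines strictly after `⌊n/2⌋`, sorted ascending), a rotation triple
   `θ ~ U[−5°, +5°]³` and a translation triple `t ~ U[−10, +10]³` pixels.
2. The motion states are cumulative: state `k` is state `k−1` rigidly
   moved by event `k` (rotation about the volume centre in fixed order
   x→y→z, then translation; trilinear interpolation, zero fill outside the
   field of view). The subject never returns to a previous pose.
3. Slice `z` is extracted from the clean volume and from every motion
   state, each is transformed to centred 2D k-space, and the composite
   k-space takes each phase-encode line from whichever state was active
   when that line was acquired (linear ordering, one line per TR).
4. The inverse FFT of the composite, followed by the complex magnitude,
   is the artifact image. The signed residual map is `artifact − clean`.

Because the first onset lies strictly beyond half of k-space, the DC line
and everything acquired before it stay motion-free: the low-frequency
contrast of the image is preserved and the corruption is recoverable, which
is what makes the pairs usable as training data. Note the constraint
protects the *acquired-first* half; the line immediately after the DC line
may legitimately be corrupted.

Every slice of a volume receives its own independent schedule (rng stream
derived from `(seed, slice index)`, so single-slice and whole-volume runs
agree bit-for-bit). A shared-schedule mode reproduces whole-volume motion
instead.

Design choices where the protocol is open, and why:

- **Rotation order x→y→z about the centre** — some fixed convention is
  needed for reproducibility; the choice is irrelevant at ±5° to the
  statistics of the artifacts.
- **Linear (top-to-bottom) acquisition ordering, echo-train length 1** —
  with linear ordering the half-of-acquisition onset constraint protects
  the k-space centre, which is the stated purpose of that constraint.
  Centric ordering and `echo_train_length > 1` (onsets snapped to
  echo-train boundaries) are available options.
- **Magnitude reconstruction** — composed k-space is not conjugate
  symmetric, so the inverse transform is complex; MR images are magnitude
  images. Taking the real part instead is an option.
- **Signed residuals** — `clean + residual == artifact` must hold exactly
  for residual-mode correction to be an algebraic identity; the artifact
  array is re-derived as `clean + residual` at storage precision so the
  identity is bit-exact.
- **Cumulative resampling by default** — transforming the previous,
  already-interpolated state mirrors the sequential physical process but
  compounds interpolation blur; a composed-transform mode (single
  resampling from the original under the algebraically composed rigid
  motion) is provided as the sharper alternative. The two agree exactly
  for integer translations.

## Synthetic phantom

The phantom is a stack of axial slices containing nested ellipsoids:
background 0.0, gray-matter-like shell 0.6, white-matter-like core 0.4,
and a small bright CSF-like region 0.95, plus additive Gaussian noise
(default sd 0.01) clipped to [0, 1]. The bright class matters: on
T2-weighted contrast, high-intensity CSF/eyeball signal is what drives the
visible ghosting and the performance gap between correction modes.

What the phantom does **not** emulate: anatomical texture and cortical
folding, Rician magnitude-noise statistics (Gaussian is used so metric
oracles stay closed-form), partial-volume effects, bias fields, and
through-plane anatomy changes at the scale of real brains. Tests passing
on phantoms therefore validate the *simulation machinery, bookkeeping and
learning plumbing*, not clinical performance.

## Dataset protocol

Volumes are intensity-normalized (division by the volume maximum, so peak
signal is exactly 1) and windowed to 50 contiguous slices centred on the
middle slice by default. The reference centring on the slice with the
best-visible lateral ventricles is an anatomical judgment; the package
offers an explicit `center_index` and a bright-area heuristic (area above
the 95th intensity percentile — a CSF proxy) as reproducible surrogates.

200 volumes × 50 slices give 10,000 pairs; the deterministic shuffled
split assigns `⌊0.1·N⌋` to validation, `⌊0.2·N⌋` to test and the rest
(70% plus any remainder) to train — 7000/1000/2000 at N = 10,000.
Slice-level splitting matches those counts; an optional subject-level mode
avoids cross-partition anatomy leakage. Pairs are stored as float32 stacks
in one HDF5 container with the split manifest.

## Quality metrics

RMSE, PSNR (`10·log10(S_peak²/RMSE²)`, with `S_peak` defaulting to the
reference-image maximum), Pearson CC, and the universal image quality
index computed globally over the frame (no sliding window, matching the
printed global formula). All SDs are population SDs. PSNR of identical
images is reported as an `inf` sentinel and excluded from aggregates
rather than raising mid-batch. Reference-free evaluation segments an image
into k = 4 intensity classes with k-means (labels re-indexed by ascending
cluster mean; cluster 0 = background/air, cluster 2 = gray-matter-like by
default) and reports COV = σ_b/μ_b and CNR = (μ_t−μ_b)/√(σ_t²+σ_b²).
Aggregates are mean ± SD with optional two-sided paired t-tests between
two correction methods.

## Correction network

A U-Net-style encoder–decoder: per contraction level two 3×3 convolutions
each followed by ReLU and batch normalization, then stride-2 max pooling;
64 feature maps at the first level, doubling per level (depth 4 → 64, 128,
256, 512, bottleneck 1024); the expansion path uses stride-2
transposed-convolution upsampling, halves the channels, concatenates the
matching skip connection and applies two convolutions; a final 1×1
convolution emits the image. Loss is L2 (MSE), optimizer Adam, reference
learning rate 0.0005 and 300 epochs. The layers and backpropagation are
implemented directly in NumPy (im2col convolutions); gradients are
verified against numerical differentiation in the test suite.

Two dataset modes: *direct* (artifact → clean) and *residual* (artifact →
residual map; corrected = artifact − predicted residual, clipped to ≥ 0).

### Desk scale

The reference regime (256×256, 7000 training pairs, depth 4/base 64, 300
epochs) is expressible but is not what the tests run. The routine
configuration used throughout tests, examples and the acceptance script is
20 pairs at 64×64, depth 2, base 8, batch 4, 300 epochs, Adam step 2e-3.
The larger step size is a deliberate desk-scale choice: with only ~4
gradient steps per epoch, the reference step of 5e-4 does not converge
past the identity baseline within 300 epochs, while 2e-3 does for both
modes; both modes always receive identical budgets so the mode comparison
stays fair. At this scale both modes reduce held-out RMSE below the
uncorrected artifact level and residual mode matches or beats direct mode
— the directional finding, not the full-scale effect sizes, which require
the real 7000-pair/300-epoch regime.

A caveat measured across repeated desk-scale runs: residual mode beats the
uncorrected baseline at every seed tried, but direct mode is marginal — at
some seeds its own reconstruction error exceeds a mild artifact level
(mean artifact RMSE ≈ 0.035–0.06 on these phantoms), so it can land above
the baseline. This is coherent with the mode comparison itself: a direct
network must reproduce the entire image, which 20 training pairs support
only barely, while the residual target carries artifact information alone.
Quantities computed by `scripts/acceptance.py` at an arbitrary seed should
be read with this variability in mind.

## Numerical notes

- FFTs use the centred convention `fftshift ∘ fft2 ∘ ifftshift`; Parseval
  ratio under this convention is `Σ|image|² = Σ|kspace|²/N`.
- Rigid resampling uses `scipy.ndimage.affine_transform`; order-1
  (trilinear) interpolation by default, spline orders optional with
  negative overshoot clipped to 0.
- k-means uses scikit-learn with a fixed `random_state`; determinism is
  asserted in tests.
- Degenerate inputs fail fast: all-zero volumes cannot be normalized,
  constant images have no CC, empty masks no COV/CNR, and PSNR needs a
  positive peak.

## Known limitations

- Motion is inter-line only: no intra-line (continuous) motion, spin
  history, B0 or coil effects.
- 2D (slice-wise) k-space corruption only; no 3D-encoded acquisitions.
- The phantom's simplicity makes the learning task easier than real
  anatomy; desk-scale results are directional evidence only.
- Repeated cumulative resampling slightly blurs later motion states;
  the composed mode trades physical sequentiality for sharpness.
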