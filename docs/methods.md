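# Methods

## Model

The codec factorizes an image over its 2×2 polyphase lattice. With 1-based
indexing, subimage A = odd rows/odd columns (the top-left pixel of every
2×2 block), B = odd/even, C = even/odd, D = even/even. Odd image dimensions
are edge-replicated to even before splitting; two header flags plus the
original dimensions let the decoder crop, so decompose→recompose is a
bijection for every size ≥ 1×1.

A is coded by a conventional lossless base codec. D, B and C are coded
sequentially by three *independent* networks (no shared parameters) whose
inputs are the previously coded subimages: {A}→D, {A,D}→B, {A,D,B}→C. This
order follows the observation that prediction quality improves with
context: D is predicted from the least information and costs the most bits,
C from the most and costs the least. Each network produces, from one pass
over a shared latent grid (the Middle Matrix), a real-valued pixel
prediction and a 511-way softmax probability field for the offset residual
classes `q = (y − ŷ_int) + 255`.

Losslessness is structural: the prediction is integerized *before* the
residual is formed (round half-away-from-zero, clip to [0,255]), so the
residual is an exact integer difference in [0,510] and reconstruction
`y = ŷ_int + q − 255` is an algebraic identity. Rounding a floating-point
residual instead would tie losslessness to rounding conventions; the
integer-first formulation removes that risk while preserving the 511-class
range. The test suite verifies the identity exhaustively over all 65,536
scalar (real, prediction) pairs.

## Architecture

The published idea fixes the heads (pixel prediction + four-scale U-Net
with skip connections and a 511-dimensional softmax) but not the layer
inventory, so the fill-ins here are deliberately canonical and all sit
behind `NetworkConfig`:

* residual block: two 3×3 convolutions with an additive skip (1×1
  projection when channel counts change), ReLU activations;
* downward process: stride-2 3×3 convolution, then residual block(s);
* upward process: nearest-neighbour ×2 upsampling, 3×3 convolution,
  concatenation of the matching encoder scale, then a residual block;
* channels double per scale, capped at 512; defaults `base_channels=64`,
  `n_scales=4`, `resblock_depth=1`.

The Middle Matrix consists of `base_channels − 1` learned feature channels
plus one deterministic *DC channel* holding the mean of the input
subimages. The pixel head (3×3 conv → ReLU → 1×1 conv) adds the DC channel
to its output, i.e. it predicts a correction to the neighbour average
rather than an absolute intensity — the standard predict-then-correct
structure of lifting-style codecs. This removes the intensity-scale burden
from training: an untrained head already predicts the neighbour average,
and short training runs reach sub-gray-level accuracy instead of carrying
a systematic bias of a few levels.

U-Net inputs are mirror-padded to a multiple of `2^n_scales` and outputs
cropped back, so any subimage size (including 1×1) is accepted; the mirror
fold has an exact adjoint used during backprop. Inference runs in float32
with plain deterministic NumPy kernels, so encoder and decoder predictions
are bit-identical on the same machine — the property the sequential decoder
relies on. The networks, their backward passes (verified against central
finite differences) and Adam are implemented in NumPy inside the package.

## Losses and weight schedule

`L_SPL` is the mean absolute deviation of the pixel prediction; `L_PPL` is
weighted cross-entropy over the realized residual classes with the
probability floored at 1e-12 inside the log; the total is
`λ_SPL·L_SPL + λ_PPL·L_PPL` with both λ defaulting to 1. Loss values are
accumulated in float64 so the unit-weight case matches plain cross-entropy
to 1e-9.

The weight schedule is a symmetric staircase over the class axis:
8 on [0,99] and [411,510], 4 on [100,149] and [361,410], 2 on [150,199] and
[311,360], 1 on [200,310]. The two anchor bands (8 for the very rare large
residuals, 1 for the common small ones) are fixed by the method; the
intermediate steps are this package's choice, constrained to be symmetric
about class 255 and non-decreasing in |class − 255|, and fully
user-overridable. (A schedule with a 2-band at [301,360], sometimes written
down for the right flank, cannot satisfy the symmetry constraint; the
[200,310] centre band is the symmetric completion of the stated anchors.)

Training supervises each network on its own subimage with ground-truth
inputs — legitimate because coding is lossless, so decoder-side inputs
equal ground truth. The residual-class targets are recomputed from the
current integerized prediction each step and treated as constants (no
gradient flows through the argmax-free integerization). The three networks
are trained side by side on the same batches but are otherwise independent.
Defaults are the full-scale recipe (batch 24, 2000 epochs, lr 1e-3 halved
every 500 epochs, 128×128 patches); the smoke-scale runs used by the tests
and the acceptance script use a small network (8 base channels, 2 scales),
16×16 patches, batch 8, 20 epochs of 40 patches (≈100 Adam steps per
network) at lr 5e-3 halved every 10 epochs — enough for the residual
histogram of smooth synthetic images to peak exactly at class 255.

## Entropy coding

Each pixel's 511-way probability vector is quantized to integer counts
summing to 2^16 by largest-remainder rounding (stable tie-break on class
index), with every class floored at one count so any residual remains
encodable; the shortfall is borrowed from the heaviest classes. Pure
largest-remainder rounding keeps the L1 error below 511·2^−precision; the
floor repair adds at most two counts of error per starved class.

Symbols are coded by a byte-oriented, carry-propagating range coder
(32-bit range, renormalization below 2^24, LZMA-style deferred-carry byte
output), specified bit-exactly in `FORMAT.md`. Flush overhead is ≤ 48 bits
per payload and renormalization truncation ≈ 0.007 bit/symbol, comfortably
inside the 64 + 0.01·n bound the tests assert. The tests cross-check the
coder against an exact big-integer arithmetic coder on short instances.
CDF precision is configurable in [10, 24] bits; below 10 bits 511 classes
cannot all receive mass, above 24 the coder's `range//total` would lose
resolution.

## Container

`FORMAT.md` specifies the 64-byte little-endian header (magic, version,
padding flags, base codec id, CDF precision, dimensions, model hash, pixel
checksum, payload lengths) and the four payloads A, D, B, C. The model
hash (SHA-256 over configuration and parameters) is checked before any
pixel is decoded; the pixel checksum is checked after recomposition, so
every decode self-verifies losslessness. The encoder also self-checks the
base codec by decoding its own A payload and refuses a non-lossless base.

## Synthetic data

Tests and the acceptance script use five deterministic generator families:
constant fields, monotone ramps (strictly monotone row means up to ~127
rows), soft Gaussian blobs, i.i.d. uniform noise, and a CT-like phantom
(bright elliptical rim, mid-intensity interior with lesion-like disks,
additive Gaussian noise, default σ=2). Together they cover both regimes a
learned predictor meets: smooth content it can predict to sub-gray-level
accuracy and noise it cannot. They do not reproduce the acquisition
physics, bit-depth quirks or anatomy of real CT/X-ray data, so passing
tests demonstrate the codec's *contracts* (losslessness, coder efficiency,
residual concentration on predictable content) rather than clinical-data
rates; the CLI accepts any user-supplied image directory for real-data
evaluation.

## Numerical choices and edge cases

* Rounding is half-away-from-zero everywhere (one explicit convention;
  avoids platform-dependent half-even behaviour).
* Probability floor 1e-12 inside the log; per-pixel softmax sums are within
  1e-5 of 1 in float32.
* Mirror padding degenerates to edge replication for axes shorter than the
  pad (1-pixel subimages through a 4-scale U-Net are legal).
* RGB inputs are reduced to BT.601 luma, rounded half-away-from-zero.
* Degenerate inputs raise typed errors: empty images, mismatched grids,
  out-of-range classes, non-finite predictions, truncated or tampered
  streams, model-hash mismatches.

## Known limitations

* Inference is NumPy on CPU; rates and speeds at full 64-channel,
  four-scale size are not evaluated here, and the desk-scale BPP numbers
  printed by the examples should not be read as benchmark results.
* Determinism is guaranteed within a machine/BLAS build, not across
  heterogeneous hardware; decode on the encoding machine (or an identical
  software stack) to be safe.
* Single-frame, single-channel, 8-bit only; no tiling for gigapixel
  images, no DICOM parsing, no adaptive (context-updating) entropy coding.
* The ablation harness compares plain vs weighted cross-entropy at reduced
  scale and asserts only the report's structure — at smoke scale either
  variant may produce the lower rate.
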