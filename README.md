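# graylift

Learned lossless compression of 8-bit grayscale images — the kind of
single-channel material (CT slices, X-rays, scientific captures) where
every gray level must survive the round trip exactly.

## How it works

An image `x ∈ [0,255]^{W×H}` is split on its 2×2 sampling lattice into four
half-resolution *polyphase subimages* A, B, C, D (A holds the odd-row,
odd-column pixels, 1-based). Subimage A is coded with a conventional
lossless codec (PNG by default; JPEG-XL when `cjxl`/`djxl` are installed).
The other three are coded in the fixed order D, B, C: for each, a
convolutional network takes the already-coded subimages and, in **one
forward pass** over a shared latent grid (the *Middle Matrix*), emits

* a pixel prediction `ŷ` of the target subimage, and
* a per-pixel probability vector over 511 *residual classes* from a U-Net
  head with skip connections and a softmax output.

The prediction is rounded (half away from zero) and clipped, and the
residual is offset into nonnegative classes

```
q = (y − ŷ_int) + 255 ∈ {0, …, 510},
```

which a static range coder compresses under the per-pixel model. The
decoder reruns the identical deterministic inference on the subimages it
has already decoded, so it reconstructs `y = ŷ_int + q − 255` exactly:
losslessness is structural, holds for untrained networks, and is verified
by a pixel checksum stored in the container (see `FORMAT.md`).

Training minimizes `L = λ_SPL·L_SPL + λ_PPL·L_PPL` with

```
L_SPL = (1/N) Σ_i |y_i − ŷ_i|                      (mean absolute error)
L_PPL = −(1/N) Σ_i w_{q_i} · log p̂_i(q_i)          (weighted cross-entropy)
```

Because a decent predictor pushes almost all residuals into a narrow band
around class 255, plain cross-entropy starves the rare classes; the weights
`w` counter that imbalance (8 on classes 0–99 and 411–510, 1 on 200–310,
a symmetric 4/2 staircase between). Defaults: Adam, batch 24, 2000 epochs,
learning rate 1e-3 halved every 500 epochs, random 128×128 patches,
λ_SPL = λ_PPL = 1.

## Worked example

`examples/02_train_and_stats.py` trains a small bundle for 20 short epochs
(~100 Adam steps per network) on smooth synthetic images, then compresses a
32×32 synthetic ramp:

```
total loss: 58.89 (epoch 1) -> 5.60 (epoch 20)
residual histogram mode: class 255 (255 = zero residual)
per-subimage bpp: B=0.422, C=0.391, D=2.070
base (PNG on A): 0.609 bpp, header: 0.500 bpp
total: 3.992 bpp
```

The mode at class 255 means the trained predictor gets most pixels exactly
right; D (predicted from A alone) is the most expensive subimage and C
(predicted from A, D, B) the cheapest, reflecting how much context each
network sees. The parts sum to the total container rate, and 8.0 bpp would
be the uncompressed rate. `examples/01_compress_roundtrip.py` shows the
bit-exact round trip with an *untrained* bundle;
`examples/03_entropy_coder.py` exercises the range coder alone.

## Command line

```
graylift train --config cfg.yaml --data images/ --out model.npz
graylift compress  scan.png scan.glc --model model.npz [--base-codec png|jxl]
graylift decompress scan.glc out.png --model model.npz
graylift verify scan.png --model model.npz      # round trip + bpp
graylift stats  scan.png --model model.npz      # residual histogram, bpp table
```

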