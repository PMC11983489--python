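# benet

Boundary-aware segmentation of microscopic hyperspectral pathology images
(MHSIs), guided by information-entropy weighting.

MHSI cubes (H×W pixels × tens of correlated spectral bands) carry both the
spatial structure and the spectral fingerprint of tissue, but lesion
boundaries are frequently blurred, broken, or confounded by isolated
lesion-like structures in the background. **BE-Net** is an encoder–decoder
network for binary lesion segmentation in this setting. It is a
quarter-width U-Net (stage widths 16–256, inputs reduced to 2 bands by PCA)
whose distinctive pieces are:

- **LoGC** — a 5×5 convolution whose learnable kernel is gated elementwise
  by a fixed discretized Laplacian-of-Gaussian matrix
  `LoG(p,q,σ) = 1/(πσ⁴)((p²+q²)/(2σ²) − 1)·e^{−(p²+q²)/(2σ²)}`,
  biasing the layer toward second-derivative (edge) structure;
- **CEA** — channel attention `W_c = 1 − H/log 2`, where H is the entropy
  of the softmaxed (global-max, global-mean) pair of a channel: constant
  channels are suppressed, sharply-responding channels kept;
- **SEA** — spatial attention `W = H/log C` from the per-pixel entropy of
  the softmaxed channel vector: uncertain, boundary-like pixels are
  emphasized;
- **LCB / GMB / MSB** — the encoder block (LoGC + 3×3 conv + CEA), the
  grouped multi-scale skip-fusion block (four group convolutions at
  dilations/sizes 3×3 d2, 3×3 d3, 1×1, 3×3, summed, ReLU, CEA), and the
  decoder boundary block (dilated-conv cascade Y, sigmoid gate, multi-scale
  max-pool weight W1, entropy weight W2, output `(W1+W2)⊙Y + Y`).

Training uses SGD (momentum 0.9, weight decay 1e−6, batch 4) with the loss
`0.3·CE + 0.7·(1 − soft Dice)`, and evaluation reports OA, DSC, IoU,
Precision, Specificity and Sensitivity with five-fold cross-validation.
Because the original pathology datasets are not redistributable, the
package ships a synthetic MHSI phantom generator (two overlapping spectral
signatures, blob lesions, boundary blur, background distractors,
band-correlated noise) so every pipeline stage is exercisable end to end.

The whole stack — including a compact reverse-mode autodiff core — runs on
numpy/scipy on a single CPU; there is no deep-learning-framework
dependency.

## Worked example

Train BE-Net on easy phantoms (16 training / 8 validation cubes, 64×64×8
reduced to 2 PCA bands):

```python
from benet import (build_benet, easy_phantom_params, generate_phantom_set,
                   pca_reduce, to_arrays, train, TrainConfig, evaluate)

params = easy_phantom_params(size=64, bands=8)
cubes, masks = generate_phantom_set(params, 24, seed=123)
reduced = pca_reduce(cubes, n_components=2, fit_indices=range(16))
train_xy = to_arrays(reduced[:16], masks[:16])
val_xy = to_arrays(reduced[16:], masks[16:])

model = build_benet(seed=11)
history = train(model, train_xy, TrainConfig(epochs=6, seed=11, lr=0.01),
                val_data=val_xy)
report = evaluate(model, *val_xy)
```

This prints (via the history entries and final report):

```
epoch 0  loss 0.892  val DSC 0.000  val IoU 0.000
epoch 1  loss 0.278  val DSC 0.000  val IoU 0.000
epoch 2  loss 0.141  val DSC 0.000  val IoU 0.000
epoch 3  loss 0.116  val DSC 0.000  val IoU 0.000
epoch 4  loss 0.090  val DSC 0.867  val IoU 0.765
epoch 5  loss 0.062  val DSC 0.964  val IoU 0.931
final: DSC 0.964  IoU 0.931  OA 0.982
```

The loss falls steadily from the first epoch; validation scores stay at
zero for a few epochs while the BatchNorm running statistics catch up with
the rapidly-moving training distribution, then jump once eval-mode
normalization is calibrated. A validation Dice of 0.96 on held-out phantoms
means the network reproduces the lesion masks almost exactly.

Model complexity from the CLI:

```sh
$ benet complexity --model benet --input 64
{
  "n_params": 3757186,
  "n_params_millions": 3.757,
  ...
}
```

The default BE-Net has 3.757M trainable parameters; the full-width U-Net
comparison model (`--model unet`) has 34.52M — roughly nine times more —
and about eleven times the convolution MACs at equal input size.

Other CLI verbs: `benet phantom` (write a phantom dataset + manifest),
`benet train`, `benet eval`, `benet predict`, `benet cv` (five-fold
cross-validation; see `--help` for each).

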