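# wmtseg

Binary segmentation of medical-style images with a **weighted (gated)
axial-attention transformer** — built for the small-dataset regime where
ordinary transformers struggle because their relative positional encodings
never get enough data to train well.

Plain 2-D self-attention over a `C×H×W` feature map,

```
y_ij = Σ_hw softmax(q_ijᵀ k_hw) v_hw ,     q = W_Q x,  k = W_K x,  v = W_V x,
```

costs (HW)² per map.  Axial attention splits it into a height pass and a
width pass with learnable relative positional encodings `r^Q, r^K, r^V`:

```
y_ij = Σ_w softmax(q_ijᵀ k_iw + q_ijᵀ r^Q_jw + k_iwᵀ r^K_jw) (v_iw + r^V_jw),
```

so each position attends to H + W keys instead of H·W.  The *weighted*
operator adds four learnable scalar gates,

```
y_ij = Σ_w softmax(q_ijᵀ k_iw + C_Q q_ijᵀ r^Q_jw + C_K k_iwᵀ r^K_jw)
           (C_V1 v_iw + C_V2 r^V_jw),
```

initialized to 1, letting a network trained on a few hundred images learn
to down-weight positional terms it cannot estimate reliably.

These layers form the encoder of a U-Net, and the full model ("wmt") adds
a coarse/fine fusion head: the image is processed as 4 blocks of side I/2
(coarse branch — preserves inter-block boundary context) and as 16 blocks
of side I/4 (fine branch — captures intra-block detail); each block runs
through a per-branch encoder–decoder, block outputs are reassembled, the
two maps are summed, and a 1×1 convolution yields the mask logits.
Training minimizes mean pixelwise binary cross-entropy; evaluation reports
F1 (Dice), IoU, and pixel accuracy.

Five architecture rungs build from one config — an ablation ladder from a
plain U-Net up to the full model (parameter counts at equal depth/width
are strictly ordered `unet_axial < unet_weighted_axial < unet < wmt <
unet_coarse_fine`):

| variant               | encoder blocks        | head        |
|-----------------------|-----------------------|-------------|
| `unet`                | double 3×3 conv       | 1×1 conv    |
| `unet_axial`          | axial attention       | 1×1 conv    |
| `unet_weighted_axial` | gated axial attention | 1×1 conv    |
| `unet_coarse_fine`    | double 3×3 conv       | dual-branch |
| `wmt`                 | gated axial attention | dual-branch |

Everything runs on a small numpy reverse-mode autodiff core included in
the package (`wmtseg._tensor`): float64, CPU, exactly the operator set the
model needs.  A built-in phantom generator (`wmtseg.synthetic`) produces
organ-like (one large smooth region) and nuclei-like (many small blobs)
image/mask datasets so the whole pipeline is trainable and testable with
no downloads.

## Worked example

Overfit the full model on four 32×32 organ phantoms — the standard sanity
check that the architecture, gradients, and optimizer all cooperate:

```python
from wmtseg import PhantomSpec, SegmentationModel, TrainConfig, generate

data = generate(PhantomSpec(mode="organ", side=32, n_images=4, seed=3))
sm = SegmentationModel(variant="wmt", input_side=32, base_channels=8,
                       depth=2, seed=1)
res = sm.fit(data, train_config=TrainConfig(epochs=200, lr=1e-3,
                                            schedule="constant",
                                            batch_size=4, seed=0))
print(res.summary(dataset=data))
```

```
Segmentation model results
==============================================
variant:            wmt
input side:         32
depth / base chans: 2 / 8
parameters:         44185
epochs trained:     200
initial loss:       0.55233
final loss:         0.01790
F1:                 0.9890
IoU:                0.9784
accuracy:           0.9958
==============================================
```

The loss falls from 0.55 (near-chance pixel predictions) to 0.018, and the
model reproduces the four training masks almost exactly (IoU 0.978) —
about two minutes on one CPU core.  `res.predict_mask(image)` returns a
binary mask; `res.save(path)` / `SegmentationModel.from_checkpoint(path)`
round-trip the trained weights with their architecture config embedded.

The same pipeline from the shell:

```bash
wmt synth --out data --mode organ --n-images 8 --side 32 --seed 0
wmt train --data data --out run --variant wmt --epochs 200 --seed 0
wmt eval  --checkpoint run/checkpoint.npz --data data --out run/eval
wmt ablate --out ablation --epochs 30 --side 32 --seed 0   # 5-rung table
wmt predict --checkpoint run/checkpoint.npz --image data/images --out pred
```

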