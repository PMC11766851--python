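# ecatbrats

A CPU-friendly implementation of a channel-attention Swin-transformer model
for 3D brain-tumour segmentation in multi-modal MRI, together with its
training recipe, evaluation metrics, and a synthetic phantom generator so the
whole pipeline runs end to end without any external imaging data.

## Who this is for

Researchers and students who want a fully inspectable, dependency-light
implementation of a hybrid transformer/CNN segmentation architecture — every
layer, gradient and metric is plain numpy and can be traced, unit-tested and
verified against brute-force oracles.  It is **not** a production inference
engine: at full BraTS resolution the numbers are computed faithfully but
slowly.

## The model

Input is a 4-channel volume of co-registered MRI modalities (T1,
T1-contrast, T2, T2-FLAIR).  The targets are the three nested, overlapping
BraTS evaluation subregions: whole tumour (WT), tumour core (TC) and
enhancing tumour (ET), with ET ⊆ TC ⊆ WT.

1. **Shifted-window transformer encoder.**  A patch-partition module splits
   the volume into 2×2×2 patches which are linearly embedded; four stages of
   window-based transformer blocks (alternating regular and half-shifted 3D
   windows, learned relative position bias) with patch merging between
   stages produce a six-level feature ladder with channels
   (48, 48, 96, 192, 384, 768) at resolutions 1 … 1/32.
2. **Channel shuffling.**  Each of the five transformer-derived maps is
   shuffled: channels are reshaped into G groups (default G = 4, matching
   the four modalities; G = 2 supported), group and within-group axes are
   transposed, and the result is flattened — a parameter-free regulariser
   that mixes information across channel groups.
3. **CAT encoding blocks.**  All six maps pass through encoding blocks of
   the form conv3×3×3 (stride 1, pad 1) → batch norm → channel attention →
   LeakyReLU.  The attention module is squeeze-and-excitation style:
   per-channel global average pooling m_k = mean over all voxels of channel
   k, a bottlenecked pair of fully connected layers (reduction r = 4) and
   sigmoid gates that rescale each channel.
4. **Residual decoder + head.**  Five residual decoding blocks upsample 2×
   per axis, concatenate the skip feature map and refine through a residual
   convolution unit; a final 1×1×1 convolution with sigmoid emits three
   independent per-voxel probabilities (sigmoid, not softmax, because the
   subregions overlap).

Training minimises the Dice loss (1 − softDSC averaged over regions) with
AdamW and a single-cycle cosine-annealed learning rate

    lr_t = lr_min + ½ (lr_max − lr_min)(1 + cos(π E_curr / E_max)),

starting from lr_max = 5·10⁻⁵ by default.  Evaluation reports DSC, Jaccard
(IoU) and the Hausdorff distance per region as mean ± std tables.

Both novel components are ablatable from config flags (`--no-shuffle`,
`--no-attention`), reproducing the four study variants; shuffling is
parameter-free and attention adds exactly the closed-form FC parameter
count, which the test suite verifies.

## Worked example

`python examples/train_tiny_model.py` trains a narrow configuration (embed
dim 8, ~1.4 M parameters) on four 16³ synthetic phantoms for 120 epochs —
a few minutes on one CPU:

```
epoch   0  lr 1.00e-02  dice loss 0.8507
epoch  40  lr 7.50e-03  dice loss 0.0808
epoch  80  lr 2.50e-03  dice loss 0.0113
epoch 119  lr 1.71e-06  dice loss 0.0074

training-set evaluation (mean ± std over the 4 cases):
Metric    Region          mean ± std
DSC       Mean         0.999 ± 0.000
DSC       TC           0.997 ± 0.001
DSC       WT           1.000 ± 0.000
DSC       ET           1.000 ± 0.000
```

The loss falls from 0.85 (near-total mismatch) to <0.01 as the model
memorises its training set; the mean DSC of ~1.0 confirms the full pipeline
— phantom generation, encoder, shuffle, attention, decoder, loss, optimiser,
metrics — is wired correctly.  Other examples: `generate_phantoms.py`
(cohort generation and geometry), `architecture_tour.py` (feature ladder and
ablation parameter arithmetic), `metrics_demo.py` (metric behaviour under
noise).

## Command line

```bash
ecatbrats synth --out cohort/ --n 8 --seed 0        # phantom cohort + manifest
ecatbrats train --manifest cohort/manifest.tsv --out ckpt.npz --epochs 50
ecatbrats eval  --checkpoint ckpt.npz --manifest cohort/manifest.tsv --out report.csv
```

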