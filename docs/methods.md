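# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, which knobs matter, what the synthetic data does and does
not emulate, and where the design was genuinely open.

## Model

The network is a hybrid transformer/CNN for volumetric semantic
segmentation of glioma subregions in 4-modality MRI.  Its three parts:

**Encoder.**  A 3D shifted-window (Swin-style) transformer: 2×2×2 patch
partition with linear embedding (embed dim E, default 48), four stages of
window-based attention blocks with patch merging between stages.  Each merge
concatenates 2×2×2 neighbouring tokens (8C channels), layer-normalises, and
reduces linearly to 2C — so every merge halves each spatial extent and
doubles the width.  The resulting ladder over levels 0–5 is
(E, E, 2E, 4E, 8E, 16E) at resolutions 1, 1/2, …, 1/32; with E = 48 that is
(48, 48, 96, 192, 384, 768).  Six encoding (CAT) blocks but only five
transformer scales exist, so level 0 is produced by a per-voxel (1×1×1)
projection of the raw 4-channel input to E channels at full resolution —
the only wiring consistent with the block counts (5 shuffle, 6 CAT, 5
decoder) and the stated first-block width E at full resolution.

**Shuffle + CAT blocks.**  Channel shuffling (reshape channels to (G, C/G),
transpose, flatten; G = 4 by default, 2 supported) is applied to the five
transformer-derived maps before their encoding blocks; level 0 is not
shuffled.  Each CAT block is conv3×3×3 (stride 1, pad 1) → BatchNorm3d →
channel attention → LeakyReLU, preserving spatial extent.  Channel
attention is squeeze-and-excitation style: global average pooling per
channel — the 2D pooling formula extended to a mean over all of W×H×D,
since the network is volumetric — followed by two fully connected layers
(C → C/r → C, r = 4) and sigmoid gating.  Two FC layers were chosen (one
part of the source material describes one layer, another two); r is
configurable.  The inter-FC nonlinearity and all block activations are
LeakyReLU with slope 0.01.

**Decoder.**  Five residual decoding blocks: 2× upsampling (transposed
convolution with kernel 2/stride 2 by default; trilinear + 1×1×1 conv as an
option), concatenation with the CAT output one level shallower, then a
conv3-BN-LeakyReLU-conv3-BN main branch summed with a 1×1×1 projection
shortcut and passed through LeakyReLU.  The internal composition of these
blocks is not prescribed anywhere authoritative; this Swin-UNETR-style unit
is an informed default.  A 1×1×1 convolution with sigmoid yields the three
per-voxel subregion probabilities.  Sigmoid rather than softmax because
WT/TC/ET are nested, overlapping targets.

Predicted masks are obtained by per-channel thresholding at 0.5; nesting is
*not* enforced — a violation is surfaced as a QC flag, never silently fixed.

## Numerical core

The network runs on a small reverse-mode autodiff engine written on numpy
(`ecatbrats.nn`): a tape of operations over `Tensor` objects with explicit
adjoints for 3D convolution (stride 1, via sliding-window views), the
kernel-2/stride-2 transposed convolution, windowed softmax attention, layer
and batch normalisation and the usual pointwise maps.  Every adjoint is
verified against central finite differences in the test suite.  Parameters
are float32; optimiser moments are float64.

Geometry handling: window sizes are clipped to the token grid per axis;
token grids are right-padded to window multiples, with padded voxels given
unique attention-mask ids so they attend only themselves; shifted partitions
use a cyclic roll with the standard region-id mask; shifts are suppressed
along axes covered by a single window.  Patch merging zero-pads odd extents.
Consequently any input extent works; extents not divisible by 32 trigger a
warning (the canonical input geometry is 96×128×128, depth × height ×
width) and the decoder's crop/pad alignment restores the input grid.
Attention logits are computed in bounded window chunks (≈128 MB per chunk)
so full-resolution volumes fit in ordinary RAM.

Degenerate regimes worth knowing: at very coarse levels a window may hold a
single token, making its softmax trivially 1 and the relative position bias
inert; and batch normalisation over a single value (batch 1 at a 1³ level)
normalises to zero, blocking gradients there.  Neither affects the default
geometry; property tests that assert full gradient coverage use a batch of
two and windows holding more than one token at every level.

## Data model and preprocessing

Cases follow the BraTS layout: four co-registered NIfTI modalities plus an
integer label volume with codes {0: background, 1: necrotic core,
2: oedema, 4: enhancing tumour} (the code table is configurable, since only
the subregion names are canonical).  Labels expand to the overlapping
evaluation channels WT = 1∪2∪4, TC = 1∪4, ET = 4, which are nested by
construction; a malformed mask raises, it is never repaired silently.

Preprocessing: per-modality z-score over nonzero (foreground) voxels —
zero-variance channels map to zeros with a logged warning — then a centre
crop/zero-pad to the target geometry (default 96×128×128).  Cropping rather
than resampling keeps label topology exact and is the package's choice where
the published pipeline is silent.  Skull stripping, registration and
bias-field correction are assumed done upstream, as in the released
datasets.

## Synthetic phantoms

`ecatbrats.synthetic` generates 4-channel phantoms: background tissue at a
baseline intensity, three concentric (optionally ellipsoidal) subregions
whose radii satisfy r_WT ≥ r_TC ≥ r_ET, per-modality contrast offsets that
stack along the nesting, and additive Gaussian noise (salt-and-pepper
available to mimic lower-quality acquisitions).  Defaults — 64³ grid, radii
(14, 9, 5) voxels, background 1.0, noise σ = 0.1, and a contrast matrix
with FLAIR/T2 bright over the oedema-dominated WT, T1c bright over ET, T1
mildly hypointense — were chosen once to echo the qualitative appearance of
glioma MRI at a desk-friendly size.  Cohort generation jitters radii
(±30%), centre (±4 voxels), contrast (±20%) and optionally noise through a
single seeded generator; per-case noise seeds are derived as base seed + i,
so a zero-jitter cohort of one reproduces the base phantom bit for bit.

What the phantoms deliberately do **not** model: k-space artefacts, bias
fields, anatomy, partial-volume effects, inter-modality misregistration.
Passing tests therefore demonstrate that the architecture, optimisation and
metric machinery are correct and that the model can fit structured
multi-modal contrast — not that it segments real brain tumours at the
published accuracy; that requires the external cohorts and GPU-scale
training, which are out of scope here.

## Metrics

DSC = 2|G∩P|/(|G|+|P|), IoU = |G∩P|/|G∪P|, and the Hausdorff distance with
Euclidean distances in millimetres (voxel spacing applied; unit spacing when
absent).  The directed form max_g min_p d(g,p) is the printed definition;
reports default to the symmetric form (max of both directions), and a
95th-percentile variant is available since both conventions appear in
practice.  Edge policies, chosen because small enhancing tumours make them
reachable: DSC/IoU of two empty regions is 1; a Hausdorff distance with one
empty region returns a penalty (default: the grid diagonal) and flags the
case.  Aggregation reports per-region mean and *sample* standard deviation
(ddof = 1) over cases plus a "Mean" row averaging the three region means.

The Dice loss is the mean over region channels of 1 − softDSC with
softDSC = (2Σpt + ε)/(Σp + Σt + ε), ε = 1e−5 in numerator and denominator.

## Training

AdamW (decoupled weight decay 0.01, betas 0.9/0.999) minimises the Dice
loss under a single-cycle cosine schedule stepped once per epoch, from
lr_max (default 5·10⁻⁵) to lr_min (default 0; the source names lr_min but
never a value).  E_max equals the total epoch count — "maximum number of
epochs" in the source's schedule description is read as E_max, and plain
single-cycle annealing is implemented with warm restarts left out.  All
randomness (init, batch order, phantom noise) flows through seeded
generators; the same seed reproduces the loss history exactly.  Checkpoints
carry weights, running statistics, both configs and the history.

**Problem sizes used in tests and the acceptance script.**  The structural
and oracle checks run the default model (embed 48) at 32³ and the encoder
at the native 96×128×128; training properties use a narrow configuration —
embed dim 8, heads (2,2,2,2), window 4³ — on four 16³ phantoms (radii
6/4/2.5, σ = 0.05), batch 4, lr_max 1e−2 for 200 epochs.  These sizes were
chosen as the package's desk-scale reference experiment; the higher peak
learning rate suits the ~1.4 M-parameter model, which memorises its
4-phantom training set (train mean DSC ≈ 1.0), demonstrating the full
pipeline end to end.

## Known limitations

* Inference at full BraTS resolution is minutes per volume on CPU; there is
  no GPU path, no sliding-window inference, no test-time augmentation.
* The published benchmark accuracies on UCSF-PDGM / UPENN-GBM / EGD /
  BraTS 2021 are not reproduced here: they require the external datasets
  and GPU-scale training.  The report layout (per-region mean ± std for
  DSC/IoU/HD) mirrors that evaluation protocol.
* Batch normalisation statistics assume batches of whole volumes; very
  small batches at very coarse levels are noisy (see the degenerate regimes
  above).
* The phantom generator is geometric, not physical (no MR simulation).
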