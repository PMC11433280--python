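# Methods

## The model

The package implements a three-stage multi-task cascade for 2-D lung-CT
nodule patches:

1. **Coarse Seg-net** — a DeepLabv3+-style encoder/decoder whose encoder
   is an aligned-Xception backbone in which every down-sampling step is a
   stride-2 depthwise separable convolution (there is no max pooling
   anywhere in the graph).  The deepest features (output stride 16 by
   default) pass through an atrous spatial pyramid (rates 6/12/18 plus a
   1×1 branch and global image pooling); the decoder fuses them with
   stride-4 low-level features; a 1×1 convolution with a single output
   channel and a sigmoid produces the nodule probability map, bilinearly
   upsampled to input size.
2. **Fine Seg-net** — structurally identical, initialised as a bit-exact
   parameter copy of the trained coarse model, plus a *Fine-layer*: the
   coarse probability map is area-downsampled to the deepest feature
   grid, concatenated as one extra channel, and fused back to the
   original channel count by 1×1 convolution → batch-norm → ReLU.
3. **Class-net** — an Xception-style classifier whose exit flow keeps
   stride-16 resolution (the reference topology's final down-sampling
   stage is removed) with its last two separable convolutions dilated
   (rate 2, padding 2), ending in global average pooling and a single
   sigmoid malignancy unit.  Its input is the RGB patch concatenated with
   the coarse probability map; the fourth input-kernel slice is
   initialised as the elementwise mean of the three RGB slices.

Information flows between stages by *prediction distillation*: later
stages consume the coarse probability map as an extra input channel, and
no gradients flow between subnetworks.  The coarse model is trained
once and frozen; its maps are precomputed for the whole manifest before
the later stages train.

### Hybrid segmentation loss

Both segmentation nets minimise `L = L_Dice + γ·L_Rank` with

* Dice loss `1 − 2ΣPG / (Σ(P+G) + ε)`, per image, batch-averaged,
  ε = 1e-6;
* rank loss: per image, the K background pixels with the largest
  predicted probability and the K foreground pixels with the smallest
  are selected after the forward pass (error = |P − G|; ties broken in
  row-major scan order), and a pairwise hinge
  `(1/(K0·K1)) Σᵢ Σⱼ max(0, Hᵢ⁰ − Hⱼ¹ + margin)` forces every selected
  foreground probability above every selected background probability by
  `margin`.  Regions smaller than K contribute all their pixels, and the
  normalisation uses the effective K0·K1; an image lacking one region
  contributes 0.  Selection carries no gradient.

Defaults γ = 0.02, K = 20, margin = 0.3 (the published operating point of
the method).  The classifier minimises binary cross-entropy.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.02 | weight of the rank term in the hybrid loss |
| `k` | 20 | hard pixels selected per region per image |
| `margin` | 0.3 | required fg/bg probability gap (unitless) |
| `epsilon` | 1e-6 | Dice smoothing |
| `lr` | 1e-4 | Adam learning rate (full scale) |
| `batch_size_seg/class` | 16 / 32 | batch sizes |
| `max_epochs` | 100 | full-scale epoch budget |
| `width_multiplier` | 1.0 | channel scaling of every flow (floor 8) |
| `output_stride` | 16 | input/deepest-feature resolution ratio |

Model selection is by best validation Jaccard (segmentation) or accuracy
(classification); the learning rate is constant (no schedule); early
stopping is off by default (`patience=None`).

## Curation rules

Per-nodule reader scores (1–5) are aggregated by their median: ≤ 2
benign, ≥ 4 malignant, the indeterminate middle band is excluded.
Nodules with illegible IDs, diameter outside [3 mm, 25 mm], or
delineated by fewer than ⌈2/3·readers⌉ are excluded.  Pixel ground truth
is a ≥ 50 % majority vote over reader masks.  Both consensus thresholds
are config-exposed because curation conventions differ.  Patches are
64×64 crops centred on the nodule centroid (zero-padded at borders),
augmented 9× (random centre-crop 50–100 %, 110 % zoom, horizontal and
vertical flips, chosen uniformly per copy under a seed), resampled to
224×224 (bilinear image, nearest-neighbour mask), and split 6:2:2
stratified by class with all copies of one source kept in the same split.
Splitting happens on source identifiers, i.e. before augmentation can
leak across splits.

## Synthetic data

The generator emulates exactly the two features the cascade needs:
bright nodules with fuzzy boundaries on noisy background, and a
benign/malignant distinction carried by boundary smoothness (the
radiological spiculation sign).  Benign nodules are ellipses with axis
ratio ≤ 1.25; malignant nodules are star-shaped regions
`r(θ) = r0·(1 + a·max(0, sin(mθ + φ)))` with amplitude a = 0.5 and
m = 9 lobes.  Radii are 6–14 px on 64×64 patches, intensity 0.45–0.75
over a 0.25 background with σ = 0.08 Gaussian noise and σ = 1 px
boundary blur; the intensity range is identical for the two classes so
brightness alone cannot solve the classification task.  The isoperimetric
compactness (4π·area/perimeter²) of the two classes is separated by a
standardised mean difference of about 7.

What the generator does **not** model: CT texture, vessels, pleural
attachment, intensity heterogeneity inside nodules, 3-D context, reader
disagreement.  Passing desk-scale tests therefore demonstrates that the
implementation learns and that guidance plumbing works — not clinical
performance on real CT.

## Desk-scale study conditions

All stochastic end-to-end checks run under one fixed recipe
(`pipeline.desk_config`): 150 patches per class split 4:1:1 into
200 train / 50 validation / 50 test; width multiplier 0.125 with two
middle-flow blocks; 64×64 inputs; ≤ 10 epochs per stage; Adam at
lr 1e-3 (scaled up from the full-scale 1e-4 to match the narrow width
and short schedule).  The classifier's training split is additionally
replicated 4-fold by horizontal/vertical flips at load time, every
training batch receives a random translation of up to ±4 px
(zero-filled), and its Adam uses decoupled weight decay 1e-2 — together
the desk-scale counterpart of the offline 9× crop/zoom/flip
augmentation.  Without them a few hundred patches are memorised long
before the decision generalises (training loss collapses below 0.05
while held-out accuracy stalls near 0.7); with them training loss stays
above ~0.1 and held-out accuracy climbs past 0.9.  The segmentation
nets need neither.
The acceptance script runs this recipe once per seed; the test suite
runs a small number of paired seeds so the whole suite stays within a
routine CI budget (problem sizes are stated in the tests themselves).

## Numerical choices

* Probability maps are binarised at 0.5 with ≥ at the boundary.
* Empty-vs-empty masks score DI = JA = 1 (correctly predicted absence);
  an empty ground truth with a non-empty prediction is an error (recall
  undefined), as is a ground truth covering the whole image
  (specificity undefined).
* AUC is the Mann–Whitney statistic with half-credit ties.
* The coarse map enters the Fine-layer and Class-net as a raw
  probability field (not binarised), preserving uncertainty; it is
  stored as 8-bit PNG (quantisation step 1/255).
* Bilinear resizing uses half-pixel-centre sampling implemented as dense
  1-D interpolation matrices, making the backward pass the exact
  transpose of the forward.
* New layers are initialised from a truncated normal (±2σ) with He
  scaling; batch-norm starts at γ=1, β=0.
* Checkpoints store the full build spec and refuse to load into a
  mismatched architecture.

## Design choices where the design was open

* **"Same structure and parameters"** between the two segmentation nets
  is realised as copy-at-initialisation followed by independent
  fine-tuning, not hard weight tying — tied weights could not produce
  different coarse and fine outputs through the identical encoder path.
* **Ranking error definition**: |P − G| per pixel; hard pixels are
  selected per image and per-image rank losses averaged over the batch.
* **Unguided ablation arm**: the second-stage segmenter is trained and
  evaluated with a zeroed prior map, so guidance is the only difference
  between arms; the unguided classifier simply takes 3-channel input.
* **Fine-layer placement**: between the backbone's deepest output and
  the atrous pyramid, so the prior informs the pyramid as well as the
  decoder.
* **Grad-CAM** (gradient-weighted activation mapping) is used for
  visualisation because it needs no architectural changes; a constant
  feature response yields an all-zero heatmap rather than NaN.
* **Classification operating point**: accuracy is reported at a
  decision threshold calibrated on the validation split (the sigmoid
  score distribution of a small-sample classifier is often shifted, so
  a fixed 0.5 cut under-reports the accuracy its ranking supports);
  AUC is reported alongside as the threshold-free measure, and 0.5
  remains the default everywhere a threshold is not supplied.

## Known limitations

* On the synthetic task the prior-location guidance has little headroom:
  once training is strong enough to clear desk-scale accuracy, the
  unguided arms (zeroed prior map; 3-channel classifier) saturate too,
  so paired guided-vs-unguided differences sit within seed noise.  The
  guidance benefit reported for this architecture arises on real CT,
  where boundaries are fuzzy and backgrounds complex enough that the
  coarse prior adds information the patch alone does not; the generator
  does not reproduce that regime.

* CPU-only; the engine favours clarity over peak throughput and has no
  GPU path.
* 2-D patches only; no DICOM/volume ingestion (PNG contract instead).
* Pre-trained backbone weights are supported only through the
  3-channel-stem loading hook; no published pre-trained weights ship
  with the package.
* Desk-scale accuracy on synthetic data does not transfer to LIDC-IDRI
  numbers; reproducing those requires the external dataset and
  full-scale training.
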