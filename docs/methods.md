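# Methods

## Model

`glomil` classifies a 3D grayscale stack `x ∈ R^{H×W×D}` for two
independent binary labels (benign, malignant) using two cooperating
stages trained end-to-end from image-level labels only.

**Global stage.**  Every slice is encoded independently by a compact
residual 2D network with group normalization (8 groups).  Processing
slices independently — rather than with 3D convolutions — reflects the
targeted data: a tomosynthesis stack is not a true 3D image but a set of
reconstructed planes in which every structure appears on many slices
with varying focus, so per-slice encoding extracts the same evidence
without paying for 3D kernels.  Group normalization keeps all statistics
per-sample: features are identical whether a slice is encoded alone or
batched with the rest of its stack, and batch size 1 per device is
well-defined.

A 1×1 convolution (channels → 2) followed by `f_n(v) = ReLU(tanh(v))`
yields the saliency stack `A ∈ [0,1]^{h×w×D×2}`.  The 1×1 weights are
initialized to a constant `ω > 0` with zero bias.  The combination is
deliberate: at a constant-weight start the saliency is a monotone
function of the channel-sum of the (ReLU, hence nonnegative) encoder
activations, so locations that excite *any* channel are bright in the
map regardless of random sign draws; and `ReLU(tanh)` maps the near-zero
background logits to exactly zero while having its steepest slope at
zero, so the background needs no active suppression (a sigmoid would
pin it at 0.5).  A sigmoid `f_n` remains available as a configuration
option for A/B comparisons, not as a recommended setting.

**Top-t% pooling.**  The per-class global probability is the mean of the
`n` largest saliency entries with `n = round(t/100 · h·w)` — the
percentage refers to *one slice's* area, so `n` is independent of the
slice count (it is only floored at 1 and capped at the plane size
`h·w·D`, which matters only for very large `t` on very shallow stacks).
This keeps the training signal consistent across stacks of different
depths: two stacks containing the same lesion pool the same number of
values whether they have 50 or 80 slices.  Rounding is
half-away-from-zero; ties at the n-th rank do not affect the mean, and
the pooled block is summed in ascending sorted order so the result is
bit-identical to a full-sort reference.

**Greedy retrieval.**  The two class maps are min-max normalized
(a constant map normalizes to zeros) and summed into a criterion map.
`K` times, the single-slice rectangle of the patch footprint maximizing
the summed criterion is selected — ties break to the lexicographically
smallest (slice, top, left), making inference a pure function of its
inputs — and the criterion is zeroed over the selected (row, col)
footprint across the ±ζ neighboring slices, so the next pick cannot be a
near-duplicate of the same structure on an adjacent slice.  During
training, each selected slice index is resampled uniformly from the same
±ζ window (clipped at the stack boundary) as a depth-jitter
augmentation; with ζ = 0 this reduces exactly to inference-mode
selection.  Rectangle criteria are evaluated with per-slice summed-area
tables; a literal sliding-window transcription ships in the package as
`naive_retrieve_roi`, and exact agreement of all K locations on random
instances is asserted in the tests and measured by the acceptance
script.  Selected grid positions are mapped to image coordinates and
shifted inward so the full patch fits; patch selection carries no
gradient — the global stage learns only through its own loss terms.

**Local stage.**  The K patches are encoded by a higher-capacity
residual 2D network with batch normalization (statistics over the union
of the K patches in the step — the single-device realization of sharing
statistics across all patches of an update), global average pooling and
a projection to `S` dimensions.  Gated attention (no bias inside the
tanh/sigmoid gates, matching the published formulation) weighs the
patches; a per-class sigmoid head on the attention-weighted sum yields
`p_local`.  The final prediction averages the two stages; there is no
fusion module combining hidden representations — with 3D stacks and the
`ReLU(tanh)` nonlinearity it contributes nothing, so the architecture
omits it.

**Loss.**  Per class: `BCE(y, p_local) + BCE(y, p_global) + β·‖A‖₁`.
The two BCE terms are kept separate — a single BCE on the averaged
prediction lets one stage collapse to a constant while the other does
all the work.  Probabilities are clamped to `[1e-7, 1 − 1e-7]` before
the logarithm.  The L1 term drives background saliency to zero, which is
what makes the maps usable as weakly-supervised segmentations.

## Parameters

| name | meaning | default | origin |
| --- | --- | --- | --- |
| `t` | pooling % per slice | 142.61 | midpoint of the published search range U(10.97, 274.25) |
| `omega` | 1×1 init constant | 10^−2.5 | midpoint of log₁₀ω ~ U(−3, −2) |
| `K` | patches per volume | 8 | published choice {8, 12, 16} |
| `zeta` | suppression half-width (slices) | 10 | published default |
| `patch_size` | patch side (pixels) | 256 | published choice |
| `S`, `L` | feature / attention dims | 512, 128 | published choice |
| `learning_rate` | Adam step size | 10^−5 | midpoint of log₁₀η ~ U(−5.5, −4.5) |
| `beta` | saliency L1 weight | 10^−5.54 | midpoint of log₁₀β ~ U(−6.54, −4.54) |
| `epochs` / patience | training budget | 40 / 15 | published protocol |
| `max_shift` | augmentation shift (pixels) | 100 | published protocol |
| `tta_count` | test-time augmentations | 10 | published protocol |

The optimizer is Adam (the published protocol specifies only the
learning-rate distribution); model selection checkpoints the epoch with
the best validation AUC for the malignant class.  Mixed precision and
multi-device synchronization are out of scope: all computation is
single-device full precision, with gradient accumulation over
`batch_size = 4` volumes per update standing in for data parallelism.

## Synthetic phantoms

The generator (`glomil.phantom`) emulates the statistical structure the
architecture exploits, not tomosynthesis physics:

* background = per-slice smoothed Gaussian noise (texture scale 8 px,
  rescaled to sd 0.05 around level 0.35) plus i.i.d. noise (sd 0.03),
  clipped to [0, 1] — so lesion-free intensity statistics are
  independent of the slice count and depth cannot leak the label;
* 0–2 lesions per class (probabilities 0.5/0.4/0.1), discs for benign,
  6–10-spike star polygons for malignant — the simplest shape pair a
  small patch encoder can separate; radius 2.5–4.5 px on a 64×64 field,
  contrast 0.25–0.5, rejection-sampled to be non-overlapping;
* each lesion keeps its full in-plane footprint on **every** slice with
  contrast scaled by `exp(−|d − d_focus|/1.5)` — the "visible from most
  slices with varying focus" redundancy that ±ζ suppression targets;
  the ground-truth mask covers the slices where that factor is ≥ 1/2,
  with an identical footprint on each (focus affects contrast, not
  extent);
* lesion voxels average well under 1% of the volume (asserted in tests):
  the small-object regime the method is for.

What the phantoms do **not** model: reconstruction artifacts, anatomy,
intensity calibration across scanners, lesion texture, or class overlap
in shape.  Passing the synthetic benchmark therefore demonstrates that
the pipeline's mechanics work end-to-end (saliency localizes, retrieval
finds the evidence, attention ranks it, both stages learn); it says
nothing about clinical performance.

## The desk-scale benchmark

`glomil.experiments.run_synthetic_benchmark` trains a small
configuration from scratch on 200 phantoms (64×64, 4–8 slices), early
stops on 48 validation volumes, and reports on 80 held-out volumes:
per-class ROC AUC, the pooled lesion-inside/outside mean-saliency ratio
over positives, and Dice / pixel average precision of the depth
max-projected saliency against the projected ground-truth masks
(block-max downsampled to the saliency grid so single-cell lesions
survive; Dice is reported at the best of 19 fixed thresholds
0.05 … 0.95 on min-max normalized maps, with the full sweep logged,
since weakly-supervised saliency has no canonical calibration).

The desk configuration (`desk_config`) scales the architecture to the
phantom geometry: encoder width 8, downsample 4 (16×16 saliency grid),
32-px patches, K = 2, ζ = 2, S = 64, L = 128→32, `t = 2%` (≈ 5 pooled
cells, matching the expected footprint of one lesion on the grid),
β = 3·10⁻⁴, Adam at 10⁻³ (training is from scratch, not fine-tuning),
30 epochs, shifts up to 3 px and rescales up to 5%.  These values were
chosen on the validation split of the synthetic data; with them the
benchmark reaches held-out malignant AUC ≈ 0.9 and saliency ratios in
the tens to hundreds across seeds.

## Numerical choices and edge cases

* Coordinates are 0-based, row-major, (row, col, slice), half-open
  rectangles — everywhere.
* Criterion ties in retrieval: first occurrence in (slice, top, left)
  order; an all-zero criterion therefore yields the deterministic
  (0, 0, 0) location (repeatedly, if K exceeds the available signal).
* Min-max normalization of a constant plane returns zeros.
* Augmentation uses exact integer shifts with zero padding and mild
  bilinear rescales applied identically to every slice.
* BCE clamp ε = 1e−7; attention softmax is computed with the max score
  subtracted.
* Integer-typed volumes are rescaled to [0, 1] by their per-volume
  maximum on read; writers are atomic (temp file + rename).
* The autodiff engine is float64 throughout; convolution gradients use
  an im2col gather/scatter and are finite-difference checked.

## Limitations

* The reference encoders are compact residual networks; no pretrained
  weights or canonical large backbones are provided, and no transfer
  learning (the published workflow's screening-score pretraining) is
  implemented — the from-scratch synthetic benchmark does not need it.
* Training is pure numpy on one CPU: practical for desk-scale stacks,
  not for full-resolution clinical volumes.
* Grouped ("breast-wise") evaluation is implemented and tested, but the
  default benchmark generates one view per subject.
* The hyperparameter random-search driver is intentionally not bundled;
  the search ranges are documented as config defaults instead.
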