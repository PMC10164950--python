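# Methods

## Problem and model

`organoidseg` segments brightfield micrographs of 3D organoid cultures
into organoid vs. background at the pixel level and converts the
resulting masks into per-organoid area statistics for drug-screening
readouts.

The segmentation model is a nested-U encoder-decoder: a U-shaped network
whose every stage is itself a small U-shaped **residual U-block (RSU)**.
An RSU of height `L` lifts its input with a 3x3 convolution from `C_in`
to `C_out` channels, runs an `L`-level encoder-decoder over `M` mid
channels (2x2 max-pool descents, bilinear x2 ascents, skip
concatenations, each conv followed by batch norm and ReLU), and adds the
result to the lifting convolution's output.  The dilated variant
(`RSU-4D`, used at the two lowest-resolution stages and the deepest
decoder) replaces all resizing with dilation rates 1, 2, 4, 8, so every
internal feature keeps the input resolution.

The backbone has six encoder stages (RSU heights 7, 6, 5, 4, 4D, 4D) and
five mirrored decoder stages, joined by 2x2 max pooling between encoder
stages; the bottleneck feature is 1/32 of the input side.  Six side
heads (a 3x3 convolution to one channel, sigmoid, bilinear upsampling to
input size) emit probability maps from the bottleneck encoder and each
decoder; their logits are spliced by a 1x1 convolution into a fused map.
For a 3x256x256 input the stage widths run
64/128/256/512/512/512 down the encoders and 512/256/128/64/32 up the
decoders (the final decoder emits 32 channels).

Two modules modify the plain skip connections:

* **Grouping cross merge (GCM).**  At each of the five encoder->decoder
  skips, the shallow (encoder) map and the deep (upsampled
  deeper-decoder) map are each divided into `n` channel groups;
  matching groups are concatenated and squeezed to half their joint
  width by a 1x1 convolution, the group outputs are re-concatenated,
  and a 1x1-projected residual of the deep input is added.  The output
  width is exactly `(C_s + C_d) / 2`, which is what the decoder then
  consumes.  Group counts follow depth: `n = 4` at the two shallowest
  skips, `6` in the middle, `8` at the two deepest.  When `n` does not
  divide the channel count (e.g. 256 channels into 6 groups) the groups
  are near-equal (`array_split` semantics); only genuinely impossible
  configurations (more groups than channels, odd total width) are
  rejected at build time.  The five GCMs are serially linked deep to
  shallow: each GCM's output is bilinearly resized, 1x1-projected and
  summed into the next shallower GCM's deep input.
* **Residual attention gate (RAG).**  At the shallowest resolution the
  last GCM output `x` is gated by the next-deeper decoder feature `g`
  (half resolution): `phi = ReLU(a(x) + b(up2(g)))` with `a`, `b` 1x1
  convolutions; `d = W_phi(phi)`; global average pooling of `d` feeds a
  two-layer bottleneck (`c -> c/r -> c`, ReLU between, sigmoid after,
  reduction ratio `r = 16` clamped so at least 4 bottleneck channels
  remain) producing per-channel weights `A in (0,1)^c`; the output is
  `A (x) d + d`.  The gated map passes through dropout (p = 0.5) and a
  1x1 classifier convolution; its logit is averaged with the six-map
  splice logit to form the fused output (the combination mode is a
  config flag: `average`, `splice`, or `rag`).

Both modules are independently switchable, so the four ablation
variants (plain backbone, +RAG, +GCM, +both) are all constructible from
`NetworkConfig`.

## Objective and metrics

Training minimises `L = L_BCE + L_Dice` per supervised map:
mean binary cross-entropy with predictions clamped to `[1e-7, 1-1e-7]`,
plus the soft Dice complement
`1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)` with smoothing `s = 1`.
Under deep supervision (default) the loss is summed over the fused map
and all six side maps; the fused map's own breakdown is logged
separately.  Evaluation uses pixel confusion counts:
`Acc = (TP+TN)/N`, `Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)`,
`F1 = 2TP/(2TP+FP+FN)`; degenerate denominators return NaN with a
warning.  Dataset-level metrics pool counts over images
(micro-averaging); macro-averaging is available behind a flag.

## Compute substrate

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff engine over numpy arrays (`organoidseg.nn`),
with convolutions expressed as k*k shifted 1x1 matmuls, dense
interpolation matrices for bilinear resizing (align-corners disabled),
argmax-tracked 2x2 ceil-mode max pooling, batch normalisation with
running statistics, inverted dropout, and SGD with classical momentum.
Every op's backward pass is pinned by finite-difference gradient tests.
Weights are He-uniform, biases zero, all seeded; a global seed governs
initialisation, shuffling and dropout, making CPU runs bit-reproducible.

## Training defaults

SGD with learning rate 0.02, momentum 0.9, no weight decay, batch size
8, dropout 0.5, up to 1000 epochs, no schedule — all exposed in
`TrainConfig`.  The optimiser family, epoch budget and dropout rate are
the method's stated recipe; the learning rate, momentum and batch size
are this package's own defaults (chosen once as standard values for
batch-norm U-nets at this batch size).  Model selection keeps the
checkpoint with the best validation F1.  Full micrographs are segmented
by sliding-window inference (tile divisible by 32, probabilities
averaged in overlaps, threshold 0.5, reflect-padding for undersized
inputs).

## Synthetic data: what it emulates and what it does not

No public dataset of annotated brightfield organoid micrographs is
bundled, so all tests run on a parametric generator
(`generate_synthetic_scene`).  It renders elliptical organoids (per-axis
radii drawn from `radius_range`, boundary perturbed by low-order radial
sinusoids of relative amplitude `boundary_wobble = 0.08`) that are
brighter than the background with a mild dome profile and a darker rim,
over a Gaussian-filtered background texture, a smooth directional
uneven-illumination ramp (`illumination_amplitude = 0.15` of full
scale), and additive Gaussian noise (`noise_sigma = 6` grey levels).
This captures the features the preprocessing and network must cope with
— heterogeneous object sizes, low contrast, uneven illumination, noise
— but not out-of-focus halos, debris, organoid adhesion or lumen
texture of real cultures.  Passing tests therefore demonstrate that the
pipeline is implemented correctly and can learn this class of imagery;
they say nothing quantitative about accuracy on real micrographs.

The drug-screen fixture (`generate_drug_screen`) emulates a three-arm
study (untreated control plus two drugs) over culture days 1, 3, 5, 7:
per-organoid radii are log-normal (sigma 0.2 in log-radius) around a
median that grows exponentially with day (6 px at day 1, rate 0.18/day);
from day 5 the control arm's median radius is multiplied by 1.25
(area x ~1.56), while days 1-3 are statistically identical across arms.
With 10 images x 8 organoids per condition, the sampling noise of a
group median is about 0.08 in log-area, so the day-5/7 effect (0.45
log-units) is detectable and day-1/3 differences stay below 0.25
log-units — the bound the tests use for "indistinguishable".

## Preprocessing pipeline

* **Denoising**: non-local means (scikit-image), defaults strength 10 on
  the 0-255 scale, 7-px patches, 21-px search window.
* **Augmentation**: each source yields `tiles_per_image = 32` tiles of
  256x256 by an independent (flip, scale in [0.8, 1.25], crop) draw;
  images are resampled bilinearly, masks nearest-neighbour, and every
  tile logs its transform so the geometry can be re-applied and checked.
  200 sources therefore expand to 6400 tiles.
* **Split**: 8:1:1 train/val/test by source — all tiles of one
  micrograph stay in one partition, so augmented copies can never leak
  across the evaluation boundary.

## Screening quantification

Connected components (8-connectivity by default; 4 available) of a
predicted mask are organoids; components under `min_size = 30` px are
discarded as speckle.  Touching organoids count as one component —
splitting adhering objects is out of scope.  Areas are reported in px
and um^2 (`area_um2 = area_px * pixel_size_um^2`); group summaries use
type-7 (linear-interpolation) quantiles so they are portable across
implementations; a long-format CSV export supports violin plots.

## Numerical choices and degenerate inputs

* BCE clamp 1e-7; Dice smooth 1.0; binarisation threshold 0.5.
* Bilinear resizing everywhere uses align-corners-disabled convention.
* Max pooling is ceil-mode; tied maxima take the first index.
* Metrics with empty denominators return NaN, never a silent 0/1.
* An RSU refuses inputs it would pool below 1x1; the backbone requires
  input sides divisible by 32 and reports the requirement.
* GCM rejects group counts exceeding the channel count and odd total
  widths at build time, naming the offending stage.

## Scaled-down study conditions

CPU-bound checks run at reduced width: the trainability gate overfits
eight 96x96 synthetic tiles with a channels/8 network (same topology,
group counts and skip structure) and must reach training F1 >= 0.8
within 300 epochs; in practice it converges in roughly 40-60 epochs.
Architecture conformance runs the full-width network once on a
3x256x256 input.  These sizes are the package's chosen desk-scale study
conditions; nothing in the test suite trains the full-width model.

## Known limitations

* No pretrained weights; headline benchmark accuracy on real organoid
  data is not reproduced here.
* Binary (semantic) masks only; no instance separation of adhering
  organoids, no boundary-distance metrics, no 3D volume estimation.
* The numpy substrate is single-process and far slower than a GPU
  framework; it is sized for correctness and desk-scale experiments.
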