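# Methods

This note records the scientific model implemented by `brainfuse`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Problem setting

Multi-modality brain-tumor MRI studies (e.g. the BraTS challenge
datasets) provide, per patient, four volumetric acquisitions — FLAIR,
T1, contrast-enhanced T1 (T1CE), and T2 — of 155 axial slices each.
The pipeline treats the four modalities as a four-class classification
problem on 2-D slices. `plan_slice_selection` encodes the bookkeeping
for slice-range sampling: selecting slices 40–114 (75 per patient, the
information-rich middle of the volume) from a 369-patient cohort yields
27,675 slices per modality class and 110,700 in total. The NIfTI
adapter (`convert_nifti_volumes`) materialises that sampling as
per-class PNG directories, min–max scaling each slice independently
(the volume-to-8-bit normalisation is otherwise under-determined; per-
slice scaling is the choice documented here).

## Feature extractors

**Modified ResNet-50.** The builder emits the standard backbone — 7×7
stride-2 stem with max-pooling, then bottleneck stages of 3/4/6/3
residual blocks (49 backbone convolutions) — followed by three
additional stride-1 residual blocks of four convolutions each
(alternating 1×1 and 3×3 kernels), one extra 3×3 stride-1 convolution
after the first added block, batch-normalisation + ReLU after every
convolution, global average pooling, and a softmax head. Where in the
backbone the added blocks sit and what channel plan they follow is the
one free architectural choice: they are appended after stage 5 with
channel width 1024·`width_scale`, so the GAP feature vector ψ_fv1 is
1024-wide at scale 1. Skip connections use identity mapping, with a 1×1
projection inserted only when channel counts differ. `width_scale`
shrinks every channel count proportionally; desk-scale work uses 0.25
(GAP width 256) on 32×32 inputs. Training is from-scratch SGDM (the
package accepts externally supplied weights for transfer-learning
workflows, but never downloads any).

**Stacked autoencoder.** Five stride-2 encoder convolutions (channel
plan 8–16–32–64–64) compress an H×W input (H, W multiples of 32) to a
flat code; two dense sigmoid bottlenecks of 100 and 50 units follow —
the "two stacks". Each stack carries its own regularisation constants
(stack 1: L2 0.004, sparsity weight 4, target activation 0.15; stack 2:
L2 0.002, sparsity weight 4, target 0.10; 5 greedy epochs each). The
decoder mirrors the encoder with five upsampling convolutions. The
feature tap must be 1236-wide regardless of input resolution, which no
plain layer arithmetic produces; the implementation gives the fifth
decoder convolution C channels and pools it to a g×g grid with
g²·C = `feature_dim` (1236 → g = 2, C = 309). That fifth convolution
uses a 1×1 kernel (a channel-mixing feature layer at full resolution;
chosen over 3×3 purely to keep the desk-scale compute modest), and a
separate 1×1 sigmoid output projection — not counted among the five
decoder convolutions — produces the reconstruction. Training is greedy:
each dense stack is first trained as a two-layer autoencoder on the
(flattened) codes of the previous level, its weights are installed into
the full graph, and the whole network is then fine-tuned jointly on the
half-mean-squared reconstruction error `L = ‖I − dOUT‖²/(2N)` plus the
per-stack L2 and KL-sparsity penalties
`Σ_j ρ log(ρ/ρ̂_j) + (1−ρ) log((1−ρ)/(1−ρ̂_j))`.

**Compute backend.** Both networks run on `brainfuse.nn`, a small numpy
layer engine (im2col convolutions, batch-norm, max/adaptive/global
pooling, nearest-neighbour upsampling, dense layers, residual joins)
with hand-written backward passes. Every layer's gradient is tested
against central finite differences; the graph backward additionally
supports activation-gradient capture at interior layers (Grad-CAM) and
gradient injection at interior layers (sparsity penalties). All
parameters derive from a seeded generator, so identical seeds give
bitwise-identical models; SGDM (momentum 0.9) and Adam are available.
The reference training recipe (SGDM, minibatch 256, learning rate 1e-3,
50:50 split, k = 10 folds) is the `TrainConfig` default; desk-scale
runs use smaller minibatches and fewer epochs, chosen so the synthetic
demo completes on one CPU in well under ten minutes.

## Fusion

Each deep-feature vector is pooled along the feature axis with window 2
and stride 2 and the pooled vectors are concatenated (extractor-1 part
first): widths 1024 and 1236 pool to 512 and 618 and fuse to 1130, and
generally to ⌈w₁/2⌉ + ⌈w₂/2⌉. Two open points were resolved as follows.
A stride of 1 cannot produce the halved widths above, so stride 2 is
the default (stride remains configurable). The pooling operator is max
by default (salience-preserving; mean available). Mean padding —
extending a vector with its own arithmetic mean — is applied only when
a vector's length does not align with the pooling window; it is not
used to equalise the two vectors' lengths, since their pooled widths
(512 vs 618) are intentionally unequal.

## Wrapper feature selection

Candidate solutions are continuous positions in [0, 1]^d, binarised at
0.5 into column masks (the standard transfer for wrapper GWO; a
position with no active column falls back to its largest component, so
masks are never empty). Fitness is the hold-out accuracy of an extreme
learning machine on the masked columns: a fixed, seeded stratified
70:30 split; a seeded Gaussian hidden projection (default width 100)
with sigmoid activation on z-scored inputs; output weights solved in
closed form from the ridge normal equations. The ridge constant
defaults to 1e-2 — at much smaller values the solve interpolates its
training targets and the hold-out fitness ranks masks by overfit noise
rather than signal. Fitness is deterministic per mask, so evaluations
are memoised; one fixed split per selection run keeps the search
surface stationary.

Phase 1 (GWO) ranks the population, keeps the three best as α/β/δ
(fitness ties broken by lower index), and moves every wolf by the
encircling equations with per-leader, per-dimension uniform draws h₁,
h₂; the exploration coefficient g decays linearly from 2 to 0 over the
iterations, so the final updates contract the pack onto the leader
centroid. Phase 2 (Jaya) refines the final population: each candidate
moves toward the current best and away from the current worst (the |X|
in the update is applied exactly as specified even though clipped
positions make it a no-op), and a move is accepted only if it improves
fitness, so the best-ever trace is non-decreasing across both phases.
The reference budget is population 50 with 200 + 100 iterations;
benchmarks in the test suite use population 40 with 80 + 50 iterations,
which completes a ten-seed recovery study in about half a minute.

## Classifiers and metrics

The five preset networks follow the MATLAB Classification Learner
conventions behind their names: narrow [10], medium [25], wide [100],
bi-layered [10, 10], tri-layered [10, 10, 10] hidden units, ReLU
activations, softmax output (sklearn `MLPClassifier` behind a
standard-scaler pipeline). The default protocol is the stratified 50:50
hold-out; k-fold is available, and pools the out-of-fold predictions of
all folds into a single confusion matrix rather than averaging per-fold
metric values — pooling is the only form under which single-sample
folds (leave-one-out) keep per-class rates well-defined. Metrics use
the standard definitions — sensitivity TP/(TP+FN), precision
TP/(TP+FP), FNR = 100 − sensitivity, all as percentages, macro-averaged
over classes — and a macro one-vs-rest AUC on predicted class
probabilities.

## Paired Student's-t comparison

Two classifiers are compared across N experiment stages by the absolute
accuracy differences D_i, μ = mean(D), σ = sample standard deviation
(N−1 denominator), T = √N·μ/σ, checked against the two-tailed critical
value at N−1 degrees of freedom (scipy's inverse CDF; ±3.182 at df = 3,
α = 0.05). The reported decision text mirrors the source framing of the
procedure, whose null hypothesis is that the classifiers *do* differ: a
statistic inside the interval "rejects" it and declares the classifiers
equivalent. The boolean `within_interval` carries the testable content;
the phrasing is reported, not endorsed, and the implementation notes
that the framing inverts the usual convention.

## Grad-CAM

Channel weights are the spatial means of the class-logit gradients at a
chosen convolutional layer, a_k = (1/N)·Σ_ij ∂y_c/∂A^k_ij, and the map
is M = ReLU(Σ_k a_k A^k) at the layer's native resolution. The raw map
is what tests assert on; bilinear upsampling to input resolution with
min–max normalisation is display-only. The default deep tap (last
convolution of the third added block) collapses to 1×1 spatial extent
at 32×32 inputs, so `deepest_spatial_conv` picks the deepest layer with
at least 4×4 maps for localisation work at desk scale.

## Synthetic data: what it emulates, what it does not

`make_feature_dataset` plants recoverable structure: informative
columns are unit-variance Gaussians around class means placed on a
regular simplex scaled so every class pair is exactly `class_sep` apart
(randomly rotated so all informative axes matter — dropping any one
loses separation); redundant columns are unit-norm linear combinations
of the informative block plus unit-variance noise (signal-bearing but
strictly degraded, so an accuracy-driven selector has a reason to
prefer the originals); noise columns are class-independent standard
Gaussians. `make_modality_images` draws four classes on an elliptical
brain-like support, distinguished by oriented gratings of
class-specific spatial frequency, class-specific base intensity, and a
random bright blob, plus pixel noise.

These generators exercise every algorithmic path — training dynamics,
tap widths, fusion arithmetic, selection pressure, calibration,
saliency localisation — but they are not MRI: there is no anatomy, no
inter-patient variability, no acquisition artefacts, no class overlap
structure resembling real modality contrast. Passing benchmarks
demonstrate algorithmic correctness and sane behaviour under known
ground truth, not clinical performance; headline accuracies reported on
real BraTS-scale data require full-resolution training on external
volumes, which is out of scope here.

## Numerical choices and degenerate inputs

Float64 throughout. Batch-norm uses ε = 1e-5 and running-moment
momentum 0.9. Cross-entropy subtracts the row max before
exponentiation; sigmoid clips pre-activations at ±60. Training aborts
with a diagnostic if the loss becomes non-finite. Empty feature masks,
single-class label sets, inverted slice ranges, shape mismatches, zero
confusion totals, and zero-variance difference vectors (σ = 0 in the
paired test) all raise `ValueError` rather than propagating NaNs.
Leader ties in GWO and equal Jaya candidates resolve deterministically
(lower index wins; greedy acceptance requires strict improvement).
Every public entry point takes a seed, and the pipeline spawns one
named substream per stage from its root seed, so a config + seed pair
reproduces every artifact byte-for-byte.

## Known limitations

- The compute backend is single-threaded numpy: fine for 32×32
  desk-scale studies, not for 224×224 full-resolution training.
- The 1236-wide autoencoder tap is realised by a pooling plan
  (g²·C = 1236) because no stated layer arithmetic yields it; other
  `feature_dim` values fall back to coarser plans (prime values force
  g = 1, i.e. a 1236-channel tap, which is expensive).
- The ELM fitness uses one fixed split per run; selection can still
  exploit split idiosyncrasies when classes are nearly separable
  (visible as best-fitness values slightly above the informative-only
  oracle in the benchmarks).
- Jaya hyperparameter tuning searches a bracketed recipe space
  (optimizer, log learning rate, momentum, minibatch); it does not
  search architecture.
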