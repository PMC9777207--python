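# Methods

## Problem and pipeline

The task is a binary, case-level diagnosis: given a whole-slide H&E image
of a lung biopsy from a patient with idiopathic interstitial pneumonia,
decide idiopathic pulmonary fibrosis (IPF, positive) versus non-IPF. The
pipeline is patch-based: slides are tiled, a CNN scores each patch with an
IPF probability, and a case is scored by the arithmetic mean of its patch
probabilities. Because cohorts for these rare diseases are small, the
classifier is trained in two steps: pretraining on images sampled from
class-conditional generative models, then fine-tuning on the real patches.

## Tiling

Patches are cut on a non-overlapping raster grid, coordinates 0-based with
a top-left origin; partial edge patches are dropped rather than padded.
The source patch edge is 2240 px, resized bilinearly to 224 px at the
network input; tests and the desk preset use 64 px sources and 32 px
inputs, which exercise identical code paths.

Tissue detection binarizes the slide grayscale (ITU-R 601 luminance) with
Otsu's method. Tissue is dark on a bright background, so foreground is
"at or below threshold". Implementation notes:

* the threshold maximizing the between-class variance of `{<=t, >t}` is
  found with exact integer arithmetic (histogram counts are integers), so
  the smallest-t tie-break is deterministic rather than at the mercy of
  floating-point rounding; a histogram with all mass in one bin returns
  that bin's index;
* the threshold is computed once per slide, not per patch — a nearly empty
  patch has a degenerate histogram, a slide does not;
* patches with tissue fraction below 0.10 are excluded; exactly 0.10 is
  kept, since the exclusion rule is *less than* 10%;
* when a region-of-interest mask is supplied, a patch is kept if its
  centre lies inside the ROI, and the tissue rule is applied after ROI
  selection. The centre rule is the package's choice; nothing in the
  procedure pins it down.

## Progressive GAN with WGAN-GP

One generator/critic pair is trained per class. The generator starts at
4x4 (a dense projection of the 128-dim latent followed by two 3x3
convolutions) and doubles its resolution per growth event, adding two 3x3
convolutions each time, up to the target edge (256 at reference scale:
seven resolutions, six growth events). Per-stage toRGB/fromRGB 1x1
adapters allow training at every intermediate resolution. During a growth
stage the new branch fades in linearly,
`out = (1 - alpha) * upsample(prev) + alpha * new`, with alpha ramping
0 to 1 over the first half of the stage (`fade_in_fraction = 0.5`).

Training minimises the WGAN-GP objectives: the critic
`mean C(fake) - mean C(real) + lambda * mean(||grad_xhat C(xhat)|| - 1)^2`
with per-sample interpolates `xhat = eps*real + (1-eps)*fake`,
`eps ~ U(0,1)`, and the generator `-mean C(fake)`. Defaults: `lambda = 10`
(the WGAN-GP reference value), Adam with lr 1e-5, beta1 0.9, beta2 0.999,
50 epochs in total split evenly across stages, batch 16, one critic update
per generator update. Channel widths halve as resolution doubles
(`base_channels` at 4x4, floor 8). Pixel normalisation and
minibatch-stddev are implemented but off by default. The generator's RGB
output is linear; samples are clipped to the display range on export.
Desk-scale runs (16 px target, base 32 channels, lr 1e-3) keep the same
code path at roughly a thousandth of the reference compute.

The penalty's parameter gradient requires differentiating through the
input-gradient computation. The in-package autodiff engine builds
vector-Jacobian products out of graph operations, so
`grad(..., create_graph=True)` returns differentiable tensors; leaky-ReLU
units are treated as multiplication by a frozen slope mask, whose second
derivative is zero almost everywhere (the standard double-backprop
convention for piecewise-linear activations). The engine is verified
against central finite differences, including the second-order path.

The DCGAN baseline (generator: latent projection, then five convolutions
interleaved with four nearest-neighbour upscalings; discriminator: six
convolutions and one fully connected output) trains with the standard
non-saturating logistic loss, lr 2e-5, 2000 epochs at reference scale.

## Two-step classifier

Backbones: canonical VGG-16/19, ResNet-50 and DenseNet-121/169/201
configurations, a compact Inception-style network (stem, mixed branch
modules with factorized 1x7/7x1 convolutions, reduced depth), and
`tiny_cnn` (three batch-normalised conv blocks, 32 features) for
desk-scale work; batch normalisation matters there because the class
signal is a subtle shift in channel means, which an unnormalised small
network optimises very slowly. After each training phase the BatchNorm
running statistics are recomputed as the cumulative average of batch
statistics over one pass of that phase's training set, so short runs
evaluate with statistics that match what was trained. All
end in global average pooling and a fresh (1024, 2) MLP head with softmax.
ImageNet weight files are not bundled; a `pretrained_imagenet` request
falls back to He initialisation and the model records
`weights_used = "random"`. Inputs are scaled to [0,1] (`tiny_cnn`) or
ImageNet-normalised (all other backbones).

Pretraining uses GAN samples only; fine-tuning uses real patches only, all
layers trainable, with class balancing: the minority class is replicated
under the first `round(n_major/n_minor)` (clipped to [1, 8]) elements of a
fixed dihedral order — r0, r90, r180, r270, then the same four after a
horizontal flip. The majority class keeps factor 1 at reference scale, so
the balancing counts (23,142 / 23,451) are exact. The desk preset applies
a base dihedral factor of 4 to *both* classes (multiplied by the balance
factor, clipped to the group size 8). The reason is statistical: with only
one slide per case, a flexible network partially fits slide-level texture
clusters — most visibly the random band orientation — and such cluster
fitting anti-generalizes across held-out cases, driving the
zero-separation null visibly below chance. Rotation/flip augmentation is
the orientation-invariance regulariser that suppresses exactly this
failure mode; with it the null sits near chance while high-separation
recovery is unaffected. Every optimisation
step is tagged `pretrain` or `finetune` in the model log, so step purity
is auditable. Loss is two-class cross-entropy; optimiser Adam with the
same betas as the GAN. Reference scale: lr 1e-5, 50 epochs per step.
Desk scale: lr 2e-3, 3 pretrain and 10 fine-tune epochs — chosen so the
small network converges on the synthetic cohort's patch counts
(roughly 300 patches per fold).

## Evaluation

Cross-validation is grouped by case and stratified by class: within each
class, cases are shuffled deterministically and dealt into K folds whose
sizes differ by at most one (12 cases over 5 folds gives sizes
{3,3,2,2,2}). All of a case's patches share its fold, so no patch of a
test case is ever seen in training, including by the per-fold GANs.

Point metrics use cut-off 0.5 (the ROC sweep, not the point metrics, is
where cut-off variation belongs): sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy, with IPF positive. ROC curves sweep every unique
score plus ±inf endpoints; AUC is the trapezoidal area, equal to the
Mann-Whitney concordance on tie-free scores. Repeated runs (different
training seeds, same cohort) are summarised as mean ± SD; the repeat
count defaults to 3 and is configurable.

Probability maps colour each patch cell by its IPF probability through a
fixed red-high colormap (matplotlib "jet") alpha-blended at 0.4 onto the
slide; unpatched regions are untouched.

## Synthetic slides

The generator emulates exactly the properties the pipeline depends on:

* bright near-white background (default gray 235) with mild sensor noise;
* tissue regions from a thresholded smoothed Gaussian field — the
  threshold is the field's quantile, so coverage is controlled tightly;
* H&E-like colouring: eosin-pink matrix (gray ~170, well below
  background, so Otsu behaves as on a real stain) and hematoxylin-purple
  nuclei placed by Poisson-disc sampling;
* two texture classes: fibrotic (oriented sinusoidal band texture, sparse
  nuclei) vs inflammatory (weak banding, dense nuclei). A single
  `texture_separation` knob moves band amplitude and nucleus density apart
  monotonically; at 0 the classes are drawn from the identical
  distribution, which is the no-signal null used in tests.

Default conditions mirror the study design: 12 cases per class, one slide
per case, coverage 0.6, separation 3.0 (at which a logistic classifier on
the nucleus-pixel fraction alone exceeds 95% patch accuracy — the
documented separability threshold backing the learning tests).

What the generator does **not** emulate: real histologic microanatomy,
stain variability between labs, scanner artefacts, focal pathology
gradients within a slide, or inter-case heterogeneity beyond sampling
noise. Passing the recovery tests therefore shows that the pipeline's
plumbing, training loops and evaluation logic recover a known signal at
desk scale — not that the method attains any particular accuracy on real
biopsies.

## Problem sizes and numerical choices

Desk-scale experiments use 256-px slides, 64-px patches resized to 32,
PGGAN target 16 px, 200 generated images per class, and 5-fold CV over 24
cases — the full pipeline in a few minutes on one CPU core. The null
check runs the no-pretraining arm over three seeds and is asserted on the
mean case-based AUC: a single 24-case AUC has sampling SD near 0.1 under
the null, so per-seed assertions would fail by sampling noise alone at a
non-trivial rate.

Numerics: float64 throughout; the gradient-norm square root is offset by
1e-12; Otsu comparisons are exact integers; ROC thresholds sweep unique
score values so ties collapse to single sweep points; Adam uses the
bias-corrected update; all randomness flows through explicitly passed
`numpy.random.Generator` objects, with per-stage seeds spawned from one
global seed via `SeedSequence`, so identical configurations reproduce
identical logs, manifests and checkpoints.

## Known limitations

* CZI/JPEG-XR scanner formats are out of scope; slides are PNG/TIFF.
* The GAN at desk scale captures colour and coarse texture statistics,
  not cellular morphology; its contribution to desk-scale accuracy is
  correspondingly modest and is asserted only directionally (the two-step
  arm must not trail the no-pretraining arm by more than 5 points).
* No ImageNet weights, no hyperparameter search, no model ensembling.
* Published cohort-level results rest on a private 24-case dataset and
  GPU-scale training; only their self-contained arithmetic (confusion
  matrices, balancing counts) is reproduced here.
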