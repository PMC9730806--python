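# Methods

## Problem

New (or newly enlarging) white-matter lesions between two longitudinal
T2-FLAIR scans are a key biomarker of multiple-sclerosis activity. Reading
them by eye is error-prone: lesions are small, scanners drift between
sessions, and residual misregistration mimics change. `mscascade`
implements an automated pipeline that takes a rigidly co-registered
baseline/follow-up pair and produces a voxel probability map and a binary
mask of *new* lesions.

## Model

The core model is a pair ("cascade") of identical 3-D patch-wise fully
convolutional networks. Each network is itself a composition:

* a **registration U-Net** reads the stacked (baseline, follow-up) patch
  and predicts a dense deformation field DF (voxel-unit displacements);
  a differentiable trilinear spatial transformer warps the baseline patch
  by DF, so registration can be learned without ground-truth fields;
* a **two-branch segmentation U-Net** reads (baseline, follow-up) in one
  branch and DF in the other; branch outputs are concatenated and a
  1×1×1 convolution with a logistic output gives the per-voxel new-lesion
  probability.

All U-Nets share one architecture: four max-pool downsampling and four
nearest-neighbour upsampling steps, "core element" blocks of two
same-padded 3×3×3 convolutions, and concatenation skips. Contracting /
expansive channel widths default to (64, 128, 256, 512) / (512, 256, 128,
64). The registration path uses LeakyReLU (slope 0.2) so displacements can
be signed; the segmentation path uses plain ReLU. Patch sides must be
divisible by 2⁴.

The training loss is the sum of a supervised and an unsupervised part:

    L = w_seg · CE(Seg, GT)
      + w_sim · (1/N) Σ_i (F_i − B(DF)_i)²        (similarity)
      + w_reg · Σ_p ‖∇DF(p)‖²                      (smoothness)

CE is mean voxelwise binary cross-entropy; F is the follow-up, B(DF) the
moved baseline. The similarity term is a per-voxel mean while the
smoothness term is a bare sum, so their natural scales differ by the patch
voxel count; the weights (default 1, 1, 1) exist to balance them, and
`TrainingConfig.with_balanced_regularization()` divides `w_reg` by the
patch voxel count to put both registration terms on the same O(1) scale.

### Cascade training

1. One training patch per ground-truth lesion voxel is extracted from every
   case (so larger lesions implicitly weigh more) and the first network
   (FCNN₁) is trained on them — every patch contains lesion, which biases
   stage 1 toward sensitivity.
2. FCNN₁ is run on each training case with overlapped lattice patches
   (step 8³); per-voxel probabilities are averaged, thresholded (> 0.5) and
   components under 3 mm³ removed.
3. The *hard-example region* is the union of the lesion area and the voxels
   stage 1 got wrong. Lattice patches (step 8³) intersecting that region
   train the second network (FCNN₂) from scratch with a fresh seed.
4. At test time the two probability maps are averaged voxelwise, then
   thresholded (> 0.5) with the < 3 mm³ component filter (26-connectivity).

Each stage trains with Adam on the combined loss, a case-stratified
75/25 train/validation split (whole cases go to validation, so neighbouring
patches of one lesion cannot leak across the split), early stopping when
the validation loss has not strictly decreased for `patience` epochs, and
restoration of the best-validation-epoch weights.

### Implementation choices that matter

* **Network input scale.** Standardized intensities live on a 0–100 scale;
  the networks see them divided by 100. This keeps activations in range
  for the He-initialized weights and puts the similarity MSE on the same
  O(1) scale as the cross-entropy.
* **Classification-head bias init.** The final 1×1×1 convolution's bias
  starts at −4.6, the logit of a ~1% lesion prior. With ≲1% positive
  voxels even in lesion-centered patches, a zero-bias start spends most of
  the optimization budget pushing background down; the prior init is the
  standard remedy for imbalanced dense detection.
* **Fused cross-entropy.** The training CE is computed from the pre-sigmoid
  logits in the standard numerically stable form. It equals the clipped
  probability-space formula (the reference implementation in
  `mscascade.losses`, asserted equal in tests) but its gradient (p − y)/N
  does not vanish when the logistic output saturates — with a separate
  sigmoid node, an early all-negative collapse is an absorbing state.
* **Patch placement.** Training patches are placed so the selected lesion
  voxel lands at a *uniformly random* position inside the patch rather than
  exactly at the center. A patch-wise network with zero padding can read
  absolute position through its borders; with perfectly centered training
  patches it learns "lesions live at the patch center" and fails on the
  arbitrary lesion/patch alignments of lattice inference (we observed
  probabilities collapsing for lesions ≥ 4 voxels off-center). Randomized
  placement makes position uninformative. `lesion_centered_patches`
  defaults to centered placement; the cascade training path opts into
  jitter with a seeded generator.
* **Warp border handling** clamps out-of-bounds samples to the edge, which
  avoids injecting zeros into the similarity loss at patch borders; clamped
  samples contribute zero gradient to the field.
* **Connectivity** for lesion components is 26 everywhere (labeling,
  post-filter, matching).
* **Threshold semantics** are strict: probability > 0.5; components with
  volume < 3 mm³ (voxel count × voxel volume) are removed.
* **Optimizer**: Adam (lr 10⁻³ default; the phantom studies use 2·10⁻³),
  batch size 8–16. Stage 2 re-seeds with `seed + 1`.
* **Determinism**: all randomness flows from explicit `numpy` generators
  seeded from the configs; training and inference are bit-reproducible on
  CPU.

The networks, spatial transformer and training loop run on a compact
reverse-mode autodiff engine written on numpy (`mscascade.nn`), with
convolution as per-offset GEMMs; every primitive's gradient is verified
against central finite differences in the test suite.

## Intensity standardization

Piecewise-linear histogram matching on landmark percentiles
{1, 10, 20, …, 90, 99}: each training image's landmarks (computed within
the brain mask when available, else over strictly positive voxels) are
affinely mapped so the outermost pair spans [0, 100]; the standard scale is
the per-landmark mean. Normalizing maps an image's own landmarks exactly
onto the standard scale with linear interpolation between and linear
extrapolation beyond. One standardizer is fitted over all training images
of both timepoints. Inputs are assumed bias-field-corrected and
skull-strippable by a simple threshold mask (`trivial_brain_mask`:
threshold at a fraction of P99, keep the largest 26-connected component,
fill holes); full skull-stripping and bias correction are upstream of this
package.

## Evaluation

Voxel level: Dice 2·TPₛ/(FNₛ + FPₛ + 2·TPₛ). Lesion level (26-connected
components): a ground-truth lesion is detected when the prediction covers
strictly more than `min_overlap_fraction` (default 0.1) of its voxels; a
predicted component is a false positive only if it touches no ground-truth
lesion. F1 = 2TP/(FN + FP + 2TP), PPVL = TP/(TP+FP), SensL = TP/(TP+FN).
Cases with no true new lesions are excluded from those means and instead
report VolTested, the falsely predicted volume in mm³ (cohort level: mean
over lesion-free cases). The matching rule is configurable and reported
results always state it; published evaluation tools do not all document
their exact rule, so ours is an explicit, documented choice.

## Synthetic phantoms

`mscascade.synthetic` generates two-timepoint cases with full ground truth:
an ellipsoidal "brain" (tissue ≈ 50 standardized units) with smooth random
internal texture and a darker central "ventricle"; a follow-up that is the
baseline anatomy warped by a smooth random deformation field (white noise
Gaussian-smoothed per component, scaled to a maximum displacement
amplitude), globally shifted in intensity, with a requested number of
bright ellipsoidal new lesions (placed non-overlapping, ≥ 2 voxels apart,
each forced above the 3 mm³ post-filter floor) and independent Gaussian
voxel noise per timepoint. Optional "distractor" blobs present at *both*
timepoints provide false-positive bait. Cohorts draw a configurable
fraction (default 25%) of lesion-free cases, mirroring longitudinal cohorts
in which a quarter to a half of patients show no new activity.

What the phantoms do **not** emulate: MR physics (partial volume, bias
fields, flow/ghosting artifacts), multi-scanner appearance shifts beyond a
global intensity offset, anatomy beyond a smooth blob, and confluent or
periventricular lesion geometry. Passing the synthetic studies therefore
demonstrates that the pipeline's machinery — registration, patch logic,
cascade mining, post-processing, metrics — is correct and that the training
recipe can recover conspicuous changes; it does not certify clinical
performance.

## Desk-scale study conditions

The self-contained studies (acceptance script and end-to-end tests) run on
1 CPU in minutes, with sizes chosen once:

* phantoms 64³ at 1 mm isotropic; 2 lesions per case with radii 1.2–2.0 mm
  at contrast 40 (conspicuous, as FLAIR new lesions are), noise σ = 2,
  inter-scan intensity shift 5, deformation amplitude 1 voxel
  (2 voxels in the registration-benefit study), smoothness 6 voxels;
* 8 training cases (a quarter lesion-free), 4 held-out test cases;
* networks with channels (4, 8, 16, 32) on 16³ patches — the architecture
  scaled down by 16× in width and 2× in patch side;
* ≤ 15 epochs per stage (Adam, lr 2·10⁻³, batch 8 — small batches keep the
  optimizer step count useful on the few hundred patches a desk-scale
  cohort yields), early-stopping patience scaled likewise; full-width
  networks, 32³ patches and the 100-epoch/patience-10 schedule remain the
  package defaults.

The cascade-vs-single-stage comparison uses harder, smaller phantoms with
distractor blobs; the registration study compares the trained similarity
loss against the unregistered baseline/follow-up MSE on the same patches.

## Known limitations

* The loss weights of the original formulation are not recoverable from
  its description; defaults expose the printed unweighted sum, with the
  voxel-count rebalancing of the smoothness term as a package choice.
* Whether stage-1 probability maps for mining should come from a held-out
  split rather than the training cases themselves is open; we follow the
  training-cases-as-mined reading, which risks optimistic mining.
* One standardizer is fitted jointly over both timepoints of all training
  images; a per-timepoint alternative is plausible but unsupported here.
* No resampling between grids: all images of a case must share one voxel
  grid within tight tolerances (10⁻⁴ mm on spacing, 10⁻³ on affine
  entries), and patches are native-voxel.
* Displacements are in voxel units; for anisotropic grids multiply by the
  spacing to obtain mm.
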