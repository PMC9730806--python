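# mscascade

Detection of **new multiple-sclerosis lesions** between two longitudinal
3-D T2-FLAIR scans, with a cascade of two 3-D patch-wise fully
convolutional networks that jointly learn deformable registration and
new-lesion segmentation.

New lesions on follow-up MRI are a core biomarker of MS activity, but
reading a baseline/follow-up pair by eye is slow and error-prone: the
lesions are small, the two sessions differ in intensity scale, and residual
misalignment after rigid registration mimics change. This package is for
researchers in longitudinal neuroimage analysis who want a complete,
self-contained implementation of the cascade approach — preprocessing,
networks, training, inference, post-processing, lesion-wise evaluation, and
a synthetic phantom generator that makes every stage testable without
access to restricted clinical data.

## The model

Each cascade stage is one end-to-end network:

* a registration U-Net predicts, from the stacked (baseline B, follow-up F)
  patch, a dense deformation field DF; a differentiable spatial transformer
  produces the moved baseline B(DF);
* a two-branch segmentation U-Net reads (B, F) and DF and outputs the
  per-voxel probability *Seg* of "new lesion".

Both are trained together by gradient descent on

```
L = CE(Seg, GT) + (1/N) Σᵢ (Fᵢ − B(DF)ᵢ)² + Σₚ ‖∇DF(p)‖²
```

(cross-entropy + image similarity + smoothness of the field; weights
configurable). The **cascade**: stage 1 trains on patches around every
ground-truth lesion voxel (sensitivity-oriented); its whole-volume output
(overlapped patches, probability averaging, threshold > 0.5, removal of
components < 3 mm³) defines the *hard-example region* — lesion area plus
misclassified voxels — from which dense lattice patches (step 8³) train
stage 2 from scratch. At test time the two probability maps are averaged,
thresholded > 0.5, and components under 3 mm³ removed.

Evaluation is two-level: voxel Dice, and lesion-wise F1 / PPVL (precision)
/ SensL (sensitivity) over 26-connected components, plus VolTested (falsely
predicted volume) on cases without true new lesions.

The networks run on a compact numpy autodiff engine included in the
package (`mscascade.nn`), with finite-difference-verified gradients; no GPU
or deep-learning framework is required.

## Worked example

```python
from mscascade import (NetworkConfig, NewLesionCascade, PhantomSpec,
                       TrainingConfig, generate_cohort)

spec = PhantomSpec(shape=(64, 64, 64), n_new_lesions=2,
                   lesion_radius_range_mm=(1.2, 2.0), lesion_contrast=40.0,
                   noise_sigma=2.0, intensity_shift=5.0,
                   deformation_amplitude_vox=1.0)
train = [c.pair for c in generate_cohort(spec, 8, seed=11, zero_lesion_fraction=0.25)]
test  = [c.pair for c in generate_cohort(spec, 4, seed=2011, zero_lesion_fraction=0.0)]

config = TrainingConfig(
    max_epochs=14, patience=7, batch_size=8, learning_rate=2e-3, seed=3,
    network=NetworkConfig(base_channels=(4, 8, 16, 32), patch_shape=(16, 16, 16)),
).with_balanced_regularization()

results = NewLesionCascade(train, config).fit()
print(results.summary())
report = results.evaluate(test)
print(report["per_case"][["case_id", "dsc", "f1", "ppvl", "sensl"]])
```

This trains the reduced-width cascade on eight phantoms (a quarter
lesion-free, as in real longitudinal cohorts) and evaluates on four
held-out phantoms. It prints (~10 min on one CPU):

```
New-lesion detection cascade
============================================================
training cases:            8
patch shape:               (16, 16, 16)
channels:                  (4, 8, 16, 32)
df source:                 learned
parameters per stage:      689,868
threshold / min volume:    >0.5 / 3.0 mm^3
------------------------------------------------------------
stage 1 (lesion-centered):
  patches:                 254
  epochs run:              14
  best epoch / val loss:   14 / 0.0325
stage 2 (hard examples):
  patches:                 122
  epochs run:              14
  best epoch / val loss:   11 / 0.0386
    case_id       dsc   f1  ppvl  sensl
0  case_000  0.938776  1.0   1.0    1.0
1  case_001  0.947368  1.0   1.0    1.0
2  case_002  0.865672  1.0   1.0    1.0
3  case_003  0.962963  1.0   1.0    1.0
```

— 254 stage-1 patches (one per lesion voxel over the cohort), 122
hard-example patches for stage 2, every held-out lesion detected with no
false positives (F1/PPVL/SensL all 1.0) and voxel overlaps (Dice
0.87–0.96) typical of small bright lesions. With full-width networks
(64–512 channels, 32³ patches, 100 epochs — the package defaults) the same
code scales to real cohorts read with `mscascade.volumes.load_case`.

A command-line layer mirrors the library: `mscascade simulate`,
`mscascade train`, `mscascade predict`, `mscascade evaluate`
(`--help` on each).

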