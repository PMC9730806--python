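"""Two-stage cascade: training orchestration, inference and post-processing.

Training (stage cascade):

1. extract lesion-centered patches from every training case;
2. train the first network (FCNN1) on them — sensitivity-oriented, since
   every patch is lesion-centered;
3. run FCNN1 on each training case (overlapped patches, probability
   averaging, threshold > 0.5, removal of components < 3 mm^3);
4. build the hard-example mining mask: lesion area plus FCNN1's
   misclassified voxels;
5. extract dense lattice patches (step 8) restricted to that mask;
6. train the second network (FCNN2) from scratch on them;
7. at test time, average the two probability maps, threshold > 0.5 and
   remove components smaller than 3 mm^3.

The module exposes both the operational functions (train_stage,
predict_stage, binarize, fit_cascade, predict_cascade) and a
model/results pair (:class:`NewLesionCascade` / :class:`CascadeResults`)
wrapping them: build the model from a cohort and a config, call ``fit()``,
inspect ``summary()``, then predict or evaluate from the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .losses import LossWeights
from .networks import JointModel, NetworkConfig, build_joint_model, load_model, save_model
from .patches import (PatchSet, concatenate_patch_sets, grid_patches,
                      hard_example_region, lesion_centered_patches,
                      reconstruct_probability)
from .preprocessing import IntensityStandardizer, fit_standardizer, normalize_case
from .volumes import CasePair, LesionMask, Volume3D

__all__ = [
    "TrainingConfig",
    "InsufficientDataError",
    "ProbabilityMap",
    "CascadeModel",
    "NewLesionCascade",
    "CascadeResults",
    "train_stage",
    "predict_stage",
    "binarize",
    "fit_cascade",
    "predict_cascade",
]

_STRUCTURE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity

#: standardized intensities live on a 0-100 scale; the networks see them
#: divided by this, i.e. in ~[0,1] — keeps activations in range and puts
#: the similarity (MSE) term on the same O(1) scale as the cross-entropy
INPUT_SCALE = 100.0


class InsufficientDataError(ValueError):
    """Too few patches or no lesion voxels to train on."""


@dataclass
class TrainingConfig:
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.25
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    inference_step: Tuple[int, int, int] = (8, 8, 8)
    mining_step: Tuple[int, int, int] = (8, 8, 8)
    threshold: float = 0.5
    min_lesion_volume_mm3: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("need 0 < patience < max_epochs")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0,1)")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1 and learning_rate > 0 required")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0,1)")

    def with_balanced_regularization(self) -> "TrainingConfig":
        """Rescale the smoothness weight by the patch voxel count so the
        summed regularization term sits on the same scale as the per-voxel
        mean similarity term."""
        n_vox = int(np.prod(self.network.patch_shape))
        lw = replace(self.loss_weights,
                     w_regularization=self.loss_weights.w_regularization / n_vox)
        return replace(self, loss_weights=lw)


@dataclass
class ProbabilityMap:
    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.clip(np.asarray(self.data, dtype=np.float32), 0.0, 1.0)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data, self.spacing, self.affine)


# ------------------------------------------------------------- training

class EarlyStopping:
    """Stop when the validation loss has not strictly decreased for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        self.patience = int(patience)
        self.best = np.inf
        self.best_epoch = 0
        self.stall = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True to stop."""
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.stall = 0
            return False
        self.stall += 1
        return self.stall >= self.patience

def _patch_tensors(ps: PatchSet, idx: np.ndarray):
    base = nn.Tensor(ps.baseline[idx][:, None] / INPUT_SCALE)
    fup = nn.Tensor(ps.followup[idx][:, None] / INPUT_SCALE)
    labels = ps.labels[idx][:, None].astype(np.float32) if ps.labels is not None else None
    ext = None
    if ps.dfs is not None:
        ext = nn.Tensor(np.moveaxis(ps.dfs[idx], -1, 1).astype(np.float32))
    return base, fup, labels, ext


def _batch_loss(model: JointModel, ps: PatchSet, idx: np.ndarray,
                weights: LossWeights):
    base, fup, labels, ext = _patch_tensors(ps, idx)
    prob, df, moved, logits = model.forward(base, fup, external_df=ext, with_logits=True)
    ce = nn.bce_with_logits_loss(logits, labels)
    comps = {"segmentation": ce.item(), "similarity": 0.0, "regularization": 0.0}
    loss = nn.scale(ce, weights.w_segmentation)
    if model.cfg.df_source == "learned":
        sim = nn.mse_loss(moved, fup)
        reg = nn.smoothness_loss(df)
        comps["similarity"] = sim.item()
        comps["regularization"] = reg.item()
        loss = nn.add(loss, nn.add(nn.scale(sim, weights.w_similarity),
                                   nn.scale(reg, weights.w_regularization)))
    comps["total"] = loss.item()
    return loss, comps


def _split_train_val(ps: PatchSet, fraction: float, rng: np.random.Generator):
    """75/25 split stratified by case: whole cases go to validation until
    the requested patch fraction is reached, avoiding leakage between
    neighbouring patches of one lesion. Falls back to a patch-level split
    when only one case is present."""
    n = len(ps)
    ids = np.asarray(ps.case_ids if ps.case_ids is not None else [""] * n)
    unique = list(dict.fromkeys(ids.tolist()))
    if len(unique) > 1:
        order = list(rng.permutation(unique))
        val_cases, val_count = [], 0
        for cid in order:
            if len(val_cases) == len(unique) - 1:
                break
            val_cases.append(cid)
            val_count += int(np.sum(ids == cid))
            if val_count >= fraction * n:
                break
        val_mask = np.isin(ids, val_cases)
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(fraction * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[perm[:n_val]] = True
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if len(train_idx) == 0 or len(val_idx) == 0:  # degenerate tiny sets
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:1], perm[1:]
    return train_idx, val_idx


def train_stage(patch_set: PatchSet, cfg: TrainingConfig,
                init_seed: Optional[int] = None) -> Tuple[JointModel, pd.DataFrame]:
    """Train one network stage on a patch set.

    Optimizes the combined loss with Adam; stops at ``max_epochs`` or when
    the validation loss has not strictly decreased for ``patience`` epochs;
    returns the weights of the best validation epoch and the per-epoch
    training log (loss components to a row per epoch).
    """
    if len(patch_set) < 2:
        raise InsufficientDataError(
            f"need at least 2 patches to split train/validation, got {len(patch_set)}")
    if patch_set.labels is None:
        raise InsufficientDataError("training patches carry no labels")
    seed = cfg.seed if init_seed is None else int(init_seed)
    model = build_joint_model(cfg.network, seed=seed)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _split_train_val(patch_set, cfg.validation_fraction, rng)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)

    stopper = EarlyStopping(cfg.patience)
    best_state = model.state_dict()
    log: List[Dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train_idx)
        epoch_comps: List[Dict] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss, comps = _batch_loss(model, patch_set, batch, cfg.loss_weights)
            loss.backward()
            opt.step()
            epoch_comps.append(comps)

        val_losses = []
        for start in range(0, len(val_idx), cfg.batch_size):
            batch = val_idx[start:start + cfg.batch_size]
            _, comps = _batch_loss(model, patch_set, batch, cfg.loss_weights)
            val_losses.append(comps["total"] * len(batch))
        val_loss = float(np.sum(val_losses) / len(val_idx))

        row = {k: float(np.mean([c[k] for c in epoch_comps]))
               for k in ("total", "segmentation", "similarity", "regularization")}
        row.update(epoch=epoch, val_total=val_loss)
        log.append(row)

        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    history = pd.DataFrame(log)
    history.attrs["best_epoch"] = stopper.best_epoch
    history.attrs["best_val"] = stopper.best
    history.attrs["n_train_patches"] = int(len(train_idx))
    history.attrs["n_val_patches"] = int(len(val_idx))
    return model, history


# ------------------------------------------------------------ inference

def predict_stage(model: JointModel, case: CasePair,
                  step: Tuple[int, int, int] = (8, 8, 8),
                  external_df: Optional[np.ndarray] = None,
                  batch_size: int = 16) -> ProbabilityMap:
    """Whole-volume probability map from one stage: overlapped lattice
    patches, batched forward passes, per-voxel probability averaging."""
    ps = grid_patches(case, model.cfg.patch_shape, step, external_df=external_df)
    probs = np.empty((len(ps),) + model.cfg.patch_shape, dtype=np.float64)
    for start in range(0, len(ps), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ps)))
        base, fup, _, ext = _patch_tensors(ps, idx)
        prob, _, _ = model.forward(base, fup, external_df=ext)
        probs[idx] = prob.data[:, 0]
    full = reconstruct_probability(ps.coords, model.cfg.patch_shape, probs, case.shape)
    return ProbabilityMap(full, case.spacing, case.baseline.affine)


def binarize(prob_map, threshold: float = 0.5, min_volume_mm3: float = 3.0,
             spacing=None, affine=None) -> LesionMask:
    """Threshold strictly above ``threshold`` and delete 26-connected
    components smaller than ``min_volume_mm3`` (voxel count x voxel volume)."""
    if isinstance(prob_map, ProbabilityMap):
        data, spacing, affine = prob_map.data, prob_map.spacing, prob_map.affine
    else:
        data = np.asarray(prob_map)
        if spacing is None:
            raise ValueError("spacing required when passing a bare array")
        if affine is None:
            affine = np.diag(list(np.asarray(spacing, float)) + [1.0])
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0,1)")
    binary = data > threshold
    labels, n = ndimage.label(binary, structure=_STRUCTURE)
    if n:
        voxvol = float(np.prod(np.asarray(spacing, float)))
        sizes = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * voxvol >= min_volume_mm3) + 1
        binary = np.isin(labels, keep)
    return LesionMask(binary.astype(np.uint8), np.asarray(spacing, float), affine)


# -------------------------------------------------------------- cascade

@dataclass
class CascadeModel:
    """Two trained stages plus everything needed to reproduce inference."""

    fcnn1: JointModel
    fcnn2: JointModel
    config: TrainingConfig
    standardizer: Optional[IntensityStandardizer] = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_model(self.fcnn1, out / "stage1")
        save_model(self.fcnn2, out / "stage2")
        if self.standardizer is not None:
            self.standardizer.to_json(out / "standardizer.json")
        meta = {
            "threshold": self.config.threshold,
            "min_lesion_volume_mm3": self.config.min_lesion_volume_mm3,
            "inference_step": list(self.config.inference_step),
            "seed": self.config.seed,
        }
        (out / "cascade.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir, config: Optional[TrainingConfig] = None) -> "CascadeModel":
        out = Path(out_dir)
        fcnn1 = load_model(out / "stage1")
        fcnn2 = load_model(out / "stage2")
        meta = json.loads((out / "cascade.json").read_text())
        std_path = out / "standardizer.json"
        std = IntensityStandardizer.from_json(std_path) if std_path.exists() else None
        if config is None:
            config = TrainingConfig(
                network=fcnn1.cfg,
                threshold=meta["threshold"],
                min_lesion_volume_mm3=meta["min_lesion_volume_mm3"],
                inference_step=tuple(meta["inference_step"]),
                seed=meta.get("seed", 0),
            )
        return cls(fcnn1=fcnn1, fcnn2=fcnn2, config=config, standardizer=std)


def _prepare_case(model_std: Optional[IntensityStandardizer], case: CasePair,
                  assume_normalized: bool) -> CasePair:
    if assume_normalized or model_std is None:
        return case
    return normalize_case(case, model_std)


def fit_cascade(cohort: Sequence[CasePair], cfg: TrainingConfig,
                normalize: bool = True,
                external_dfs: Optional[Sequence[Optional[np.ndarray]]] = None,
                ) -> Tuple[CascadeModel, Dict]:
    """Train the full two-stage cascade on a cohort of cases.

    Returns the trained model and a diagnostics dict (per-stage training
    histories and patch counts). Stage 2 trains from scratch with a fresh
    seed (cfg.seed + 1) on dense patches restricted to the union of the
    lesion area and stage 1's misclassified voxels of each training case.
    """
    cohort = list(cohort)
    if external_dfs is None:
        external_dfs = [None] * len(cohort)
    if not any(c.gt_new_lesions is not None and c.gt_new_lesions.data.sum() > 0
               for c in cohort):
        raise InsufficientDataError("no lesion voxels anywhere in the training cohort")

    std = None
    if normalize:
        vols = [c.baseline for c in cohort] + [c.followup for c in cohort]
        masks = [c.brain_mask for c in cohort] * 2
        std = fit_standardizer(vols, masks)
        cohort = [normalize_case(c, std) for c in cohort]

    # stage 1: one patch per lesion voxel, pooled over the cohort; the
    # voxel's position inside its patch is randomized so lattice inference
    # stays within the training distribution
    jitter_rng = np.random.default_rng(cfg.seed + 7919)
    sets1 = [
        lesion_centered_patches(c, cfg.network.patch_shape, external_df=df,
                                jitter_rng=jitter_rng)
        for c, df in zip(cohort, external_dfs)
        if c.gt_new_lesions is not None and c.gt_new_lesions.data.sum() > 0
    ]
    patches1 = concatenate_patch_sets(sets1)
    fcnn1, hist1 = train_stage(patches1, cfg, init_seed=cfg.seed)

    # stage 2: dense patches on the hard-example region of each case
    sets2 = []
    for c, df in zip(cohort, external_dfs):
        if c.gt_new_lesions is None:
            continue
        p1 = predict_stage(fcnn1, c, step=cfg.inference_step, external_df=df)
        m1 = binarize(p1, cfg.threshold, cfg.min_lesion_volume_mm3)
        region = hard_example_region(c.gt_new_lesions, m1)
        if region.data.sum() == 0:
            continue
        sets2.append(grid_patches(c, cfg.network.patch_shape, cfg.mining_step,
                                  region_mask=region, external_df=df))
    if not sets2 or sum(len(s) for s in sets2) < 2:
        raise InsufficientDataError("stage-1 output leaves no hard-example patches to mine")
    patches2 = concatenate_patch_sets(sets2)
    fcnn2, hist2 = train_stage(patches2, cfg, init_seed=cfg.seed + 1)

    model = CascadeModel(fcnn1=fcnn1, fcnn2=fcnn2, config=cfg, standardizer=std)
    diagnostics = {
        "history_stage1": hist1,
        "history_stage2": hist2,
        "n_patches_stage1": len(patches1),
        "n_patches_stage2": len(patches2),
    }
    return model, diagnostics


def predict_cascade(model: CascadeModel, case: CasePair,
                    assume_normalized: bool = False,
                    external_df: Optional[np.ndarray] = None,
                    ) -> Tuple[ProbabilityMap, LesionMask]:
    """Final prediction: voxelwise mean of the two stages' probability
    maps, thresholded > 0.5 with the < 3 mm^3 component filter."""
    case = _prepare_case(model.standardizer, case, assume_normalized)
    cfg = model.config
    y1 = predict_stage(model.fcnn1, case, step=cfg.inference_step, external_df=external_df)
    y2 = predict_stage(model.fcnn2, case, step=cfg.inference_step, external_df=external_df)
    final = ProbabilityMap((y1.data.astype(np.float64) + y2.data.astype(np.float64)) / 2.0,
                           y1.spacing, y1.affine)
    mask = binarize(final, cfg.threshold, cfg.min_lesion_volume_mm3)
    return final, mask


def predict_stage1_only(model: CascadeModel, case: CasePair,
                        assume_normalized: bool = False,
                        external_df: Optional[np.ndarray] = None,
                        ) -> Tuple[ProbabilityMap, LesionMask]:
    """Ablation harness: the first stage alone, same post-processing."""
    case = _prepare_case(model.standardizer, case, assume_normalized)
    cfg = model.config
    y1 = predict_stage(model.fcnn1, case, step=cfg.inference_step, external_df=external_df)
    return y1, binarize(y1, cfg.threshold, cfg.min_lesion_volume_mm3)


# ------------------------------------------------- model/results surface

class NewLesionCascade:
    """New-lesion detection cascade over a training cohort.

    Parameters
    ----------
    cohort : sequence of CasePair
        Training cases (baseline, follow-up, ground-truth new lesions).
    config : TrainingConfig
        Optimization, architecture and post-processing settings.
    normalize : bool
        Fit an intensity standardizer on the cohort and apply it to every
        case seen at train or predict time.
    """

    def __init__(self, cohort: Sequence[CasePair], config: Optional[TrainingConfig] = None,
                 normalize: bool = True,
                 external_dfs: Optional[Sequence[Optional[np.ndarray]]] = None):
        self.cohort = list(cohort)
        self.config = config if config is not None else TrainingConfig()
        self.normalize = normalize
        self.external_dfs = external_dfs

    def fit(self) -> "CascadeResults":
        model, diag = fit_cascade(self.cohort, self.config,
                                  normalize=self.normalize,
                                  external_dfs=self.external_dfs)
        return CascadeResults(model=model, diagnostics=diag,
                              n_training_cases=len(self.cohort))


@dataclass
class CascadeResults:
    """Fitted cascade: trained stages, training diagnostics, prediction
    and evaluation entry points."""

    model: CascadeModel
    diagnostics: Dict
    n_training_cases: int

    def predict(self, case: CasePair, assume_normalized: bool = False,
                external_df: Optional[np.ndarray] = None):
        return predict_cascade(self.model, case, assume_normalized, external_df)

    def predict_stage1(self, case: CasePair, assume_normalized: bool = False,
                       external_df: Optional[np.ndarray] = None):
        return predict_stage1_only(self.model, case, assume_normalized, external_df)

    def evaluate(self, cases: Sequence[CasePair], min_overlap_fraction: float = 0.1,
                 assume_normalized: bool = False) -> Dict:
        from .evaluation import evaluate_cohort

        pairs = []
        ids = []
        for case in cases:
            _, mask = self.predict(case, assume_normalized=assume_normalized)
            pairs.append((mask, case.gt_new_lesions))
            ids.append(case.case_id)
        return evaluate_cohort(pairs, min_overlap_fraction, case_ids=ids)

    def summary(self) -> str:
        h1 = self.diagnostics["history_stage1"]
        h2 = self.diagnostics["history_stage2"]
        cfg = self.model.config
        lines = [
            "New-lesion detection cascade",
            "=" * 60,
            f"training cases:            {self.n_training_cases}",
            f"patch shape:               {cfg.network.patch_shape}",
            f"channels:                  {cfg.network.base_channels}",
            f"df source:                 {cfg.network.df_source}",
            f"parameters per stage:      {self.model.fcnn1.num_parameters():,}",
            f"threshold / min volume:    >{cfg.threshold} / {cfg.min_lesion_volume_mm3} mm^3",
            "-" * 60,
        ]
        for name, h, npatch in (("stage 1 (lesion-centered)", h1,
                                 self.diagnostics["n_patches_stage1"]),
                                ("stage 2 (hard examples)", h2,
                                 self.diagnostics["n_patches_stage2"])):
            lines += [
                f"{name}:",
                f"  patches:                 {npatch}",
                f"  epochs run:              {len(h)}",
                f"  best epoch / val loss:   {h.attrs['best_epoch']} / {h.attrs['best_val']:.4f}",
            ]
        return "\n".join(lines)
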