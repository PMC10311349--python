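"""Contrastive encoder pretraining and main L1 training.

Main training minimizes the mean absolute error between the enhanced patch
and the full-coverage target patch on unmasked pixels, with:

* coverage augmentation — each training example draws one downsampling
  level per epoch from pre-generated thinned copies of the training map
  (levels 1, 1/2, ..., 1/64 by default);
* reference subsampling — a fresh uniform draw of ``refs_per_example``
  panel samples per example per epoch (all panel samples at evaluation);
* AdamW with linear warmup then cosine annealing of the learning rate to
  ``final_lr`` by 95% of the epoch budget;
* early stopping on validation L1 with a configurable patience, returning
  the best-validation parameters.

Pretraining teaches F/E1-E3 a coverage-invariant representation: patches of
the same genomic region at different coverages are pulled together, patches
of other regions in the batch pushed apart (cross-entropy with in-batch
negatives, dot-product similarity, temperature 1), optimized with
layer-wise trust-ratio scaling over Adam (LARS-style) for 20 epochs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .hic_io import ContactMap
from .model import RefPanelUNet
from .preprocess import (Patch, downsample, extract_patch, ice_balance,
                         make_tile_plan, map_scale, scale_patch)

__all__ = [
    "TrainConfig",
    "ContrastiveBatch",
    "DEFAULT_LEVELS",
    "learning_rate",
    "contrastive_loss",
    "PatchDataset",
    "build_dataset",
    "pretrain_encoder",
    "train",
    "TrainResult",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625)


@dataclass
class TrainConfig:
    batch_size: int = 46
    epochs: int = 2000
    lr: float = 1e-3
    final_lr: float = 1e-6
    weight_decay: float = 0.1
    warmup_epochs: int = 5
    refs_per_example: int = 10
    patience: int = 50
    pretrain_epochs: int = 20
    tau: float = 1.0
    cosine_end_frac: float = 0.95
    levels: tuple[float, ...] = DEFAULT_LEVELS
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")
        if any(not 0 < r <= 1 for r in self.levels):
            raise ValueError("augmentation levels must lie in (0, 1]")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """LR schedule: 0 -> lr over warmup, cosine to final_lr at 95% of epochs."""
    end = cfg.cosine_end_frac * cfg.epochs
    if epoch <= cfg.warmup_epochs:
        return cfg.lr * epoch / cfg.warmup_epochs
    if epoch >= end:
        return cfg.final_lr
    t = (epoch - cfg.warmup_epochs) / (end - cfg.warmup_epochs)
    return cfg.final_lr + 0.5 * (cfg.lr - cfg.final_lr) * (1.0 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# Contrastive loss
# ---------------------------------------------------------------------------

@dataclass
class ContrastiveBatch:
    """Anchor/positive embedding pairs with (implicit or explicit) negatives.

    ``h_i`` and ``h_i_plus`` are (B, M) aligned anchor/positive embeddings
    (same region, different downsampling). If ``h_j_minus`` is None the
    negatives for anchor i are the other anchors' positives in the batch
    (in-batch negatives); otherwise it is an explicit (B, K, M) stack.
    """

    h_i: "nn.Tensor"
    h_i_plus: "nn.Tensor"
    h_j_minus: "nn.Tensor | None" = None
    tau: float = 1.0


def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=float),
                                                        requires_grad=False)


def contrastive_loss(batch: ContrastiveBatch) -> nn.Tensor:
    """Mean InfoNCE over anchors; similarity is an (unnormalized) dot product."""
    h = _as_tensor(batch.h_i)
    hp = _as_tensor(batch.h_i_plus)
    if batch.h_j_minus is not None:
        hn = _as_tensor(batch.h_j_minus)
        if hn.shape[1] < 1:
            raise ValueError("contrastive loss requires at least one negative")
        pos = nn.rowwise_dot_stack(h, _reshape3(hp))
        neg = nn.rowwise_dot_stack(h, hn)
        logits = nn.scale_mul(nn.concat_cols(pos, neg), 1.0 / batch.tau)
        return nn.info_nce(logits)
    if h.shape[0] < 2:
        raise ValueError("in-batch negatives require a batch of >= 2 regions")
    sims = nn.scale_mul(nn.matmul(h, nn.transpose2d(hp)), 1.0 / batch.tau)
    return nn.info_nce_pairs(sims)


def _reshape3(t: nn.Tensor) -> nn.Tensor:
    out = t.data[:, None, :]

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[:, 0, :])

    if t.requires_grad:
        return nn.Tensor(out, (t,), backward)
    return nn.Tensor(out, requires_grad=False)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class PatchDataset:
    """Region-aligned patches of one study chromosome at several coverages."""

    level_maps: dict[float, ContactMap]   # balanced maps keyed by ratio
    target_map: ContactMap                # balanced full-coverage map
    corners: list[tuple[int, int]]
    w: int
    levels: tuple[float, ...] = field(init=False)

    def __post_init__(self):
        self.levels = tuple(sorted(self.level_maps, reverse=True))

    def __len__(self):
        return len(self.corners)

    def pair_scale(self, level) -> float:
        """Shared study/target scale: the larger of the two map scales."""
        if not hasattr(self, "_pair_scales"):
            self._pair_scales = {}
        if level not in self._pair_scales:
            self._pair_scales[level] = max(map_scale(self.level_maps[level]),
                                           map_scale(self.target_map))
        return self._pair_scales[level]

    def study_target(self, corner, level) -> tuple[Patch, Patch]:
        """Study/target pair in the shared (pair map-scale) unit system."""
        sv, sm = extract_patch(self.level_maps[level], corner, self.w)
        tv, tm = extract_patch(self.target_map, corner, self.w)
        mask = sm & tm
        if not mask.any():
            raise ValueError(f"fully masked example at corner {corner}")
        scale = self.pair_scale(level)
        study = scale_patch(sv, mask, corner, scale=scale)
        target = scale_patch(tv, mask, corner, scale=scale)
        return study, target

    def study_only(self, corner, level) -> Patch:
        """A single patch scaled by its source map's scale (pretraining views)."""
        sv, sm = extract_patch(self.level_maps[level], corner, self.w)
        return scale_patch(sv, sm, corner, scale=map_scale(self.level_maps[level]))


def build_dataset(raw_cm: ContactMap, w: int, trim: int,
                  levels: tuple[float, ...] = DEFAULT_LEVELS,
                  corners: list[tuple[int, int]] | None = None,
                  seed: int = 0, ice_tol: float = 1e-5,
                  ice_max_iter: int = 200) -> PatchDataset:
    """Thin a raw map to each coverage level, re-balance, and index corners.

    Downsampling acts on raw counts and each level is freshly ICE-balanced
    (sequencing depth precedes normalization in real pipelines). Corner list
    defaults to the full tile plan of the chromosome.
    """
    ss = np.random.SeedSequence([seed, 0xDA7A])
    child = ss.generate_state(len(levels))
    level_maps = {}
    for k, r in enumerate(levels):
        thinned = downsample(raw_cm, r, seed=int(child[k] % (2 ** 31)))
        level_maps[r] = ice_balance(thinned, tol=ice_tol, max_iter=ice_max_iter)
    target = level_maps[max(levels)] if 1.0 in level_maps else \
        ice_balance(raw_cm, tol=ice_tol, max_iter=ice_max_iter)
    if corners is None:
        plan = make_tile_plan(raw_cm.n_bins, w, trim, raw_cm.max_distance_bins)
        corners = plan.tiles
    return PatchDataset(level_maps=level_maps, target_map=target,
                        corners=list(corners), w=w)


# ---------------------------------------------------------------------------
# Contrastive pretraining
# ---------------------------------------------------------------------------

def pretrain_encoder(dataset: PatchDataset, model: RefPanelUNet,
                     cfg: TrainConfig) -> list[float]:
    """Contrastively pretrain F/E1-E3 in place; returns per-epoch losses.

    Each batch draws, per region, two patches of the same region at two
    distinct coverage levels (anchor and positive); the other regions'
    positives serve as in-batch negatives.
    """
    if len(dataset) < 2:
        raise ValueError("pretraining needs at least two regions "
                         "(one region leaves no negatives)")
    enc_params = {k: model.params[k] for k in model.encoder_param_names()}
    opt = nn.LARS(enc_params, lr=cfg.lr, weight_decay=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E7]))
    model.rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))
    model.train()
    losses = []
    corners = list(dataset.corners)
    bs = min(cfg.batch_size, len(corners))
    for _ in range(cfg.pretrain_epochs):
        order = rng.permutation(len(corners))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order) - 1, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue
            anchors, positives = [], []
            for k in idx:
                la, lp = rng.choice(len(dataset.levels), size=2, replace=False)
                anchors.append(dataset.study_only(corners[k], dataset.levels[la]).values)
                positives.append(dataset.study_only(corners[k], dataset.levels[lp]).values)
            emb = model.encode(np.asarray(anchors + positives))
            h = nn.slice_batch(emb.key, 0, len(idx))
            hp = nn.slice_batch(emb.key, len(idx), None)
            loss = contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=hp, tau=cfg.tau))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        logger.info("pretrain epoch %d/%d loss %.4f", len(losses),
                    cfg.pretrain_epochs, losses[-1])
    return losses


# ---------------------------------------------------------------------------
# Main training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: RefPanelUNet
    history: pd.DataFrame     # epoch, train_l1, val_l1, lr
    best_val: float
    best_epoch: int


def _ref_patches(panel_maps: list[ContactMap], corner, w, cache: dict,
                 indices=None, maps_key=0) -> np.ndarray:
    """Scaled reference patches at a corner (each by its own max), cached."""
    indices = range(len(panel_maps)) if indices is None else indices
    out = []
    for r in indices:
        key = (maps_key, r, corner)
        if key not in cache:
            rv, rm = extract_patch(panel_maps[r], corner, w)
            if rm.any():
                cache[key] = scale_patch(rv, rm, corner,
                                         scale=map_scale(panel_maps[r])).values
            else:
                cache[key] = np.zeros((w, w))
        out.append(cache[key])
    return np.asarray(out)


def _as_task_list(datasets, panels):
    """Normalize (dataset, panel) arguments to parallel lists.

    Training may span several chromosomes, each with its own patch dataset
    and reference-panel maps (the full-scale setting trains on all
    autosomes); a single dataset plus one panel list is the common case.
    """
    if isinstance(datasets, PatchDataset):
        datasets = [datasets]
        panels = [panels]
    if len(panels) != len(datasets):
        raise ValueError("need one panel-map list per training chromosome")
    return list(datasets), [list(p) if p else [] for p in panels]


def _validation_l1(model: RefPanelUNet, val_set, panel_maps,
                   cache: dict) -> float:
    """Mean L1 on the validation corners at the lowest coverage level,
    using all panel samples as references (evaluation mode)."""
    datasets, panels = _as_task_list(val_set, panel_maps)
    model.eval()
    losses = []
    for d, (ds, pmaps) in enumerate(zip(datasets, panels)):
        level = min(ds.levels)
        for corner in ds.corners:
            study, target = ds.study_target(corner, level)
            refs = _ref_patches(pmaps, corner, ds.w, cache,
                                maps_key=d) if model.use_panel else None
            pred = model.forward(study.values, refs)
            loss = nn.l1_masked(pred, target.values[None, None],
                                study.mask[None, None])
            losses.append(float(loss.data))
    model.train()
    return float(np.mean(losses))


def train(model: RefPanelUNet, train_set, val_set,
          panel_maps, cfg: TrainConfig) -> TrainResult:
    """L1 training with coverage augmentation, reference subsampling,
    warmup+cosine LR, and early stopping on validation L1.

    ``train_set``/``val_set`` are :class:`PatchDataset` objects (or lists of
    them, one per chromosome, with ``panel_maps`` then a parallel list of
    reference-map lists).
    """
    if val_set is None or (isinstance(val_set, PatchDataset) and
                           len(val_set) == 0):
        raise ValueError("a validation set is required (early stopping is "
                         "undefined without one)")
    datasets, panels = _as_task_list(train_set, panel_maps)
    if isinstance(val_set, PatchDataset) and len(datasets) == 1:
        val_args = (val_set, panels[0])
    else:
        val_args = (val_set, panel_maps)
    if model.use_panel and any(not p for p in panels):
        raise ValueError("panel model requires a nonempty reference panel")
    opt = nn.AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7121]))
    model.rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD1]))
    model.train()
    cache: dict = {}
    history = []
    best_val, best_epoch = np.inf, -1
    best_params, best_bn = None, None
    wait = 0
    examples = [(d, corner) for d, ds in enumerate(datasets)
                for corner in ds.corners]
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = learning_rate(epoch, cfg)
        order = rng.permutation(len(examples))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            for k in idx:
                d, corner = examples[k]
                ds, pmaps = datasets[d], panels[d]
                level = ds.levels[rng.integers(len(ds.levels))]
                study, target = ds.study_target(corner, level)
                if model.use_panel:
                    n_refs = min(cfg.refs_per_example, len(pmaps))
                    ref_idx = rng.choice(len(pmaps), size=n_refs,
                                         replace=False)
                    refs = _ref_patches(pmaps, corner, ds.w,
                                        cache, ref_idx, maps_key=d)
                else:
                    refs = None
                pred = model.forward(study.values, refs)
                loss = nn.l1_masked(pred, target.values[None, None],
                                    study.mask[None, None])
                loss.backward()
                train_losses.append(float(loss.data))
            for p in model.params.values():
                if p.grad is not None:
                    p.grad /= len(idx)
            opt.step()
        val_l1 = _validation_l1(model, *val_args, cache)
        history.append({"epoch": epoch, "train_l1": float(np.mean(train_losses)),
                        "val_l1": val_l1, "lr": opt.lr})
        logger.info("epoch %d train %.4f val %.4f lr %.2e", epoch,
                    history[-1]["train_l1"], val_l1, opt.lr)
        if val_l1 < best_val:
            best_val, best_epoch, wait = val_l1, epoch, 0
            best_params = {k: p.data.copy() for k, p in model.params.items()}
            best_bn = copy.deepcopy(model.bn_running)
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d (best %.4f @ %d)",
                            epoch, best_val, best_epoch)
                break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
        model.bn_running = best_bn
    model.eval()
    return TrainResult(model=model, history=pd.DataFrame(history),
                       best_val=best_val, best_epoch=best_epoch)
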