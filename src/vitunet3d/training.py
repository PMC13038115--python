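"""Training, evaluation and prediction driver.

Optimization recipe: Adam (initial LR 1e-3, weight decay 1e-5), batch size 2,
hybrid dice+focal loss on label-smoothed targets (factor 0.1), gradient
clipping to unit global norm, reduce-on-plateau LR schedule (factor 0.5,
patience 5) monitoring mean validation DSC, and DSC-based early stopping.
Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor
from .data import (CaseRecord, crop_volume, normalize_channels, remap_labels,
                   stack_modalities)
from .metrics import REGION_LABELS, dsc, evaluate_labels, region_masks
from .network import ModelConfig, VitUNet3D
from .nn import Adam, clip_grad_norm
from .objectives import LossWeights, hybrid_loss, one_hot, smooth_labels

__all__ = ["TrainConfig", "RunLog", "ReduceLROnPlateau", "prepare_case",
           "train_step", "fit_volume", "train", "evaluate", "predict_case"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 140
    batch_size: int = 2
    lr: float = 1e-3
    weight_decay: float = 1e-5
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    grad_clip_norm: float = 1.0
    early_patience: int = 15
    label_smoothing: float = 0.1
    loss: LossWeights = field(default_factory=LossWeights)
    crop_size: tuple[int, int, int] | None = None
    crop_mode: str = "center"
    normalize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.plateau_patience < 1 or self.early_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not (self.lr >= 0 and self.weight_decay >= 0
                and self.label_smoothing >= 0):
            raise ValueError("rates must be >= 0")


@dataclass
class RunLog:
    """Per-epoch training record, serializable as CSV or JSON lines."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(dict(kwargs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


class ReduceLROnPlateau:
    """Halve (by ``factor``) the LR after ``patience`` non-improving epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 5, mode: str = "max", eps: float = 1e-12):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.best = -np.inf
        self.stale = 0
        self.eps = eps

    def step(self, metric: float) -> bool:
        """Returns True if the LR was reduced this epoch."""
        if self.sign * metric > self.best + self.eps:
            self.best = self.sign * metric
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.opt.lr *= self.factor
            self.stale = 0
            return True
        return False


def prepare_case(case: CaseRecord, crop_size=None, crop_mode: str = "center",
                 normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Case -> (3-channel input volume, dense class labels {0..3})."""
    x = stack_modalities(case)
    labels = case.labels
    if crop_size is not None:
        x, labels = crop_volume(x, labels, size=crop_size, mode=crop_mode)
    if normalize:
        x = normalize_channels(x)
    return x, remap_labels(labels)


def train_step(model: VitUNet3D, optimizer: Adam, x: np.ndarray,
               classes: np.ndarray, weights: LossWeights,
               label_smoothing: float, grad_clip_norm: float) -> float:
    """One optimization step on a (B, 3, D, H, W) batch; returns the loss."""
    num_classes = model.cfg.num_classes
    target = smooth_labels(one_hot(classes, num_classes), label_smoothing)
    scores = model(x)
    probs = scores.transpose(0, 2, 3, 4, 1).reshape(-1, num_classes) \
        .softmax(axis=-1)
    loss = hybrid_loss(probs, Tensor(target.reshape(-1, num_classes)), weights)
    loss_val = float(loss.data)
    if not np.isfinite(loss_val):
        raise RuntimeError(
            f"non-finite training loss ({loss_val}); aborting — check LR/inputs")
    model.zero_grad()
    loss.backward()
    clip_grad_norm(model.parameters(), grad_clip_norm)
    optimizer.step()
    return loss_val


def fit_volume(model: VitUNet3D, x: np.ndarray, classes: np.ndarray,
               steps: int, cfg: TrainConfig = TrainConfig()) -> list[float]:
    """Repeatedly fit one volume for ``steps`` steps (overfitting probe)."""
    model.train()
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    xb = x[None] if x.ndim == 4 else x
    cb = classes[None] if classes.ndim == 3 else classes
    return [train_step(model, opt, xb, cb, cfg.loss, cfg.label_smoothing,
                       cfg.grad_clip_norm) for _ in range(steps)]


def _validation_dsc(model: VitUNet3D, cases: list[CaseRecord],
                    cfg: TrainConfig) -> dict[str, float]:
    per_region = {r: [] for r in REGION_LABELS}
    for case in cases:
        x, classes = prepare_case(case, cfg.crop_size, cfg.crop_mode,
                                  cfg.normalize)
        pred = model.predict_labels(x[None])[0]
        pred_regions = region_masks(remap_labels(pred, inverse=True))
        true_regions = region_masks(remap_labels(classes, inverse=True))
        for r in REGION_LABELS:
            per_region[r].append(dsc(pred_regions[r], true_regions[r]))
    out = {r: float(np.mean(v)) for r, v in per_region.items()}
    out["mean"] = float(np.mean(list(out.values())))
    return out


def train(model: VitUNet3D, train_cases: list[CaseRecord],
          val_cases: list[CaseRecord], cfg: TrainConfig = TrainConfig()
          ) -> tuple[RunLog, dict]:
    """Full training loop; returns the run log and the best checkpoint state.

    The checkpoint with the highest mean validation DSC is retained; the LR
    halves after ``plateau_patience`` stagnant epochs and training stops
    early after ``early_patience`` consecutive non-improving epochs.
    """
    if not train_cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    model.train()
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
    log = RunLog()
    best_state = model.state_dict()
    best_dsc = -np.inf
    stale = 0
    prepared = [prepare_case(c, cfg.crop_size, cfg.crop_mode, cfg.normalize)
                for c in train_cases]
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(prepared))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = np.stack([prepared[i][0] for i in idx])
            cb = np.stack([prepared[i][1] for i in idx])
            losses.append(train_step(model, opt, xb, cb, cfg.loss,
                                     cfg.label_smoothing, cfg.grad_clip_norm))
        val = _validation_dsc(model, val_cases, cfg) if val_cases else {"mean": np.nan}
        log.append(epoch=epoch, train_loss=float(np.mean(losses)),
                   lr=opt.lr, seconds=round(time.time() - t0, 3),
                   **{f"val_dsc_{k}": v for k, v in val.items()})
        metric = val["mean"]
        if np.isfinite(metric) and metric > best_dsc:
            best_dsc = metric
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
        if val_cases:
            sched.step(metric)
        if stale >= cfg.early_patience:
            break
    return log, best_state


def predict_case(model: VitUNet3D, case: CaseRecord,
                 cfg: TrainConfig = TrainConfig()) -> np.ndarray:
    """Predicted {0,1,2,4} label volume for one case."""
    x, _ = prepare_case(case, cfg.crop_size, cfg.crop_mode, cfg.normalize)
    pred = model.predict_labels(x[None])[0]
    return remap_labels(pred, inverse=True)


def evaluate(model: VitUNet3D, cases: list[CaseRecord],
             cfg: TrainConfig = TrainConfig(), tolerance: float = 1.0
             ) -> pd.DataFrame:
    """Per-case, per-region seven-metric report plus Avg rows.

    Averages are arithmetic means over regions within a case and over cases
    per region; distance metrics may be NaN for empty regions and are
    averaged with NaN exclusion (warned).
    """
    frames = []
    for case in cases:
        pred = predict_case(model, case, cfg)
        _, truth = prepare_case(case, cfg.crop_size, cfg.crop_mode, False)
        rep = evaluate_labels(pred, remap_labels(truth, inverse=True),
                              spacing=case.spacing, tolerance=tolerance)
        rep.insert(0, "case_id", case.case_id)
        frames.append(rep.reset_index())
    table = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        region_means = table.groupby("region", sort=False).mean(numeric_only=True)
    region_means.insert(0, "case_id", "Avg")
    avg_row = region_means.mean(numeric_only=True).to_frame().T
    avg_row.insert(0, "case_id", "Avg")
    avg_row.index = ["Avg"]
    summary = pd.concat([region_means, avg_row]).reset_index(
        names="region")
    return pd.concat([table, summary], ignore_index=True)
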