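"""Seeded training, evaluation and prediction for the segmentation model.

The training recipe follows the standard lightweight-segmentation setup:
BCE+Dice loss, AdamW, cosine-annealed learning rate from ``lr_init`` down to
``lr_min`` over the run, batch size 8, flip/rotation augmentation.  All
randomness (parameter init, shuffling, augmentation) derives from one seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import augment
from .metrics import (MetricsReport, bce_dice_loss, confusion_counts,
                      segmentation_metrics)
from .model import ModelConfig, UltraLightVMUNet, build_model
from .nn.optim import AdamW, cosine_annealing_lr

__all__ = ["TrainConfig", "train_loop", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 250
    batch_size: int = 8
    lr_init: float = 1e-3
    lr_min: float = 1e-5
    weight_decay: float = 1e-2
    seed: int = 0
    w_bce: float = 1.0
    w_dice: float = 1.0
    augment: bool = True
    max_rotation: float = 30.0
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be smaller than lr_init")


def _as_batch(records) -> tuple:
    images = np.stack([r.image for r in records]).astype(np.float32)
    masks = np.stack([r.mask for r in records])[:, None].astype(np.float32)
    return images, masks


def train_loop(cfg: TrainConfig, train_records, val_records=None, out_dir=None):
    """Train a model; returns ``(model, history)``.

    ``history`` is a list of per-epoch dicts (mean training loss, learning
    rate, validation DSC).  The parameters with the best validation DSC are
    restored at the end and, when ``out_dir`` is given, written as a
    checkpoint together with the config and a TSV log.
    """
    if not train_records:
        raise ValueError("training set is empty")
    model = build_model(cfg.model, seed=cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr_init,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    aug_seeds = np.random.SeedSequence([cfg.seed, 2]).generate_state(
        cfg.epochs * len(train_records)).astype(np.int64)

    history = []
    best = {"dsc": -1.0, "state": model.state_dict(), "epoch": -1}
    for epoch in range(cfg.epochs):
        opt.lr = cosine_annealing_lr(epoch, cfg.epochs, cfg.lr_init, cfg.lr_min)
        order = rng.permutation(len(train_records))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = []
            for j in idx:
                rec = train_records[j]
                if cfg.augment:
                    rec = augment(rec, int(aug_seeds[epoch * len(train_records) + j]),
                                  max_rotation=cfg.max_rotation)
                batch.append(rec)
            images, masks = _as_batch(batch)
            opt.zero_grad()
            pred = model(images)
            loss = bce_dice_loss(pred, masks, w_bce=cfg.w_bce, w_dice=cfg.w_dice)
            loss_val = float(loss)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch}, batch "
                    f"{start // cfg.batch_size}; lr={opt.lr:.2e}")
            loss.backward()
            opt.step()
            losses.append(loss_val)
        entry = {"epoch": epoch, "lr": opt.lr,
                 "train_loss": float(np.mean(losses))}
        if val_records:
            report = evaluate(model, val_records)
            entry["val_dsc"] = report.dsc
            if report.dsc > best["dsc"]:
                best = {"dsc": report.dsc, "state": model.state_dict(),
                        "epoch": epoch}
        history.append(entry)
        log.info("epoch %d: loss=%.4f lr=%.2e val_dsc=%s", epoch,
                 entry["train_loss"], opt.lr, entry.get("val_dsc"))

    if val_records and best["epoch"] >= 0:
        model.load_state_dict(best["state"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, cfg, out_dir / "checkpoint.npz")
        _write_history(history, out_dir / "log.tsv")
    return model, history


def _write_history(history, path):
    keys = sorted({k for h in history for k in h})
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for h in history:
            fh.write("\t".join(str(h.get(k, "")) for k in keys) + "\n")


def evaluate(model, records, threshold: float = 0.5, batch_size: int = 8,
             out_prefix=None) -> MetricsReport:
    """Pooled confusion counts over ``records`` -> the six metrics.
    Optionally writes ``<out_prefix>.json`` and ``<out_prefix>.tsv``."""
    if isinstance(model, (str, Path)):
        model, _ = load_checkpoint(model)
    if not records:
        raise ValueError("evaluation set is empty")
    pooled = None
    for start in range(0, len(records), batch_size):
        images, masks = _as_batch(records[start:start + batch_size])
        pred = model(images).data
        c = confusion_counts(pred, masks.astype(np.uint8), threshold=threshold)
        pooled = c if pooled is None else pooled + c
    report = segmentation_metrics(pooled)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(out_prefix.with_suffix(".json"), "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        with open(out_prefix.with_suffix(".tsv"), "w") as fh:
            d = report.as_dict()
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(f"{v:.6f}" for v in d.values()) + "\n")
    return report


def predict(model, records, threshold: float = 0.5, batch_size: int = 8):
    """Binary masks (uint8 {0, 1} arrays) for a list of records."""
    if isinstance(model, (str, Path)):
        model, _ = load_checkpoint(model)
    masks = []
    for start in range(0, len(records), batch_size):
        images, _ = _as_batch(records[start:start + batch_size])
        pred = model(images).data[:, 0]
        masks.extend((p >= threshold).astype(np.uint8) for p in pred)
    return masks


def _config_to_jsonable(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["model"]["channels"] = list(d["model"]["channels"])
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    model = dict(d.get("model", {}))
    model["channels"] = tuple(model.get("channels", (8, 16, 24, 32, 48, 64)))
    rest = {k: v for k, v in d.items() if k != "model"}
    return TrainConfig(model=ModelConfig(**model), **rest)


def save_checkpoint(model: UltraLightVMUNet, cfg: TrainConfig, path) -> None:
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(path, config=json.dumps(_config_to_jsonable(cfg)), **arrays)


def load_checkpoint(path):
    """Rebuild (model, TrainConfig) from a checkpoint; raises on any
    mismatch between stored arrays and the configured architecture."""
    with np.load(path, allow_pickle=False) as npz:
        cfg = _config_from_dict(json.loads(str(npz["config"])))
        state = {k[len("param:"):]: npz[k] for k in npz.files
                 if k.startswith("param:")}
    model = build_model(cfg.model, seed=cfg.seed)
    model.load_state_dict(state)
    return model, cfg
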