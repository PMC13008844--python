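"""Staged training loop for RAM-UNet.

Training follows the two-phase transfer-learning recipe: Adam at an initial
learning rate of 1e-4 decayed by cosine annealing over the full run, batch
size 4, 300 epochs of which the first 100 keep the encoder ("backbone")
frozen so that only the context block, decoder and classifier adapt, after
which all parameters are unfrozen.  Validation runs every ``eval_every``
epochs and at the final epoch; the checkpoint with the highest validation
mIoU is kept (ties resolved to the earlier epoch).

The defaults reproduce the full-scale recipe; tests and the worked examples
run a width-reduced model at 96 px for a handful of epochs with the freeze
phase disabled, since no pretrained weights are involved at that scale.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .losses import LossConfig, composite_loss
from .metrics import ConfusionMatrix, MetricReport, metric_report
from .model import ModelConfig, RamUnet
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cosine_lr",
    "apply_freeze_policy",
    "fit",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONE_PREFIX = "encoder."


@dataclass
class TrainConfig:
    total_epochs: int = 300
    freeze_epochs: int = 100
    batch_size: int = 4
    lr0: float = 1e-4
    lr_min: float = 0.0
    eval_every: int = 10
    input_size: int = 512
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.freeze_epochs > self.total_epochs:
            raise ValueError("freeze_epochs cannot exceed total_epochs")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr_min > self.lr0:
            raise ValueError("lr_min cannot exceed lr0")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "total_epochs",
                "freeze_epochs",
                "batch_size",
                "lr0",
                "lr_min",
                "eval_every",
                "input_size",
                "seed",
            )
        }
        d["loss"] = {"alpha": self.loss.alpha, "eps": self.loss.eps, "clip": self.loss.clip}
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "loss" in d:
            d["loss"] = LossConfig(**d["loss"])
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_epochs: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_miou: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_miou: float = -1.0

    def record_val(self, epoch: int, loss: float, miou: float) -> bool:
        """Record one validation pass; True when this is a new best."""
        self.val_epochs.append(epoch)
        self.val_loss.append(loss)
        self.val_miou.append(miou)
        if miou > self.best_val_miou:  # strict: ties keep the earlier epoch
            self.best_val_miou = miou
            self.best_epoch = epoch
            return True
        return False

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    def write_csv(self, path: str | Path) -> None:
        val_at = dict(zip(self.val_epochs, zip(self.val_loss, self.val_miou)))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "lr", "val_loss", "val_miou"])
            for e, (tl, lr) in enumerate(zip(self.train_loss, self.lr)):
                vl, vm = val_at.get(e, ("", ""))
                writer.writerow([e, f"{tl:.6f}", f"{lr:.8g}", vl, vm])


def cosine_lr(epoch: int, total: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate:
    lr_min + 0.5 (lr0 - lr_min)(1 + cos(pi * epoch / total))."""
    if total <= 0:
        raise ValueError("total epochs must be positive")
    if not 0 <= epoch <= total:
        raise ValueError(f"epoch {epoch} outside [0, {total}]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * epoch / total))


def apply_freeze_policy(model: RamUnet, epoch: int, freeze_epochs: int) -> set[str]:
    """Freeze or release the encoder according to the staged schedule.

    Before ``freeze_epochs`` the encoder parameters are excluded from
    updates; from that epoch on everything trains.  Returns the names of the
    trainable parameters.
    """
    frozen = epoch < freeze_epochs
    trainable = set()
    for name, p in model.named_parameters():
        if frozen and name.startswith(_BACKBONE_PREFIX):
            p.requires_grad = False
        else:
            p.requires_grad = True
            trainable.add(name)
    return trainable


def _foreground_prob(logits: Tensor) -> Tensor:
    """P(stem) from 2-channel scores: sigmoid of the score margin."""
    return (logits[:, 1] - logits[:, 0]).sigmoid()


def _stack_batch(dataset, indices, input_size: int | None) -> tuple[np.ndarray, np.ndarray]:
    imgs, masks = [], []
    for i in indices:
        img, msk = dataset[i]
        imgs.append(np.asarray(img, dtype=np.float32))
        masks.append((np.asarray(msk) > 0).astype(np.float32))
    return np.stack(imgs), np.stack(masks)


def evaluate(model: RamUnet, dataset) -> MetricReport:
    """Accumulate a single global confusion matrix over every pixel of the
    dataset, then compute the metric report.  Order-invariant."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    model.eval()
    cm = ConfusionMatrix()
    for img, msk in dataset:
        pred = model.predict(np.asarray(img, dtype=np.float32))
        cm.update(pred, (np.asarray(msk) > 0).astype(np.uint8))
    model.train()
    return metric_report(cm)


def _val_loss(model: RamUnet, dataset, loss_cfg: LossConfig) -> float:
    model.eval()
    total = 0.0
    with nn.no_grad():
        for img, msk in dataset:
            logits = model(Tensor(np.asarray(img, dtype=np.float32)[None]))
            p = _foreground_prob(logits)
            total += float(composite_loss(p, (np.asarray(msk) > 0).astype(np.float32)[None], loss_cfg).item())
    model.train()
    return total / len(dataset)


def save_checkpoint(path: str | Path, model: RamUnet, config: TrainConfig, epoch: int, val_miou: float | None = None) -> None:
    """Single-file archive: weights + buffers + config + epoch."""
    meta = {"config": config.to_dict(), "epoch": epoch, "val_miou": val_miou}
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[RamUnet, TrainConfig, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/") :]: data[k] for k in data.files if k.startswith("state/")}
    config = TrainConfig.from_dict(meta["config"])
    model = RamUnet(config.model)
    model.load_state_dict(state)
    return model, config, meta


def fit(
    config: TrainConfig,
    train_set,
    val_set,
    out_dir: str | Path | None = None,
) -> tuple[RamUnet, TrainHistory]:
    """Train RAM-UNet on (image, mask) pair sequences.

    Every source of randomness (weight init, shuffling) derives from
    ``config.seed``; two runs with the same config and data produce
    identical loss trajectories on the same hardware.  A non-finite loss
    aborts with diagnostics.  Checkpoints: best-by-val-mIoU and last.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.write_yaml(out / "resolved_config.yaml")
    nn.set_seed(config.seed)
    model = RamUnet(config.model)
    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(model.parameters(), lr=config.lr0)
    history = TrainHistory()
    n = len(train_set)

    for epoch in range(config.total_epochs):
        lr = cosine_lr(epoch, config.total_epochs, config.lr0, config.lr_min)
        optimizer.lr = lr
        apply_freeze_policy(model, epoch, config.freeze_epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            images, masks = _stack_batch(train_set, idx, config.input_size)
            logits = model(Tensor(images))
            p = _foreground_prob(logits)
            loss = composite_loss(p, masks, config.loss)
            value = float(loss.item())
            if not math.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, batch {start // config.batch_size}; "
                    f"lr={lr:.3g}, batch plants={list(idx)}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)
        history.train_loss.append(float(np.mean(losses)))
        history.lr.append(lr)
        logger.info("epoch %d: train loss %.4f lr %.3g", epoch, history.train_loss[-1], lr)

        last = epoch == config.total_epochs - 1
        if len(val_set) and ((epoch + 1) % config.eval_every == 0 or last):
            report = evaluate(model, val_set)
            vloss = _val_loss(model, val_set, config.loss)
            is_best = history.record_val(epoch, vloss, report.miou)
            logger.info("epoch %d: val loss %.4f mIoU %.2f%%", epoch, vloss, report.miou)
            if is_best and out is not None:
                save_checkpoint(out / "best.npz", model, config, epoch, report.miou)
        if last and out is not None:
            save_checkpoint(out / "last.npz", model, config, epoch, history.best_val_miou)
            history.write_json(out / "history.json")
            history.write_csv(out / "history.csv")
    return model, history
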