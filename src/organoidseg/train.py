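"""Seeded SGD training loop, checkpointing and tiled inference.

Training follows the standard recipe for this architecture family: SGD
with momentum on the compound BCE+Dice objective with deep supervision
over all six side maps, per-epoch validation, and retention of the
checkpoint with the best validation F1.  Everything stochastic (weight
init, shuffling, dropout) derives from a single seed, so runs are
bit-reproducible on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data import AnnotatedImage
from .model import ACU2Net, NetworkConfig, assemble_acu2net
from .nn import Tensor, set_global_seed
from .objectives import (
    Metrics,
    combined_loss_t,
    confusion_counts,
    metrics,
    ConfusionCounts,
)


@dataclass
class TrainConfig:
    epochs: int = 1000
    optimizer: str = "sgd"
    learning_rate: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    dropout_p: float = 0.5
    seed: int = 0
    early_stop_patience: int | None = None
    deep_supervision: bool = True
    threshold: float = 0.5
    stop_at_val_f1: float | None = None  # optional early exit for overfit runs

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_loss: float
    val_metrics: Metrics


def _to_batch(samples: list[AnnotatedImage]):
    x = np.stack([s.image.astype(np.float32).transpose(2, 0, 1) / 255.0 for s in samples])
    y = np.stack([s.mask.astype(np.float32)[None] for s in samples])
    return x, y


def train(model: ACU2Net, train_set: list[AnnotatedImage],
          val_set: list[AnnotatedImage], cfg: TrainConfig):
    """Train in place; returns (best_checkpoint_dict, list of EpochLog)."""
    cfg.validate()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    set_global_seed(cfg.seed)
    model.config.dropout_p = cfg.dropout_p
    opt = nn.SGD(model.parameters(), cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    order_rng = np.random.default_rng(cfg.seed + 1)

    logs: list[EpochLog] = []
    best: dict | None = None
    best_f1 = -np.inf
    since_best = 0

    for epoch in range(1, cfg.epochs + 1):
        model.train()
        idx = order_rng.permutation(len(train_set))
        losses = []
        for b0 in range(0, len(idx), cfg.batch_size):
            batch = [train_set[i] for i in idx[b0 : b0 + cfg.batch_size]]
            x, y = _to_batch(batch)
            out = model(Tensor(x))
            loss, _ = combined_loss_t(
                out["fused"], out["sides"], y, deep_supervision=cfg.deep_supervision
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_loss, val_m = evaluate(model, val_set, cfg)
        logs.append(EpochLog(epoch, float(np.mean(losses)), val_loss, val_m))

        f1 = val_m.f1 if np.isfinite(val_m.f1) else -np.inf
        if f1 > best_f1:
            best_f1 = f1
            since_best = 0
            best = {
                "state": model.state_dict(),
                "config": model.config.to_dict(),
                "seed": cfg.seed,
                "epoch": epoch,
                "val_f1": float(val_m.f1),
            }
        else:
            since_best += 1
        if cfg.stop_at_val_f1 is not None and f1 >= cfg.stop_at_val_f1:
            break
        if cfg.early_stop_patience is not None and since_best >= cfg.early_stop_patience:
            break
    assert best is not None
    return best, logs


def evaluate(model: ACU2Net, samples: list[AnnotatedImage],
             cfg: TrainConfig) -> tuple[float, Metrics]:
    """Validation loss and pooled (micro) confusion metrics."""
    model.eval()
    total_loss = 0.0
    counts = ConfusionCounts()
    with nn.no_grad():
        for b0 in range(0, len(samples), cfg.batch_size):
            batch = samples[b0 : b0 + cfg.batch_size]
            x, y = _to_batch(batch)
            out = model(Tensor(x))
            loss, _ = combined_loss_t(
                out["fused"], out["sides"], y, deep_supervision=cfg.deep_supervision
            )
            total_loss += float(loss.data) * len(batch)
            pred = (out["fused"].data >= cfg.threshold).astype(np.uint8)
            counts = counts + confusion_counts(pred, y.astype(np.uint8))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate Se/Sp early in training
        m = metrics(counts)
    return total_loss / len(samples), m


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(ckpt: dict, path) -> None:
    path = Path(path)
    arrays = {f"param::{k}": v for k, v in ckpt["state"].items()}
    meta = {k: v for k, v in ckpt.items() if k != "state"}
    np.savez(path, __meta__=np.str_(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[ACU2Net, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    cfg = NetworkConfig.from_dict(meta["config"])
    model = assemble_acu2net(cfg, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    model.eval()
    return model, meta


def restore_model(ckpt: dict) -> ACU2Net:
    """Rebuild a model from an in-memory checkpoint dict."""
    cfg = NetworkConfig.from_dict(ckpt["config"])
    model = assemble_acu2net(cfg, seed=ckpt.get("seed", 0))
    model.load_state_dict(ckpt["state"])
    model.eval()
    return model


# ---------------------------------------------------------------------------
# full-image inference
# ---------------------------------------------------------------------------


def predict(model: ACU2Net, image: np.ndarray, tile: int = 256,
            overlap: int = 32, threshold: float = 0.5) -> np.ndarray:
    """Sliding-window segmentation of an arbitrarily sized image.

    Probabilities are averaged in overlap regions; images smaller than the
    tile are reflect-padded.  Returns a binary H x W mask.
    """
    if tile % 32:
        raise ValueError("tile must be divisible by 32")
    if not 0 <= overlap < tile:
        raise ValueError("overlap must satisfy 0 <= overlap < tile")
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    H, W = img.shape[:2]
    ph, pw = max(0, tile - H), max(0, tile - W)
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    Hp, Wp = img.shape[:2]
    stride = tile - overlap
    ys = sorted({min(y, Hp - tile) for y in range(0, Hp - tile + stride, stride)})
    xs = sorted({min(x, Wp - tile) for x in range(0, Wp - tile + stride, stride)})
    prob = np.zeros((Hp, Wp), dtype=np.float64)
    weight = np.zeros((Hp, Wp), dtype=np.float64)
    model.eval()
    x = img.astype(np.float32).transpose(2, 0, 1) / 255.0
    with nn.no_grad():
        for y0 in ys:
            for x0 in xs:
                patch = x[:, y0 : y0 + tile, x0 : x0 + tile][None]
                out = model(Tensor(patch))
                prob[y0 : y0 + tile, x0 : x0 + tile] += out["fused"].data[0, 0]
                weight[y0 : y0 + tile, x0 : x0 + tile] += 1.0
    prob /= np.maximum(weight, 1.0)
    return (prob[:H, :W] >= threshold).astype(np.uint8)
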