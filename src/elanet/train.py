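"""Training and evaluation loops.

Training follows the published protocol: binary cross-entropy on the
sigmoid head, SGD with momentum 0.9 and weight decay 1e-4, initial
learning rate 0.01 annealed to ``lr_min`` by a cosine schedule stepped
per iteration.  Runs are fully seeded: the parameter initialization, the
epoch shuffling and the augmentation draws all derive from the
configured seed, so two runs on one CPU thread produce identical logs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import AugmentConfig, ImageSample, augment, letterbox
from .metrics import ConfusionMatrix, acc, accumulate, bce_with_logits, miou
from .network import ELANet, NetworkConfig, build, save_checkpoint
from .nn import SGD, cosine_lr, no_grad
from .nn.tensor import Tensor

__all__ = ["TrainingConfig", "train", "evaluate", "predict", "overfit_single"]


@dataclass
class TrainingConfig:
    lr0: float = 0.01
    lr_min: float = 0.0
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 1000
    batch_size: int = 8
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    augment: AugmentConfig | None = None

    def __post_init__(self):
        if not self.lr0 > self.lr_min >= 0:
            raise ValueError(f"need lr0 > lr_min >= 0, got {self.lr0}, {self.lr_min}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")


def _to_batch(samples: list[ImageSample]):
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return Tensor(x), y


def train(cfg: TrainingConfig, net_cfg: NetworkConfig,
          samples: list[ImageSample], val_samples: list[ImageSample] | None = None,
          log=None):
    """Train a freshly built network; returns (net, history).

    ``history`` is one dict per epoch: epoch, lr, train loss, and - when a
    validation set is given - val mIoU / Acc.  The best-mIoU weights are
    restored into the returned network and written to ``checkpoint_dir``.
    """
    if not samples:
        raise ValueError("training requires a non-empty sample list")
    aug = cfg.augment or AugmentConfig(
        target_size=net_cfg.input_size, seed=cfg.seed
    )
    net = build(net_cfg)
    opt = SGD(net.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(len(samples) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    rng = np.random.default_rng([net_cfg.seed, cfg.seed, 1])
    history: list[dict] = []
    best = {"miou": -1.0, "state": None, "epoch": -1}
    step = 0
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(len(samples))
        losses = []
        for lo in range(0, len(samples), cfg.batch_size):
            batch = [
                augment(samples[i], aug, np.random.default_rng([cfg.seed, epoch, int(i)]))
                for i in order[lo : lo + cfg.batch_size]
            ]
            x, y = _to_batch(batch)
            lr = cosine_lr(step, total_steps, cfg.lr0, cfg.lr_min)
            opt.lr = lr
            loss = bce_with_logits(net.forward_logits(x), y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: {loss.data!r}; "
                    f"lr={lr:.4g}, batch ids={[s.id for s in batch]}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
        entry = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))}
        if val_samples:
            _, agg = evaluate(net, val_samples, input_size=net_cfg.input_size)
            entry["val_miou"] = agg["miou"]
            entry["val_acc"] = agg["acc"]
            if agg["miou"] > best["miou"]:
                best = {"miou": agg["miou"], "state": net.state_dict(), "epoch": epoch}
        if log:
            log(entry)
        history.append(entry)
    if best["state"] is not None:
        net.load_state_dict(best["state"])
    if cfg.checkpoint_dir:
        path = Path(cfg.checkpoint_dir)
        path.mkdir(parents=True, exist_ok=True)
        save_checkpoint(path / "best.npz", net,
                        extra={"best_epoch": best["epoch"], "best_miou": best["miou"]})
    return net, history


def predict(net: ELANet, samples: list[ImageSample],
            input_size: tuple[int, int] | None = None, threshold: float = 0.5):
    """Letterbox, forward, threshold; returns one binary mask per sample
    (at the network input resolution, alongside the letterboxed sample)."""
    size = input_size or net.cfg.input_size
    out = []
    net.eval()
    for s in samples:
        boxed = letterbox(s, size)
        x, _ = _to_batch([boxed])
        with no_grad():
            prob = net(x).data[0, 0]
        out.append((boxed, (prob >= threshold).astype(np.uint8)))
    return out


def evaluate(net: ELANet, samples: list[ImageSample],
             input_size: tuple[int, int] | None = None, threshold: float = 0.5,
             csv_path=None, per_image_average: bool = False):
    """Per-image IoU/accuracy rows plus the aggregate.

    The aggregate mIoU/Acc come from one global confusion matrix by
    default; ``per_image_average=True`` averages per-image scores instead.
    """
    rows = []
    total = ConfusionMatrix()
    for boxed, pred in predict(net, samples, input_size, threshold):
        cm = accumulate(ConfusionMatrix(), pred, boxed.mask)
        total = total + cm
        fg = cm.tp / u if (u := cm.tp + cm.fp + cm.fn) else float("nan")
        bg = cm.tn / u if (u := cm.tn + cm.fn + cm.fp) else float("nan")
        rows.append({
            "id": boxed.id, "iou_fg": 100 * fg, "iou_bg": 100 * bg,
            "miou": miou(cm), "acc": acc(cm),
        })
    if per_image_average:
        agg = {
            "miou": float(np.mean([r["miou"] for r in rows])),
            "acc": float(np.mean([r["acc"] for r in rows])),
        }
    else:
        agg = {"miou": miou(total), "acc": acc(total)}
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "iou_fg", "iou_bg", "miou", "acc"])
            writer.writeheader()
            writer.writerows(rows)
            writer.writerow({"id": "aggregate", "iou_fg": "", "iou_bg": "",
                             "miou": agg["miou"], "acc": agg["acc"]})
    return rows, agg


def overfit_single(net_cfg: NetworkConfig, sample: ImageSample, steps: int = 200,
                   lr0: float = 0.01, seed: int = 0):
    """Optimization sanity run: fit one image for ``steps`` SGD steps.

    Returns (net, loss history).  No augmentation; cosine-annealed lr.
    """
    net = build(net_cfg)
    opt = SGD(net.parameters(), lr0, momentum=0.9, weight_decay=0.0)
    boxed = letterbox(sample, net_cfg.input_size)
    x, y = _to_batch([boxed])
    losses = []
    net.train()
    for t in range(steps):
        opt.lr = cosine_lr(t, steps, lr0)
        loss = bce_with_logits(net.forward_logits(x), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return net, losses
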