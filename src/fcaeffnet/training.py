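"""Training loop: Adam, cross-entropy, linear warmup + exponential decay.

The published recipe trains for 200 epochs at batch size 32 with Adam at a
base learning rate of 1e-3, warmed up linearly over the first 20 epochs and
decayed by a factor of 0.99 per epoch thereafter.  Everything stochastic —
initialisation, batch order, augmentation, branch drops — is derived from
one seed, so a run is exactly repeatable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .architecture import ArchitectureSpec, FCAEfficientNet, build_model
from .autograd import Tensor
from .datapipe import AugmentationConfig, apply_online_augmentation, to_model_input


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults are the published recipe)."""

    optimizer: str = "adam"
    base_lr: float = 1e-3
    epochs: int = 200
    warmup_epochs: int = 20
    gamma: float = 0.99
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimizer is supported")
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be in [0, epochs)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.base_lr <= 0 or self.batch_size < 1:
            raise ValueError("base_lr and batch_size must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate of a given 0-based epoch.

    Linear warmup from base_lr / warmup_epochs to base_lr across the warmup
    epochs, then exponential decay: base_lr * gamma**(epoch - warmup).
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.base_lr * (epoch + 1) / cfg.warmup_epochs
    return cfg.base_lr * cfg.gamma ** (epoch - cfg.warmup_epochs)


class Adam:
    """Adaptive moment estimation with reference defaults, no weight decay."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainHistory:
    """Per-epoch learning curves."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "lr", "train_loss", "train_acc",
                        "val_loss", "val_acc"])
            for i in range(len(self)):
                w.writerow([i, self.lr[i], self.train_loss[i], self.train_acc[i],
                            self.val_loss[i], self.val_acc[i]])


def evaluate_loss_acc(model: FCAEfficientNet, images: np.ndarray,
                      labels: np.ndarray, batch_size: int = 32
                      ) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in inference mode."""
    model.eval()
    losses, correct = [], 0
    with ag.no_grad():
        for s in range(0, len(labels), batch_size):
            xb = Tensor(images[s:s + batch_size])
            yb = labels[s:s + batch_size]
            logits = model.forward(xb)
            losses.append(float(ag.softmax_cross_entropy(logits, yb).item()) * len(yb))
            correct += int((logits.numpy().argmax(axis=1) == yb).sum())
    n = len(labels)
    return sum(losses) / n, correct / n


def train(model: FCAEfficientNet,
          train_set: tuple[np.ndarray, np.ndarray],
          valid_set: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig,
          augment: AugmentationConfig | None = None,
          epochs: int | None = None,
          log=None) -> tuple[TrainHistory, dict]:
    """Run the schedule and return (history, best-validation state dict).

    ``train_set``/``valid_set`` are (images, labels); images may be HWC
    uint8 (standardised internally, and augmented online when ``augment``
    is given) or already-standardised NCHW float32 (used as-is).
    A non-finite loss aborts with a diagnostic.
    """
    xtr, ytr = train_set
    xva, yva = valid_set
    if len(ytr) == 0 or len(yva) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if int(max(ytr.max(), yva.max())) >= model.spec.num_classes:
        raise ValueError("a label exceeds the model's class count")
    epochs = cfg.epochs if epochs is None else epochs
    raw_hwc = xtr.ndim == 4 and xtr.shape[-1] == 3 and xtr.dtype == np.uint8
    xva_in = to_model_input(xva) if (xva.ndim == 4 and xva.shape[-1] == 3
                                     and xva.dtype == np.uint8) else xva
    yva = np.asarray(yva, dtype=np.int64)
    ytr = np.asarray(ytr, dtype=np.int64)

    seq = np.random.SeedSequence(cfg.seed)
    order_rng, aug_rng = (np.random.default_rng(c) for c in seq.spawn(2))
    model.seed_stochastic(cfg.seed + 1)
    opt = Adam(model.parameters())
    history = TrainHistory()
    best = {"val_acc": -1.0, "state": None, "epoch": -1}

    for epoch in range(epochs):
        lr = lr_at(epoch, cfg)
        model.train()
        order = order_rng.permutation(len(ytr))
        losses, correct = [], 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            if raw_hwc:
                batch = xtr[idx]
                if augment is not None:
                    batch = np.stack([apply_online_augmentation(im, augment, aug_rng)
                                      for im in batch])
                xb = Tensor(to_model_input(batch))
            else:
                xb = Tensor(xtr[idx])
            yb = ytr[idx]
            logits = model.forward(xb)
            loss = ag.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.item()}")
            opt.zero_grad()
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(loss.item() * len(yb))
            correct += int((logits.numpy().argmax(axis=1) == yb).sum())
        tr_loss = sum(losses) / len(ytr)
        tr_acc = correct / len(ytr)
        va_loss, va_acc = evaluate_loss_acc(model, xva_in, yva, cfg.batch_size)
        history.train_loss.append(tr_loss)
        history.train_acc.append(tr_acc)
        history.val_loss.append(va_loss)
        history.val_acc.append(va_acc)
        history.lr.append(lr)
        if va_acc > best["val_acc"]:
            best.update(val_acc=va_acc, state=model.state_dict(), epoch=epoch)
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.6f}  "
                f"train loss {tr_loss:.4f} acc {tr_acc:.4f}  "
                f"valid loss {va_loss:.4f} acc {va_acc:.4f}")
    return history, best


# -- checkpoints ---------------------------------------------------------------

def save_checkpoint(path, model: FCAEfficientNet,
                    state: dict[str, np.ndarray] | None = None,
                    extra: dict | None = None) -> None:
    """Write weights + architecture spec as a compressed npz."""
    payload = dict(state if state is not None else model.state_dict())
    meta = {"spec": model.spec.to_dict(), "extra": extra or {}}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(Path(path), **payload)


def load_checkpoint(path) -> tuple[FCAEfficientNet, dict]:
    """Rebuild the model from a checkpoint; returns (model, extra metadata)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(ArchitectureSpec.from_dict(meta["spec"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})
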