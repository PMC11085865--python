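"""Training: Adam with two parameter groups and a plain epoch loop.

The optimizer follows the published setup for this architecture family:
Adam with learning rate 1e-5 for the backbone and 1e-4 for the classifier
head, batch size 30, up to 2000 epochs.  Those are the defaults here;
desk-scale experiments (see :mod:`tetcad.harness`) override the epoch
count and learning rates explicitly.  Remaining Adam constants are the
standard published defaults (beta1 0.9, beta2 0.999, eps 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn.layers import BatchNorm2d, Param, softmax
from .nn.network import CLASS_NAMES, MultiStateNet

__all__ = ["TrainConfig", "Adam", "train", "stratified_split",
           "calibrate_batchnorm"]


@dataclass(frozen=True)
class TrainConfig:
    lr_backbone: float = 1e-5
    lr_classifier: float = 1e-4
    batch_size: int = 30
    max_epochs: int = 2000
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    lr_schedule: str = "constant"  # "constant" | "cosine"

    def __post_init__(self) -> None:
        if self.lr_backbone < 0 or self.lr_classifier < 0:
            raise ValueError("learning rates must be non-negative")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    def desk_scale(self, epochs: int = 15,
                   lr_backbone: float = 6e-3,
                   lr_classifier: float = 6e-3,
                   batch_size: int = 10) -> "TrainConfig":
        """Short-schedule variant for desk-scale runs: a few-epoch budget
        needs proportionally larger and more numerous steps than the
        published 2000-epoch schedule, plus cosine decay to settle the
        final epochs."""
        return replace(self, max_epochs=epochs, lr_backbone=lr_backbone,
                       lr_classifier=lr_classifier, batch_size=batch_size,
                       lr_schedule="cosine")


@dataclass
class Adam:
    """Adam over one parameter group."""

    params: list[Param]
    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            if self.lr:
                p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def calibrate_batchnorm(model: MultiStateNet, x: np.ndarray,
                        batch_size: int = 30) -> None:
    """Re-estimate batch-norm running statistics over *x*.

    After a short training schedule the exponentially averaged statistics
    still lag the trained weights; replacing them with the plain average
    of the batch statistics over one pass makes inference consistent with
    the final weights.
    """
    bns = [layer for layer in model.layers if isinstance(layer, BatchNorm2d)]
    saved = [(bn.momentum,) for bn in bns]
    n = (len(x) // batch_size) * batch_size or len(x)
    for i, start in enumerate(range(0, n, batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)  # running average of batch stats
        model.forward_logits(x[start:start + batch_size], training=True)
    for bn, (momentum,) in zip(bns, saved):
        bn.momentum = momentum
    for layer in model.layers:  # drop training caches
        for attr in ("_x", "_xr", "_out", "_xp", "_mean", "_inv_std"):
            if hasattr(layer, attr):
                setattr(layer, attr, None)


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2), dtype=np.float32)
    out[np.arange(len(y)), y.astype(int)] = 1.0
    return out


def train(
    model: MultiStateNet,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> list[float]:
    """Train in place; returns the per-epoch mean loss history.

    *y* holds class indices (0 non-CAD, 1 CAD) or the corresponding label
    strings.  Deterministic given the config seed (single-threaded).
    """
    x = np.asarray(x, dtype=np.float32)
    if len(x) == 0:
        raise ValueError("training set is empty")
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = np.asarray([CLASS_NAMES.index(lab) for lab in y])
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError(f"labels must be binary (0/1 or {CLASS_NAMES}), got {classes}")

    groups = model.param_groups()
    optimizers = [
        Adam(groups["backbone"], lr=config.lr_backbone,
             beta1=config.beta1, beta2=config.beta2, eps=config.eps),
        Adam(groups["classifier"], lr=config.lr_classifier,
             beta1=config.beta1, beta2=config.beta2, eps=config.eps),
    ]
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    n = len(x)
    base_lrs = (config.lr_backbone, config.lr_classifier)
    for epoch in range(config.max_epochs):
        if config.lr_schedule == "cosine":
            factor = 0.5 * (1.0 + np.cos(np.pi * epoch / config.max_epochs))
            for opt, base in zip(optimizers, base_lrs):
                opt.lr = base * factor
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], _onehot(y[idx])
            logits = model.forward_logits(xb, training=True)
            probs = softmax(logits)
            loss = float(-(yb * np.log(np.clip(probs, 1e-12, None))).sum() / len(idx))
            for group in groups.values():
                for p in group:
                    p.zero_grad()
            model.backward((probs - yb) / len(idx))
            for opt in optimizers:
                opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    # statistics are estimated in batches of 30 (the published batch size)
    # independently of the training batch size; larger batches give more
    # stable per-batch variance estimates
    calibrate_batchnorm(model, x, batch_size=30)
    return history


def stratified_split(
    labels,
    test_fraction: float = 63 / 416,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified train/test index split.

    The default test fraction mirrors the 353/63 split of the cohort this
    pipeline was designed around.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for value in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == value))
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))
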