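"""Reproducible training loop for the segmentation network.

The loss is an equally weighted sum of soft Dice and binary cross-entropy
on logits; optimization is Adam.  All randomness (weight init, the
stratified train/validation split, per-epoch shuffling, flip/rotation
augmentation, DropBlock) derives from a single seed, so a rerun with the
same configuration is bit-identical.  The checkpoint with the best
validation Dice is the one returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, TrainingDivergenceError
from .imaging_io import make_contour_label
from .nn.autograd import Parameter, Tensor
from .nn.network import NetworkConfig, SegmentationModel, build_network
from .synthetic import Dataset

__all__ = ["TrainConfig", "TrainingHistory", "dice_loss", "train_segmenter", "Adam"]

_EPS = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "dice+bce"
    contour_loss_weight: float = 0.0
    seed: int = 0
    augment_flips: bool = True
    augment_rotations: bool = True
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ParameterError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.loss not in ("dice", "bce", "dice+bce"):
            raise ParameterError("loss must be one of dice, bce, dice+bce")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -1.0

    def __len__(self) -> int:
        return len(self.train_loss)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def dice_loss(prob_map, truth_mask) -> float | Tensor:
    """Soft Dice loss 1 - 2*sum(p*y) / (sum(p) + sum(y) + eps).

    Accepts arrays (returns a float) or autograd tensors (returns a node).
    Zero for an exact binary match; bounded above by 1 + O(eps).
    """
    p = prob_map if isinstance(prob_map, Tensor) else np.asarray(prob_map, np.float64)
    y = np.asarray(truth_mask.data if isinstance(truth_mask, Tensor) else truth_mask,
                   np.float32)
    if p.shape != y.shape:
        raise ParameterError(f"shape mismatch: {p.shape} vs {y.shape}")
    if isinstance(p, Tensor):
        inter = (p * Tensor(y)).sum()
        return 1.0 - (2.0 * inter) / (p.sum() + float(y.sum()) + _EPS)
    return float(1.0 - 2.0 * (p * y).sum() / (p.sum() + y.sum() + _EPS))


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    z = logits.data
    y = np.asarray(target, np.float32)
    val = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        val = val * weight
    out = Tensor(val.mean(), (logits,))
    n = z.size
    sig = 1.0 / (1.0 + np.exp(-z))
    grad_base = (sig - y) if weight is None else (sig - y) * weight

    def backward(g):
        logits._accum(g * grad_base / n)

    out._backward = backward
    return out


def _dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = float((pred & truth).sum())
    denom = float(pred.sum() + truth.sum())
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _prepare_inputs(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-b-value images into channels, z-scored per image."""
    xs, ys = [], []
    for s in dataset:
        chans = []
        for img in s.images:
            img = img.astype(np.float32)
            sd = img.std()
            chans.append((img - img.mean()) / (sd if sd > 0 else 1.0))
        xs.append(np.stack(chans))
        ys.append(s.mask.astype(np.float32))
    return np.stack(xs), np.stack(ys)


def stratified_split(labels: list[str], validation_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; at least one validation case per class."""
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * validation_fraction)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _augment(x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if cfg.augment_flips:
        if rng.random() < 0.5:
            x, y = x[..., ::-1], y[..., ::-1]
        if rng.random() < 0.5:
            x, y = x[..., ::-1, :], y[..., ::-1, :]
    if cfg.augment_rotations:
        k = int(rng.integers(4))
        if k:
            x = np.rot90(x, k, axes=(-2, -1))
            y = np.rot90(y, k, axes=(-2, -1))
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def _batch_loss(model: SegmentationModel, xb: np.ndarray, yb: np.ndarray,
                cfg: TrainConfig, contours: np.ndarray | None) -> Tensor:
    logits = model.forward_logits(Tensor(xb))
    target = yb[:, None]
    terms = []
    if "dice" in cfg.loss:
        terms.append(dice_loss(logits.sigmoid(), target))
    if "bce" in cfg.loss:
        terms.append(bce_with_logits(logits, target))
    if cfg.contour_loss_weight > 0 and contours is not None:
        # emphasize boundary pixels: weighted BCE along the contour band
        w = 1.0 + cfg.contour_loss_weight * contours[:, None]
        terms.append(bce_with_logits(logits, target, weight=w))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def train_segmenter(dataset: Dataset, net_config: NetworkConfig,
                    train_config: TrainConfig
                    ) -> tuple[SegmentationModel, TrainingHistory]:
    """Train the attention U-Net; returns the best-validation-Dice model."""
    if len(dataset) < 2:
        raise ParameterError("need at least 2 samples to train")
    cfg = train_config
    ss = np.random.SeedSequence([int(cfg.seed), 0x7261])
    seed_init, seed_split, seed_order, seed_aug = ss.spawn(4)

    model = build_network(net_config, seed=int(seed_init.generate_state(1)[0] % 2**31))
    x_all, y_all = _prepare_inputs(dataset)
    train_idx, val_idx = stratified_split(
        dataset.labels(), cfg.validation_fraction, np.random.default_rng(seed_split)
    )
    if len(val_idx) == 0 or len(train_idx) == 0:
        raise ParameterError("split leaves an empty train or validation set")

    contours = None
    if cfg.contour_loss_weight > 0:
        contours = np.stack(
            [make_contour_label(s.mask).astype(np.float32) for s in dataset]
        )

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(seed_order)
    aug_rng = np.random.default_rng(seed_aug)
    history = TrainingHistory()
    best_state = model.state_dict()

    for epoch in range(cfg.epochs):
        model.train()
        perm = order_rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = np.empty((len(idx),) + x_all.shape[1:], np.float32)
            yb = np.empty((len(idx),) + y_all.shape[1:], np.float32)
            for k, i in enumerate(idx):
                xb[k], yb[k] = _augment(x_all[i], y_all[i], cfg, aug_rng)
            loss = _batch_loss(model, xb, yb, cfg,
                               contours[idx] if contours is not None else None)
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        model.eval()
        val_losses, val_dscs = [], []
        for start in range(0, len(val_idx), cfg.batch_size):
            idx = val_idx[start : start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            loss = _batch_loss(model, xb, yb, cfg, None)
            val_losses.append(float(loss.data) * len(idx))
            probs = model(Tensor(xb)).data[:, 0]
            for p, y in zip(probs, yb):
                val_dscs.append(
                    _dsc(p >= net_config.out_threshold, y.astype(bool))
                )
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(float(np.sum(val_losses) / len(val_idx)))
        history.val_dsc.append(float(np.mean(val_dscs)))
        if history.val_dsc[-1] > history.best_val_dsc:
            history.best_val_dsc = history.val_dsc[-1]
            history.best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.eval()
    return model, history
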