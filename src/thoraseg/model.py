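"""Lung segmenter: residual encoder + U-Net decoder, trained with Dice loss.

The network follows the ResNet34 pattern — a strided 7×7 stem, four residual
stages with (3, 4, 6, 3) units, batch normalization and PReLU activations —
as the encoder of a U-Net whose decoder upsamples with 2×2 transpose
convolutions, concatenates the encoder skips, and ends in a 1×1 convolution
with a sigmoid producing a per-pixel lung probability map.  Training uses the
soft Dice loss ``1 − (2Σpt + s)/(Σp + Σt + s)`` with Adam, a seeded 30%
validation split, and keeps the weights of the best-validation epoch.

:class:`LungSegmenter` wraps this in a scikit-learn estimator (``fit`` /
``predict`` / ``predict_proba``, ``get_params``/``set_params``); the
module-level :func:`build_segmenter`, :func:`train` and :func:`predict`
functions are thin wrappers for pipeline-style use.  ``base_filters``
defaults to 16 — a CPU-scale width; 64 gives the full-width original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .errors import ConfigurationError, DimensionError, GridError

__all__ = [
    "SegmenterConfig",
    "TrainConfig",
    "LungSegmenter",
    "build_segmenter",
    "dice_loss",
    "train",
    "predict",
]


@dataclass
class SegmenterConfig:
    """Architecture parameters of the segmenter."""

    input_size: tuple[int, int] = (128, 128)
    encoder_blocks: tuple[int, ...] = (3, 4, 6, 3)
    base_filters: int = 16
    prelu: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_blocks) != 4:
            raise ConfigurationError("encoder must have exactly 4 stages")
        if any(s % 32 for s in self.input_size):
            raise ConfigurationError(
                f"input sides must be divisible by the 32x downsampling factor, got {self.input_size}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError("threshold must be in [0, 1]")


@dataclass
class TrainConfig:
    """Optimization parameters (Adam, lr 1e-4, batch 8, 30% validation)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    val_fraction: float = 0.30
    epochs: int = 20
    seed: int = 0
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in (0, 1)")


def build_segmenter(cfg: SegmenterConfig) -> _nn.ResUNet:
    """Instantiate the network with seeded random weights."""
    return _nn.ResUNet(
        base_filters=cfg.base_filters,
        blocks=tuple(cfg.encoder_blocks),
        prelu=cfg.prelu,
        seed=cfg.seed,
    )


def dice_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss of a probability map against a binary mask."""
    return _nn.dice_loss(pred, truth, smooth=smooth)


def _as_batch(x: np.ndarray, input_size) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != tuple(input_size):
        raise DimensionError(f"expected slices of shape {tuple(input_size)}, got {x.shape}")
    return x[:, None]


def train(
    net: _nn.ResUNet,
    slices: np.ndarray,
    masks: np.ndarray,
    cfg: TrainConfig,
    input_size=(128, 128),
) -> tuple[_nn.ResUNet, dict]:
    """Train in place; returns the net (best-validation weights) and history.

    ``slices``: (n, H, W) normalized images; ``masks``: (n, H, W) binary.
    """
    x = _as_batch(slices, input_size)
    y = np.asarray(masks, dtype=np.float32)
    if y.ndim == 2:
        y = y[None]
    y = y[:, None]
    if y.shape != x.shape:
        raise GridError(f"mask batch shape {y.shape} does not match image batch {x.shape}")
    n = x.shape[0]
    if n < 2:
        raise ConfigurationError("need at least 2 slices to split off validation data")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ConfigurationError("validation split leaves no training data")
    import warnings

    if len(tr_idx) < cfg.batch_size:
        warnings.warn(
            f"fewer training slices ({len(tr_idx)}) than batch size ({cfg.batch_size}); "
            "using one smaller batch per epoch",
            stacklevel=2,
        )
    opt = _nn.Adam(net.params(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_dsc": []}
    best = (np.inf, None)
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), cfg.batch_size):
            sel = tr_idx[perm[start : start + cfg.batch_size]]
            pred = net.forward(x[sel], train=True)
            loss, grad = _nn.dice_loss_and_grad(pred, y[sel], smooth=cfg.smooth)
            net.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_pred = _predict_proba(net, x[val_idx], batch_size=cfg.batch_size)
        val_loss = _nn.dice_loss(val_pred, y[val_idx], smooth=cfg.smooth)
        val_bin = val_pred >= 0.5
        inter = (val_bin * y[val_idx]).sum(axis=(1, 2, 3))
        sizes = val_bin.sum(axis=(1, 2, 3)) + y[val_idx].sum(axis=(1, 2, 3))
        with np.errstate(invalid="ignore"):
            val_dsc = np.where(sizes > 0, 2 * inter / sizes, 1.0)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        history["val_dsc"].append(float(val_dsc.mean()))
        if val_loss < best[0]:
            best = (val_loss, net.get_state())
    if best[1] is not None:
        net.set_state(best[1])
    history["best_epoch"] = int(np.argmin(history["val_loss"]))
    history["n_val"] = int(n_val)
    return net, history


def _predict_proba(net: _nn.ResUNet, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
    out = [net.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def predict(
    net: _nn.ResUNet,
    slices: np.ndarray,
    threshold: float = 0.5,
    input_size=(128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """Probability maps and thresholded binary masks for (n, H, W) slices."""
    x = _as_batch(slices, input_size)
    prob = _predict_proba(net, x)[:, 0]
    return prob, (prob >= threshold).astype(np.uint8)


class LungSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the residual U-Net segmenter.

    Parameters mirror :class:`SegmenterConfig` and :class:`TrainConfig`.
    ``fit(X, y)`` takes ``X`` of shape (n_slices, H, W) with values in
    [0, 1] (see :mod:`thoraseg.preprocess`) and binary masks ``y`` of the
    same shape.  Fitted attributes: ``net_``, ``history_``, ``best_epoch_``.
    """

    def __init__(
        self,
        input_size=(128, 128),
        encoder_blocks=(3, 4, 6, 3),
        base_filters=16,
        prelu=True,
        threshold=0.5,
        learning_rate=1e-4,
        batch_size=8,
        val_fraction=0.30,
        epochs=20,
        smooth=1.0,
        seed=0,
    ):
        self.input_size = input_size
        self.encoder_blocks = encoder_blocks
        self.base_filters = base_filters
        self.prelu = prelu
        self.threshold = threshold
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.epochs = epochs
        self.smooth = smooth
        self.seed = seed

    def _configs(self) -> tuple[SegmenterConfig, TrainConfig]:
        seg = SegmenterConfig(
            input_size=tuple(self.input_size),
            encoder_blocks=tuple(self.encoder_blocks),
            base_filters=self.base_filters,
            prelu=self.prelu,
            threshold=self.threshold,
            seed=self.seed,
        )
        tr = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            val_fraction=self.val_fraction,
            epochs=self.epochs,
            seed=self.seed,
            smooth=self.smooth,
        )
        return seg, tr

    def fit(self, X, y):
        seg_cfg, tr_cfg = self._configs()
        net = build_segmenter(seg_cfg)
        net, history = train(net, X, y, tr_cfg, input_size=seg_cfg.input_size)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = history["best_epoch"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        prob, _ = predict(self.net_, X, threshold=self.threshold, input_size=tuple(self.input_size))
        return prob

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        _, binary = predict(self.net_, X, threshold=self.threshold, input_size=tuple(self.input_size))
        return binary

    def score(self, X, y) -> float:
        """Mean Dice coefficient over slices (1.0 is a perfect match)."""
        from .metrics import dsc

        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dsc(p, t) for p, t in zip(pred, y)]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            from sklearn.exceptions import NotFittedError

            raise NotFittedError("this LungSegmenter instance is not fitted yet")
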