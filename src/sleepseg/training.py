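"""Masked losses, the optimization loop, and multi-resolution ensembling.

Records enter training already normalized, resolution-reduced (averaging
every 2 or 8 successive time points for the "half"/"eighth" models, labels
block-reduced alongside with arousal-preserving precedence), and
zero-center-padded to the network input length with padding labeled -1.
Non-scored samples (label -1, which includes all padding) are masked out of
every loss: training on them would teach falsehoods, since they cover wake
and apnea regions whose signal does not mean "not arousal".

Optimization is Adam (lr 1e-4, per-update decay 1e-5 at full scale) with
batch size 1 — one whole record per update, with fresh augmentation draws
each epoch — and the returned weights are those of the epoch with minimal
validation loss.  Final predictions may ensemble the three resolution
models: each coarse track is upsampled to the native rate by value
repetition and the tracks are averaged pointwise.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, apply_policy_arrays
from .errors import (
    AlignmentError,
    ParameterError,
    ShapeError,
    UndefinedMetricError,
    ValidationError,
)
from .nn import Adam, UNet1d, UNetConfig, build_unet
from .records import LabelTrack

EPS_CLIP = 1e-7

RESOLUTION_FACTORS = {"full": 1, "half": 2, "eighth": 8}


@dataclass
class PredictionTrack:
    """Per-sample arousal probabilities at a record's native rate."""

    probabilities: np.ndarray
    native_rate: float = 200.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 1:
            raise ShapeError("prediction track must be 1D")
        if self.probabilities.size and (
            self.probabilities.min() < 0.0 or self.probabilities.max() > 1.0
        ):
            raise ValidationError("probabilities outside [0, 1]")

    def __len__(self) -> int:
        return self.probabilities.shape[0]


@dataclass
class TrainConfig:
    """Optimization hyperparameters for one model."""

    resolution: str = "eighth"
    loss: str = "cross_entropy"  # or "dice", "combined"
    learning_rate: float = 1e-4
    lr_decay: float = 1e-5
    epochs: int = 10
    batch_size: int = 1
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.resolution not in RESOLUTION_FACTORS:
            raise ParameterError(f"unknown resolution {self.resolution!r}")
        if self.loss not in ("cross_entropy", "dice", "combined"):
            raise ParameterError(f"unknown loss {self.loss!r}")

    @property
    def factor(self) -> int:
        return RESOLUTION_FACTORS[self.resolution]


@dataclass
class TrainHistory:
    """Per-epoch mean training and validation losses."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _coerce(labels, predictions):
    y = np.asarray(getattr(labels, "values", labels))
    p = np.asarray(getattr(predictions, "probabilities", predictions),
                   dtype=np.float64)
    if y.shape != p.shape:
        raise AlignmentError("labels and predictions differ in length")
    return y, p


def per_sample_cross_entropy(labels, predictions) -> np.ndarray:
    """Pointwise -y log p - (1-y) log(1-p) with p clipped to
    [1e-7, 1 - 1e-7]; exactly 0 at non-scored samples."""
    y, p = _coerce(labels, predictions)
    scored = y >= 0
    pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    yb = (y == 1).astype(np.float64)
    terms = -(yb * np.log(pc) + (1.0 - yb) * np.log1p(-pc))
    terms[~scored] = 0.0
    return terms


def cross_entropy_loss(labels, predictions) -> float:
    """Masked cross-entropy summed over scored samples."""
    y, _ = _coerce(labels, predictions)
    scored = y >= 0
    if not np.any(scored):
        raise UndefinedMetricError("loss undefined: no scored samples")
    return float(per_sample_cross_entropy(labels, predictions)[scored].sum())


def dice_score(labels, predictions, convention: str = "as_printed") -> float:
    """Sorensen-dice overlap between soft predictions and the arousal mask.

    ``as_printed`` evaluates sum(y*p) / (sum(y) + sum(p)), whose maximum for
    perfect binary agreement is 0.5; ``standard`` doubles the numerator so
    perfect agreement scores 1.  Non-scored samples are masked.  A zero
    denominator is defined as 0 with a warning.
    """
    if convention not in ("as_printed", "standard"):
        raise ParameterError(f"unknown convention {convention!r}")
    y, p = _coerce(labels, predictions)
    scored = y >= 0
    yb = (y[scored] == 1).astype(np.float64)
    ps = p[scored]
    num = float(np.sum(yb * ps))
    den = float(yb.sum() + ps.sum())
    if den == 0.0:
        warnings.warn("empty masks: dice defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return (2.0 * num if convention == "standard" else num) / den


def _loss_and_dlogits(loss: str, y: np.ndarray, p: np.ndarray):
    """Mean loss over scored samples and its gradient w.r.t. the logits."""
    scored = y >= 0
    n = int(scored.sum())
    if n == 0:
        raise UndefinedMetricError("loss undefined: no scored samples")
    yb = (y == 1).astype(np.float64)
    mask = scored.astype(np.float64)
    pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    ce = float(np.sum(mask * -(yb * np.log(pc) + (1 - yb) * np.log1p(-pc))) / n)
    dce = (p - yb) * mask / n
    if loss == "cross_entropy":
        return ce, dce
    # soft dice (standard convention) on the scored samples
    num = float(np.sum(mask * yb * p))
    den = float(np.sum(mask * (yb + p)))
    if den == 0.0:
        dice_loss, ddice = 0.0, np.zeros_like(p)
    else:
        dice_loss = 1.0 - 2.0 * num / den
        dp = -2.0 * (yb * den - num) / den ** 2 * mask
        ddice = dp * p * (1.0 - p)
    if loss == "dice":
        return dice_loss, ddice
    return 0.5 * (ce + dice_loss), 0.5 * (dce + ddice)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _mean_val_loss(net: UNet1d, pairs, loss: str) -> float:
    losses = []
    for x, y in pairs:
        p = net.forward(x, training=False)
        value, _ = _loss_and_dlogits(loss, y, p)
        losses.append(value)
    return float(np.mean(losses))


def train_model(
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    model_config: UNetConfig,
    train_config: TrainConfig,
) -> tuple[UNet1d, TrainHistory]:
    """Fit the network on prepared ``(signals, labels)`` pairs.

    Each pair must already be at the model resolution and padded to
    ``model_config.input_length``.  Per epoch the training records are
    visited in a fresh random order with fresh augmentation draws; the mean
    training loss and the (augmentation-free, inference-mode) validation
    loss are recorded, and the weights from the epoch with minimal
    validation loss are restored before returning.  Everything is driven by
    ``train_config.seed``, so a fixed seed reproduces the history exactly.
    """
    if len(train_pairs) == 0:
        raise ParameterError("empty training set")
    rng = np.random.default_rng(train_config.seed)
    net, _ = build_unet(model_config,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
    optimizer = Adam(net.parameters(), net.gradients(),
                     learning_rate=train_config.learning_rate,
                     decay=train_config.lr_decay)
    history = TrainHistory()
    best_state: Optional[list[np.ndarray]] = None
    best_val = np.inf
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for idx in order:
            x, y = train_pairs[idx]
            x_aug, y_aug = apply_policy_arrays(x, y, train_config.augment, rng)
            p = net.forward(x_aug, training=True)
            value, dlogits = _loss_and_dlogits(train_config.loss, y_aug, p)
            net.backward(dlogits.astype(net.dtype))
            optimizer.step()
            epoch_losses.append(value)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if len(val_pairs):
            val = _mean_val_loss(net, val_pairs, train_config.loss)
        else:
            val = history.train_loss[-1]
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_state = [a.copy() for a in net.get_state()]
    if best_state is not None:
        net.set_state(best_state)
        history.best_epoch = best_epoch
    return net, history


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------

def ensemble_predictions(
    tracks: Sequence,
    target_length: int,
    offset: int = 0,
    native_length: Optional[int] = None,
    record_id: str = "",
    native_rate: float = 200.0,
) -> PredictionTrack:
    """Average prediction tracks from models at different resolutions.

    Each coarse track is upsampled to ``target_length`` by value repetition
    (its length must divide ``target_length`` exactly), the pointwise
    arithmetic mean is taken with equal weights, and finally the track is
    cropped to the original record extent ``[offset, offset + native_length)``
    (the stored center-padding offset; defaults keep the full length).
    """
    if not len(tracks):
        raise ParameterError("need at least one track")
    upsampled = []
    for track in tracks:
        p = np.asarray(getattr(track, "probabilities", track), dtype=np.float64)
        if target_length % p.shape[0]:
            raise ShapeError(
                f"track length {p.shape[0]} does not divide target "
                f"{target_length}"
            )
        upsampled.append(np.repeat(p, target_length // p.shape[0]))
    mean = np.mean(upsampled, axis=0)
    if native_length is None:
        native_length = target_length - offset
    return PredictionTrack(mean[offset : offset + native_length],
                           native_rate=native_rate, record_id=record_id)
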