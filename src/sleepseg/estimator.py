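"""High-level estimator: normalization + resolution reduction + padding +
U-Net training + native-rate prediction, behind the scikit-learn API.

``ArousalSegmenter.fit`` takes lists of :class:`PolysomnogramRecord` and
:class:`LabelTrack`; ``predict_proba`` returns one :class:`PredictionTrack`
per record at the record's native sampling rate, ready for the gross
metrics.  The estimator composes with sklearn model-selection utilities via
``get_params``/``set_params``/``clone``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentPolicy
from .errors import ParameterError, SizeError
from .metrics import EvalReport, evaluate_dataset, gross_auprc
from .nn import UNetConfig, forward_predict
from .preprocess import (
    QuantileReference,
    build_quantile_reference,
    gaussian_normalize_record,
    quantile_normalize,
)
from .records import (
    LabelTrack,
    PolysomnogramRecord,
    center_pad_arrays,
    downsample_average,
    downsample_labels,
)
from .training import (
    PredictionTrack,
    TrainConfig,
    TrainHistory,
    ensemble_predictions,
    train_model,
)


class ArousalSegmenter(BaseEstimator):
    """Per-sample sleep-arousal segmentation with a 1D U-Net.

    Parameters
    ----------
    resolution : {'full', 'half', 'eighth'}
        Input resolution; 'half'/'eighth' average every 2/8 successive time
        points before the network (labels are block-reduced alongside, with
        arousal-preserving precedence).
    input_length : int
        Network input length at model resolution; records are zero-center-
        padded (labels -1) to this length after reduction.
    pooling_sizes, channel_schedule, kernel_size, pooling_type
        Architecture knobs; see :class:`~sleepseg.nn.UNetConfig`.  Defaults
        are the desk-scale three-level network (~43k parameters).
    normalization : {'quantile', 'gaussian'}
        Per-channel normalization; quantile (default) maps each record onto
        a reference averaged over the training records.
    loss : {'cross_entropy', 'dice', 'combined'}
    learning_rate, lr_decay, epochs
        Adam settings.  The desk-scale default lr is 1e-3; the full-scale
        pipeline uses 1e-4 with decay 1e-5.
    swap_channels, magnitude_range, stretch_range
        Augmentation policy (fresh draws per record per epoch).
    val_fraction : float
        Fraction of the training records held out internally to select the
        best epoch by validation loss.
    random_state : int
        Drives initialization, the internal split, shuffling and
        augmentation; a fixed value makes fit deterministic.

    Attributes
    ----------
    model_ : UNet1d
        Trained network (weights of the best validation epoch).
    history_ : TrainHistory
    reference_ : QuantileReference or None
    summary_ : NetworkSummary
    """

    def __init__(
        self,
        resolution: str = "eighth",
        input_length: int = 2048,
        pooling_sizes: tuple[int, ...] = (4, 4, 4),
        channel_schedule: tuple[int, ...] = (12, 16, 24),
        kernel_size: int = 7,
        pooling_type: str = "max",
        normalization: str = "quantile",
        grid_size: int = 10_001,
        loss: str = "cross_entropy",
        learning_rate: float = 1e-3,
        lr_decay: float = 1e-5,
        epochs: int = 10,
        swap_channels: bool = True,
        magnitude_range: Optional[tuple[float, float]] = (0.90, 1.15),
        stretch_range: Optional[tuple[float, float]] = None,
        val_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.resolution = resolution
        self.input_length = input_length
        self.pooling_sizes = pooling_sizes
        self.channel_schedule = channel_schedule
        self.kernel_size = kernel_size
        self.pooling_type = pooling_type
        self.normalization = normalization
        self.grid_size = grid_size
        self.loss = loss
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.swap_channels = swap_channels
        self.magnitude_range = magnitude_range
        self.stretch_range = stretch_range
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- pipeline pieces -------------------------------------------------
    def _factor(self) -> int:
        from .training import RESOLUTION_FACTORS

        return RESOLUTION_FACTORS[self.resolution]

    def _normalize(self, record: PolysomnogramRecord) -> PolysomnogramRecord:
        if self.normalization == "gaussian":
            return gaussian_normalize_record(record)
        if self.normalization == "quantile":
            return quantile_normalize(record, self.reference_)
        raise ParameterError(f"unknown normalization {self.normalization!r}")

    def _prepare(self, record: PolysomnogramRecord,
                 labels: Optional[LabelTrack]):
        """normalize -> reduce -> pad; returns (x, y, offset, native_n)."""
        factor = self._factor()
        normalized = self._normalize(record)
        x = downsample_average(normalized.samples, factor)
        if x.shape[1] > self.input_length:
            raise SizeError(
                f"record {record.record_id} reduces to {x.shape[1]} samples "
                f"> input_length {self.input_length}"
            )
        y = None
        if labels is not None:
            y = downsample_labels(labels.values, factor)
        x, y, offset = center_pad_arrays(x, y, self.input_length)
        return x.astype(np.float32), y, offset, record.n_timepoints

    # -- sklearn API ------------------------------------------------------
    def fit(
        self,
        X: Sequence[PolysomnogramRecord],
        y: Sequence[LabelTrack],
        X_val: Optional[Sequence[PolysomnogramRecord]] = None,
        y_val: Optional[Sequence[LabelTrack]] = None,
    ) -> "ArousalSegmenter":
        """Fit on training records; ``X_val``/``y_val`` override the internal
        ``val_fraction`` split when given."""
        if len(X) == 0:
            raise ParameterError("empty training set")
        if len(X) != len(y):
            raise ParameterError("records and labels differ in count")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            order = rng.permutation(len(X))
            n_val = int(round(self.val_fraction * len(X)))
            n_val = min(n_val, len(X) - 1)
            val_idx = set(order[:n_val].tolist())
            train_records = [X[i] for i in range(len(X)) if i not in val_idx]
            train_labels = [y[i] for i in range(len(X)) if i not in val_idx]
            val_records = [X[i] for i in sorted(val_idx)]
            val_labels = [y[i] for i in sorted(val_idx)]
        else:
            train_records, train_labels = list(X), list(y)
            val_records = list(X_val)
            val_labels = list(y_val)

        if self.normalization == "quantile":
            self.reference_ = build_quantile_reference(
                train_records, grid_size=self.grid_size
            )
        else:
            self.reference_ = None

        train_pairs = [
            self._prepare(r, lab)[:2]
            for r, lab in zip(train_records, train_labels)
        ]
        val_pairs = [
            self._prepare(r, lab)[:2]
            for r, lab in zip(val_records, val_labels)
        ]

        model_config = UNetConfig(
            input_length=self.input_length,
            in_channels=train_records[0].n_channels,
            pooling_sizes=tuple(self.pooling_sizes),
            channel_schedule=tuple(self.channel_schedule),
            kernel_size=self.kernel_size,
            pooling_type=self.pooling_type,
        )
        train_config = TrainConfig(
            resolution=self.resolution,
            loss=self.loss,
            learning_rate=self.learning_rate,
            lr_decay=self.lr_decay,
            epochs=self.epochs,
            augment=AugmentPolicy(
                swap_channels=self.swap_channels,
                magnitude_range=self.magnitude_range,
                stretch_range=self.stretch_range,
            ),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        self.model_, self.history_ = train_model(
            train_pairs, val_pairs, model_config, train_config
        )
        self.summary_ = self.model_.summary()
        self.model_config_ = model_config
        self.train_config_ = train_config
        return self

    def predict_proba(
        self, X: Sequence[PolysomnogramRecord]
    ) -> list[PredictionTrack]:
        """One native-rate probability track per record (deterministic:
        batch-norm statistics frozen)."""
        if not hasattr(self, "model_"):
            raise ParameterError("ArousalSegmenter is not fitted")
        factor = self._factor()
        tracks = []
        for record in X:
            x, _, offset, native_n = self._prepare(record, None)
            probs = forward_predict(self.model_, x)
            tracks.append(
                ensemble_predictions(
                    [probs],
                    target_length=self.input_length * factor,
                    offset=offset * factor,
                    native_length=native_n,
                    record_id=record.record_id,
                    native_rate=record.sampling_rate,
                )
            )
        return tracks

    def predict(
        self, X: Sequence[PolysomnogramRecord], threshold: float = 0.5
    ) -> list[np.ndarray]:
        """Binary arousal masks at the native rate."""
        return [
            (t.probabilities >= threshold).astype(np.int8)
            for t in self.predict_proba(X)
        ]

    def score(
        self, X: Sequence[PolysomnogramRecord], y: Sequence[LabelTrack]
    ) -> float:
        """Gross AUPRC (the study's primary metric) on the given records."""
        return gross_auprc(y, self.predict_proba(X))

    def evaluate(
        self, X: Sequence[PolysomnogramRecord], y: Sequence[LabelTrack]
    ) -> EvalReport:
        return evaluate_dataset(y, self.predict_proba(X))
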