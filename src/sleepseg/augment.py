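"""Training-time augmentation.

Three transforms, all label-safe by construction:

* **Channel swapping** — the six EEG derivations are physiologically
  interchangeable for arousal scoring, as are the abdominal and chest EMG
  belts; a fresh random permutation of the EEG block (uniform over all 6!)
  and a coin-flip ABD/Chest swap are drawn per record per epoch.  Chin EMG,
  EOG, airflow, SaO2 and ECG are never touched.
* **Magnitude jitter** — one scalar per record drawn uniformly from a range
  (default [0.90, 1.15], the wider [0.80, 1.25] variant available via
  config) multiplies every channel, simulating instrument gain fluctuation.
* **Time stretch** — resample the record along the time axis by a uniform
  factor (signals linearly interpolated, labels nearest-neighbor).  Ships
  disabled by default; stretching was found to hurt rather than help.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError, ShapeError, SizeError
from .records import (
    ABD_INDEX,
    CANONICAL_CHANNELS,
    CHEST_INDEX,
    EEG_INDICES,
    LabelTrack,
    PolysomnogramRecord,
)


@dataclass
class AugmentPolicy:
    """Which augmentations to apply during training and with what ranges."""

    swap_channels: bool = True
    magnitude_range: Optional[tuple[float, float]] = (0.90, 1.15)
    stretch_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in ("magnitude_range", "stretch_range"):
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if not (0.0 < lo <= hi):
                    raise ParameterError(
                        f"{name} must satisfy 0 < low <= high, got {rng}"
                    )

    @classmethod
    def disabled(cls) -> "AugmentPolicy":
        return cls(swap_channels=False, magnitude_range=None, stretch_range=None)


def _check_canonical(n_channels: int) -> None:
    if n_channels != len(CANONICAL_CHANNELS):
        raise ShapeError(
            f"augmentation expects the canonical {len(CANONICAL_CHANNELS)}-"
            f"channel montage, got {n_channels} channels"
        )


def swap_channels_array(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the EEG rows uniformly and swap ABD/Chest with prob. 1/2.

    Operates on a ``[13 x time]`` matrix in canonical order; returns a new
    array.  Rows outside the two interchangeable groups are copied verbatim.
    """
    _check_canonical(x.shape[0])
    out = x.copy()
    eeg = list(EEG_INDICES)
    perm = rng.permutation(len(eeg))
    out[eeg] = x[[eeg[i] for i in perm]]
    if rng.random() < 0.5:
        out[[ABD_INDEX, CHEST_INDEX]] = x[[CHEST_INDEX, ABD_INDEX]]
    return out


def swap_channels(
    record: PolysomnogramRecord, rng: np.random.Generator
) -> PolysomnogramRecord:
    """Record-level :func:`swap_channels_array`.  Labels are untouched by
    design — the groups are assumed interchangeable for arousal scoring."""
    return record.with_samples(swap_channels_array(record.samples, rng))


def scale_magnitude_array(
    x: np.ndarray,
    rng: np.random.Generator,
    magnitude_range: tuple[float, float] = (0.90, 1.15),
) -> np.ndarray:
    """Multiply all channels by one scalar ~ Uniform(range)."""
    lo, hi = magnitude_range
    if lo <= 0:
        raise ParameterError("magnitude range must be positive")
    if hi < lo:
        raise ParameterError("magnitude range must satisfy low <= high")
    c = rng.uniform(lo, hi)
    return x * c


def scale_magnitude(
    record: PolysomnogramRecord,
    rng: np.random.Generator,
    magnitude_range: tuple[float, float] = (0.90, 1.15),
) -> PolysomnogramRecord:
    return record.with_samples(
        scale_magnitude_array(record.samples, rng, magnitude_range)
    )


def stretch_time_arrays(
    x: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    stretch_range: tuple[float, float] = (0.90, 1.15),
):
    """Stretch/shrink along time by c ~ Uniform(range).

    New length is ``round(old * c)``; signals are linearly interpolated,
    labels nearest-neighbor resampled so values stay in {-1, 0, 1}.
    """
    lo, hi = stretch_range
    if lo <= 0 or hi < lo:
        raise ParameterError("invalid stretch range")
    c = rng.uniform(lo, hi)
    n = x.shape[-1]
    new_n = int(round(n * c))
    if new_n < 2:
        raise SizeError("stretched record would be shorter than 2 samples")
    positions = np.linspace(0.0, n - 1.0, new_n)
    old = np.arange(n, dtype=np.float64)
    out = np.stack([np.interp(positions, old, row) for row in np.atleast_2d(x)])
    if x.ndim == 1:
        out = out[0]
    nearest = np.clip(np.round(positions).astype(np.int64), 0, n - 1)
    return out, labels[nearest]


def stretch_time(
    record: PolysomnogramRecord,
    labels: LabelTrack,
    rng: np.random.Generator,
    stretch_range: tuple[float, float] = (0.90, 1.15),
):
    x, y = stretch_time_arrays(
        record.samples, labels.values, rng, stretch_range
    )
    return record.with_samples(x), LabelTrack(y)


def apply_policy_arrays(
    x: np.ndarray,
    y: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
):
    """Apply a full policy to prepared arrays (fresh draws per call).

    Used online in the training loop, after normalization.  Order: channel
    swap, magnitude jitter, then (if enabled) time stretch.
    """
    if policy.swap_channels:
        x = swap_channels_array(x, rng)
    if policy.magnitude_range is not None:
        x = scale_magnitude_array(x, rng, policy.magnitude_range)
    if policy.stretch_range is not None:
        x, y = stretch_time_arrays(x, y, rng, policy.stretch_range)
    return x, y
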