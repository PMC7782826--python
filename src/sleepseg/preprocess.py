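"""Per-channel signal normalization.

Two schemes are provided, matching the two the pipeline compares:

* **Gaussian normalization** — subtract the channel mean and divide by the
  sample standard deviation (N-1 denominator), channel by channel.
* **Quantile normalization** — map each channel's empirical distribution onto
  a reference distribution by rank: sort the channel, replace the sorted
  values with the reference quantiles, and restore the original order.  The
  reference is built by averaging the sorted training records per channel.
  Because the mapping depends only on ranks, any strictly monotone per-record
  distortion (instrument gain, offset) is removed exactly — this is what
  makes it the default for cross-individual, cross-instrument batch effects.

Records differ in length by hours, so rank replacement is generalized to a
fixed evenly spaced quantile grid (default 10,001 points) with linear
interpolation, both when building the reference and when mapping a record
onto it.  Ties get their average rank before grid mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError, ShapeError
from .records import PolysomnogramRecord

DEFAULT_GRID_SIZE = 10_001


def gaussian_normalize(channel: np.ndarray) -> np.ndarray:
    """Normalize a 1D signal to zero mean, unit sample standard deviation.

    The standard deviation uses the N-1 denominator.  A constant channel
    (zero spread) is degenerate: all zeros are returned with a warning.
    """
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1:
        raise ShapeError("gaussian_normalize expects a 1D channel")
    if x.size < 2:
        raise ParameterError("need at least 2 samples to normalize")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        warnings.warn(
            "constant channel: returning zeros", RuntimeWarning, stacklevel=2
        )
        return np.zeros_like(x)
    return (x - mean) / sd


def gaussian_normalize_record(record: PolysomnogramRecord) -> PolysomnogramRecord:
    """Apply :func:`gaussian_normalize` channel by channel."""
    out = np.empty_like(record.samples, dtype=np.float64)
    for c in range(record.n_channels):
        out[c] = gaussian_normalize(record.samples[c])
    return record.with_samples(out)


@dataclass
class QuantileReference:
    """Per-channel reference quantile table on an even grid.

    ``values[c, g]`` is the reference signal value of channel ``c`` at
    quantile position ``g / (grid_size - 1)``.  Rows are nondecreasing.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ShapeError("reference must be [channels x grid] with grid >= 2")
        if np.any(np.diff(self.values, axis=1) < -1e-12):
            raise ParameterError("reference rows must be nondecreasing")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def grid_size(self) -> int:
        return self.values.shape[1]

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_size)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("reference", data=self.values)
            f.attrs["grid_size"] = self.grid_size

    @classmethod
    def load(cls, path: str | Path) -> "QuantileReference":
        with h5py.File(path, "r") as f:
            return cls(f["reference"][()])


def _sorted_to_grid(channel: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Interpolate one channel's order statistics onto the quantile grid."""
    s = np.sort(np.asarray(channel, dtype=np.float64))
    n = s.size
    if n == 1:
        return np.full(grid.size, s[0])
    positions = np.arange(n) / (n - 1)
    return np.interp(grid, positions, s)


def build_quantile_reference(
    records: Sequence[PolysomnogramRecord] | Iterable[PolysomnogramRecord],
    grid_size: int = DEFAULT_GRID_SIZE,
) -> QuantileReference:
    """Average the sorted training records, per channel, onto a common grid.

    Records of different lengths are first interpolated onto the evenly
    spaced quantile grid, then averaged pointwise; the average of
    nondecreasing rows is nondecreasing.
    """
    if grid_size < 2:
        raise ParameterError("grid_size must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    total = None
    count = 0
    for record in records:
        rows = np.stack(
            [_sorted_to_grid(record.samples[c], grid)
             for c in range(record.n_channels)]
        )
        total = rows if total is None else total + rows
        count += 1
    if count == 0:
        raise ParameterError("need at least one record to build a reference")
    return QuantileReference(total / count)


def quantile_normalize(
    record: PolysomnogramRecord, reference: QuantileReference
) -> PolysomnogramRecord:
    """Map each channel of a record onto the reference distribution by rank.

    Rank ``k`` of ``N`` (ties by average rank) maps to quantile position
    ``(k - 1) / (N - 1)``; the output takes the reference value there by
    linear interpolation and is written back at the original position, so
    the output's sort order equals the input's.
    """
    if reference.n_channels != record.n_channels:
        raise ShapeError(
            f"reference has {reference.n_channels} channels, record "
            f"{record.n_channels}"
        )
    grid = reference.grid
    n = record.n_timepoints
    out = np.empty_like(record.samples, dtype=np.float64)
    for c in range(record.n_channels):
        if n == 1:
            out[c] = reference.values[c, reference.grid_size // 2]
            continue
        ranks = rankdata(record.samples[c], method="average")
        q = (ranks - 1.0) / (n - 1.0)
        out[c] = np.interp(q, grid, reference.values[c])
    return record.with_samples(out)


def normalize_record(
    record: PolysomnogramRecord,
    method: str = "quantile",
    reference: QuantileReference | None = None,
) -> PolysomnogramRecord:
    """Dispatch on the normalization method (``'quantile'`` needs a
    reference; ``'gaussian'`` does not)."""
    if method == "gaussian":
        return gaussian_normalize_record(record)
    if method == "quantile":
        if reference is None:
            raise ParameterError("quantile normalization needs a reference")
        return quantile_normalize(record, reference)
    raise ParameterError(f"unknown normalization method {method!r}")


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping reference construction and
    rank mapping.

    ``fit`` builds the averaged reference from a list of
    :class:`PolysomnogramRecord`; ``transform`` maps records onto it.
    """

    def __init__(self, grid_size: int = DEFAULT_GRID_SIZE):
        self.grid_size = grid_size

    def fit(self, X: Sequence[PolysomnogramRecord], y=None):
        self.reference_ = build_quantile_reference(X, grid_size=self.grid_size)
        return self

    def transform(self, X: Sequence[PolysomnogramRecord]):
        if not hasattr(self, "reference_"):
            raise ParameterError("QuantileNormalizer is not fitted")
        return [quantile_normalize(r, self.reference_) for r in X]
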