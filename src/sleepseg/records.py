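"""Polysomnogram data model, container IO, padding, resolution reduction and
dataset partitioning.

A record is a ``[n_channels x n_timepoints]`` matrix of physiological signals
in the canonical 13-channel montage (six EEG derivations, one EOG, chin /
abdominal / chest EMG, airflow, oxygen saturation, ECG) sampled at a single
rate, typically 200 Hz.  Per-sample annotations live in a parallel
:class:`LabelTrack` over ``{-1, 0, 1}``: arousal is ``1``, sleep is ``0`` and
``-1`` marks non-scored regions (wakefulness, apnea/hypopnea arousals) that
are excluded from both training losses and evaluation.

The native on-disk container is one HDF5 file per record with datasets
``/signals``, ``/labels``, ``/stages`` and attributes ``record_id``,
``sampling_rate`` and ``channel_names``.  Read-only adapters exist for
PhysioNet-2018-style WFDB ``.mat``/``.hea`` pairs (via :mod:`scipy.io`) and
for EDF (via :mod:`mne`, imported lazily).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import (
    AlignmentError,
    FormatError,
    ParameterError,
    ShapeError,
    SizeError,
    ValidationError,
)

#: Canonical channel order.  All downstream code (augmentation groups in
#: particular) indexes channels by position after records are reordered to
#: this montage at read time.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "F3-M2", "F4-M1", "C3-M2", "C4-M1", "O1-M2", "O2-M1",
    "E1-M2", "Chin", "ABD", "Chest", "Airflow", "SaO2", "ECG",
)

#: Positional channel groups used by augmentation and the synthetic generator.
EEG_INDICES: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
EOG_INDEX: int = 6
CHIN_INDEX: int = 7
ABD_INDEX: int = 8
CHEST_INDEX: int = 9

#: Hypnogram-style annotation categories (used by the synthetic generator and
#: the track visualizer only; the segmentation target is the binary arousal
#: label).
STAGE_CATEGORIES: tuple[str, ...] = (
    "Arousal", "Undefined", "REM", "N1", "N2", "N3", "Wake", "Apnea",
)

# Aliases seen in PhysioNet-2018 headers / EDF montages, lower-cased.
_CHANNEL_ALIASES = {
    "chest": "Chest",
    "airflow": "Airflow",
    "chin1-chin2": "Chin",
    "chin": "Chin",
    "abd": "ABD",
    "sao2": "SaO2",
    "ecg": "ECG",
}
_CANONICAL_BY_LOWER = {name.lower(): name for name in CANONICAL_CHANNELS}


def canonicalize_channel_name(name: str) -> str:
    """Map a vendor channel label onto the canonical montage name.

    Unknown labels are returned unchanged (and will be reported as
    missing/extra by :func:`read_record`).
    """
    low = name.strip().lower()
    if low in _CANONICAL_BY_LOWER:
        return _CANONICAL_BY_LOWER[low]
    return _CHANNEL_ALIASES.get(low, name.strip())


@dataclass
class PolysomnogramRecord:
    """A multi-channel polysomnographic signal matrix.

    Parameters
    ----------
    record_id : str
        Identifier, unique within a dataset.
    sampling_rate : float
        Samples per second; must be positive.
    channel_names : tuple of str
        One name per row of ``samples``; unique.
    samples : ndarray, shape (n_channels, n_timepoints)
        Signal values in arbitrary per-channel physical units; finite.
    """

    record_id: str
    sampling_rate: float
    channel_names: tuple[str, ...]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ShapeError("samples must be a 2D [channels x time] matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ShapeError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("duplicate channel names")
        if self.samples.shape[1] < 1:
            raise ShapeError("record must contain at least one timepoint")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "PolysomnogramRecord":
        """Copy of this record with a replaced signal matrix."""
        return PolysomnogramRecord(
            self.record_id, self.sampling_rate, self.channel_names, samples
        )


@dataclass
class LabelTrack:
    """Per-sample arousal annotation over ``{-1, 0, 1}``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ShapeError("label track must be 1D")
        bad = np.setdiff1d(np.unique(self.values), [-1, 0, 1])
        if bad.size:
            raise ValidationError(f"labels outside {{-1,0,1}}: {bad.tolist()}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class StageTrack:
    """Per-sample annotation over the eight hypnogram categories.

    Stored as small-integer codes indexing :data:`STAGE_CATEGORIES`.
    """

    values: np.ndarray
    categories: tuple[str, ...] = STAGE_CATEGORIES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ShapeError("stage track must be 1D")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() >= len(self.categories)
        ):
            raise ValidationError("stage code out of range")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class DatasetPartition:
    """Disjoint train/validation/test record-id lists."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def all_ids(self) -> list[str]:
        return list(self.train_ids) + list(self.val_ids) + list(self.test_ids)


# ---------------------------------------------------------------------------
# Container IO
# ---------------------------------------------------------------------------

def _reorder_to_canonical(
    names: Sequence[str], samples: np.ndarray
) -> np.ndarray:
    mapped = [canonicalize_channel_name(n) for n in names]
    if len(set(mapped)) != len(mapped):
        dupes = sorted({n for n in mapped if mapped.count(n) > 1})
        raise FormatError(f"duplicate channel name(s): {', '.join(dupes)}")
    index = {n: i for i, n in enumerate(mapped)}
    missing = [n for n in CANONICAL_CHANNELS if n not in index]
    if missing:
        raise FormatError(f"missing channel(s): {', '.join(missing)}")
    order = [index[n] for n in CANONICAL_CHANNELS]
    return samples[order]


def write_record(
    path: str | Path,
    record: PolysomnogramRecord,
    labels: Optional[LabelTrack] = None,
    stages: Optional[StageTrack] = None,
) -> None:
    """Write a record (plus optional annotation tracks) to the native HDF5
    container.  Round-trips losslessly through :func:`read_record`."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=record.samples)
        f.attrs["record_id"] = record.record_id
        f.attrs["sampling_rate"] = float(record.sampling_rate)
        f.attrs["channel_names"] = [n for n in record.channel_names]
        if labels is not None:
            if len(labels) != record.n_timepoints:
                raise AlignmentError(
                    f"labels ({len(labels)}) and signals "
                    f"({record.n_timepoints}) differ in length"
                )
            f.create_dataset("labels", data=labels.values)
        if stages is not None:
            if len(stages) != record.n_timepoints:
                raise AlignmentError("stages and signals differ in length")
            f.create_dataset("stages", data=stages.values)
            f.attrs["stage_categories"] = list(stages.categories)


def _read_hdf5(path: Path):
    with h5py.File(path, "r") as f:
        samples = f["signals"][()]
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        ]
        record_id = str(f.attrs.get("record_id", path.stem))
        rate = float(f.attrs["sampling_rate"])
        labels = f["labels"][()] if "labels" in f else None
        stages = f["stages"][()] if "stages" in f else None
    samples = _reorder_to_canonical(names, samples)
    record = PolysomnogramRecord(record_id, rate, CANONICAL_CHANNELS, samples)
    label_track = None
    if labels is not None:
        if labels.shape[0] != record.n_timepoints:
            raise AlignmentError(
                f"labels ({labels.shape[0]}) and signals "
                f"({record.n_timepoints}) differ in length"
            )
        label_track = LabelTrack(labels)
    stage_track = StageTrack(stages) if stages is not None else None
    return record, label_track, stage_track


_HEA_GAIN_RE = re.compile(r"^([-+0-9.eE]+)")


def _read_wfdb_mat(path: Path):
    """Read a PhysioNet-2018-style ``.mat``/``.hea`` pair.

    The ``.hea`` header carries one line per signal whose third token encodes
    the ADC gain (``6553.59(0)/uV`` style) and whose last token is the channel
    name; the MATLAB file stores the raw digital matrix under ``val``.
    """
    from scipy.io import loadmat

    base = path.with_suffix("")
    hea = base.with_suffix(".hea")
    mat = base.with_suffix(".mat")
    if not hea.exists():
        raise FormatError(f"header file not found: {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    rate = float(head[2])
    names, gains = [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        names.append(tok[-1])
        m = _HEA_GAIN_RE.match(tok[2])
        gains.append(float(m.group(1)) if m else 1.0)
    raw = loadmat(str(mat))["val"].astype(np.float64)
    if raw.shape[0] != n_sig:
        raise FormatError(
            f"header declares {n_sig} signals, .mat holds {raw.shape[0]}"
        )
    samples = raw / np.asarray(gains)[:, None]
    samples = _reorder_to_canonical(names, samples)
    record = PolysomnogramRecord(base.name, rate, CANONICAL_CHANNELS, samples)
    return record, None, None


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = _reorder_to_canonical(raw.ch_names, raw.get_data())
    record = PolysomnogramRecord(
        path.stem, float(raw.info["sfreq"]), CANONICAL_CHANNELS, samples
    )
    return record, None, None


def read_record(
    path: str | Path, format: Optional[str] = None
):
    """Read a polysomnogram from disk.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {'hdf5', 'wfdb-mat', 'edf'}, optional
        Dialect; inferred from the suffix when omitted.

    Returns
    -------
    (PolysomnogramRecord, LabelTrack or None, StageTrack or None)
        Channels are reordered to the canonical montage.  Annotation tracks
        are returned when the container holds them (native HDF5 only).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".h5": "hdf5", ".hdf5": "hdf5",
            ".mat": "wfdb-mat", ".hea": "wfdb-mat",
            ".edf": "edf",
        }.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "wfdb-mat":
        return _read_wfdb_mat(path)
    if format == "edf":
        return _read_edf(path)
    raise ParameterError(f"unknown format {format!r}")


def write_predictions(probabilities, path: str | Path) -> None:
    """Write per-sample probabilities as a flat text column (one value per
    line), the PhysioNet ``.vec`` style.  Values must lie in [0, 1]."""
    from .training import PredictionTrack  # local import to avoid a cycle

    if isinstance(probabilities, PredictionTrack):
        probabilities = probabilities.probabilities
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim != 1:
        raise ShapeError("prediction track must be 1D")
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValidationError("probabilities outside [0, 1]")
    np.savetxt(path, probs, fmt="%.9f")


def read_predictions(path: str | Path) -> np.ndarray:
    """Read a flat-text probability column written by
    :func:`write_predictions`."""
    probs = np.atleast_1d(np.loadtxt(path, dtype=np.float64))
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValidationError("probabilities outside [0, 1]")
    return probs


# ---------------------------------------------------------------------------
# Padding and resolution reduction
# ---------------------------------------------------------------------------

def center_pad_arrays(
    samples: np.ndarray, labels: np.ndarray, target_length: int
):
    """Center a signal matrix (and its label vector) inside ``target_length``
    samples, zero-filling the signal extremes and marking padded labels as
    non-scored (``-1``).

    Returns ``(padded_samples, padded_labels, offset)`` where the original
    content occupies ``[offset, offset + n)`` and
    ``offset = floor((target - n) / 2)`` (left-biased for odd remainders).
    """
    n = samples.shape[-1]
    if labels is not None and labels.shape[0] != n:
        raise AlignmentError("labels and signals differ in length")
    if target_length < n:
        raise SizeError(
            f"target_length {target_length} < record length {n}; "
            "this operation never truncates"
        )
    offset = (target_length - n) // 2
    right = target_length - n - offset
    if samples.ndim == 1:
        padded = np.pad(samples, (offset, right))
    else:
        padded = np.pad(samples, ((0, 0), (offset, right)))
    padded_labels = None
    if labels is not None:
        padded_labels = np.pad(labels, (offset, right), constant_values=-1)
    return padded, padded_labels, offset


def center_pad(
    record: PolysomnogramRecord, labels: LabelTrack, target_length: int
):
    """Record-level :func:`center_pad_arrays`; see there for the contract."""
    padded, padded_labels, offset = center_pad_arrays(
        record.samples, labels.values if labels is not None else None,
        target_length,
    )
    out_labels = LabelTrack(padded_labels) if padded_labels is not None else None
    return record.with_samples(padded), out_labels, offset


def _pad_to_multiple(x: np.ndarray, factor: int) -> np.ndarray:
    """Edge-pad the time axis to a multiple of ``factor``."""
    n = x.shape[-1]
    rem = (-n) % factor
    if rem == 0:
        return x
    if x.ndim == 1:
        return np.pad(x, (0, rem), mode="edge")
    return np.pad(x, ((0, 0), (0, rem)), mode="edge")


def downsample_average(x: np.ndarray, factor: int) -> np.ndarray:
    """Reduce temporal resolution by averaging blocks of ``factor``
    successive time points.

    Works on a 1D signal or a ``[channels x time]`` matrix.  If the length is
    not divisible by ``factor`` the time axis is edge-padded to a multiple
    first (the trailing block then averages fewer distinct values).
    """
    if factor < 1:
        raise ParameterError("factor must be a positive integer")
    x = np.asarray(x, dtype=np.float64)
    if factor == 1:
        return x.copy()
    x = _pad_to_multiple(x, factor)
    if x.ndim == 1:
        return x.reshape(-1, factor).mean(axis=1)
    return x.reshape(x.shape[0], -1, factor).mean(axis=2)


def downsample_labels(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-reduce a ``{-1, 0, 1}`` label track with the precedence
    ``1 > -1 > 0``: any arousal sample marks the whole block arousal,
    otherwise any non-scored sample marks it non-scored.

    Arousal is the rare class; block voting with this precedence preserves it
    under resolution reduction.
    """
    if factor < 1:
        raise ParameterError("factor must be a positive integer")
    values = np.asarray(values, dtype=np.int8)
    if factor == 1:
        return values.copy()
    padded = _pad_to_multiple(values, factor)
    blocks = padded.reshape(-1, factor)
    out = np.zeros(blocks.shape[0], dtype=np.int8)
    out[np.any(blocks == -1, axis=1)] = -1
    out[np.any(blocks == 1, axis=1)] = 1
    return out


# ---------------------------------------------------------------------------
# Dataset partitioning
# ---------------------------------------------------------------------------

def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [math.floor(e) for e in exact]
    leftover = n - sum(base)
    remainders = [e - b for e, b in zip(exact, base)]
    # distribute leftover to the largest fractional parts; ties go to the
    # earlier entry for determinism
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_records(
    ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
) -> DatasetPartition:
    """Randomly partition record ids into train/validation/test sets.

    Sizes follow largest-remainder rounding of ``len(ids) * fraction`` (so 100
    ids under the default 60/15/25 split give exactly 60, 15 and 25 ids).
    Reproducible for a fixed seed.
    """
    ids = list(ids)
    if not ids:
        raise ParameterError("ids must be non-empty")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train, n_val, _ = _largest_remainder_sizes(len(ids), fractions)
    return DatasetPartition(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train : n_train + n_val],
        test_ids=shuffled[n_train + n_val :],
        seed=seed,
    )
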