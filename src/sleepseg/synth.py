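"""Seeded synthetic polysomnogram generator.

Emulates the statistical structure the pipeline has to cope with — variable
record lengths, sparse arousal events (~7% of scored time, overdispersed
per-record counts), arousal-correlated channel signatures (EMG amplitude
bursts on the abdominal/chest belts, an EEG high-band power increase),
non-scored ``-1`` regions (wake at the record edges, apnea blocks), and a
per-record instrument gain — without attempting physiological realism: the
channels are band-limited or amplitude-modulated noise processes, which is
exactly enough to test normalization, augmentation, training and scoring.

Two properties are built in deliberately:

* the arousal effects are applied identically across each interchangeable
  channel group, so EEG permutation and ABD/Chest swapping are label-neutral
  by construction (validating the augmentation assumption where it is
  literally true);
* the per-record gain jitter gives quantile normalization a batch effect to
  remove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError, PlacementError
from .records import (
    ABD_INDEX,
    CANONICAL_CHANNELS,
    CHEST_INDEX,
    CHIN_INDEX,
    EEG_INDICES,
    EOG_INDEX,
    STAGE_CATEGORIES,
    LabelTrack,
    PolysomnogramRecord,
    StageTrack,
)

_STAGE = {name: i for i, name in enumerate(STAGE_CATEGORIES)}


@dataclass
class SynthConfig:
    """Study-condition parameters of the generator.

    Defaults are desk-scale: 2^14-sample records (~82 s at 200 Hz) standing
    in for overnight recordings, with the arousal fraction, per-record event
    heterogeneity and non-scored structure of the real data preserved.
    """

    n_records: int = 10
    record_length: int = 2 ** 14
    sampling_rate: float = 200.0
    arousal_rate: float = 0.07
    event_duration: tuple[float, float] = (100.0, 600.0)  # samples, log-uniform
    per_record_count_dispersion: float = 1.0
    wake_edge_fraction: float = 0.05
    apnea_block_rate: float = 1.5
    effect_emg_gain: float = 3.0
    effect_eeg_shift: float = 1.0
    noise_gain_range: tuple[float, float] = (0.5, 2.0)
    length_fraction_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.arousal_rate < 0.5:
            raise ParameterError("arousal_rate must lie in (0, 0.5)")
        if not self.wake_edge_fraction < 0.25:
            raise ParameterError("wake_edge_fraction must be < 0.25")
        for name in ("effect_emg_gain", "effect_eeg_shift"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.noise_gain_range[0] <= 0:
            raise ParameterError("gains must be positive")
        lo, hi = self.event_duration
        if not 0 < lo <= hi:
            raise ParameterError("event_duration must satisfy 0 < low <= high")


def _band_noise(rng, n, sr, low, high):
    """Unit-variance band-limited Gaussian noise via a zero-phase
    Butterworth filter; band edges are clipped below Nyquist."""
    nyq = sr / 2.0
    high = min(high, 0.9 * nyq)
    low = min(low, 0.5 * high)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [low / nyq, high / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _place_events(rng, free: np.ndarray, durations, max_tries: int = 200):
    """Place non-overlapping events of given durations where ``free`` is
    True; returns (start, length) pairs and marks the occupancy in-place."""
    n = free.shape[0]
    placed = []
    for dur in durations:
        dur = int(dur)
        ok = False
        for _ in range(max_tries):
            start = int(rng.integers(0, max(1, n - dur)))
            if free[start : start + dur].all():
                free[start : start + dur] = False
                placed.append((start, dur))
                ok = True
                break
        if not ok:
            raise PlacementError(
                "could not place events without overlap; lower arousal_rate "
                "or apnea_block_rate"
            )
    return placed


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_record(
    config: SynthConfig,
    rng: np.random.Generator,
    record_id: str = "syn-0000",
):
    """Generate one record; returns ``(record, labels, stages, info)`` where
    ``info`` is a manifest row (event count, arousal fraction, gain)."""
    sr = config.sampling_rate
    lo_f, hi_f = config.length_fraction_range
    n = int(round(config.record_length * rng.uniform(lo_f, hi_f)))
    n = max(n, 64)
    t = np.arange(n) / sr

    labels = np.zeros(n, dtype=np.int8)
    stages = np.full(n, _STAGE["Undefined"], dtype=np.int8)

    edge = int(config.wake_edge_fraction * n)
    if edge:
        labels[:edge] = -1
        labels[-edge:] = -1
        stages[:edge] = _STAGE["Wake"]
        stages[-edge:] = _STAGE["Wake"]

    # sleep-stage blocks in the interior (visualization only)
    pos = edge
    cycle = ["N1", "N2", "N3", "N2", "REM"]
    ci = 0
    while pos < n - edge:
        block = int(rng.uniform(20.0, 40.0) * sr)
        stages[pos : min(pos + block, n - edge)] = _STAGE[cycle[ci % len(cycle)]]
        ci += 1
        pos += block

    free = np.zeros(n, dtype=bool)
    free[edge : n - edge] = True

    # apnea blocks: non-scored, Poisson count
    n_apnea = int(rng.poisson(config.apnea_block_rate))
    apnea_durs = rng.uniform(0.01 * n, 0.03 * n, n_apnea)
    for start, dur in _place_events(rng, free, apnea_durs):
        labels[start : start + dur] = -1
        stages[start : start + dur] = _STAGE["Apnea"]

    # arousal events: overdispersed (gamma-poisson) count around the rate
    # implied by the target arousal fraction and the mean event duration
    d_lo, d_hi = config.event_duration
    mean_dur = (d_hi - d_lo) / np.log(d_hi / d_lo) if d_hi > d_lo else d_lo
    n_scored_target = int(free.sum())
    lam = config.arousal_rate * n_scored_target / mean_dur
    disp = config.per_record_count_dispersion
    if disp > 0:
        lam = lam * rng.gamma(shape=1.0 / disp, scale=disp)
    n_events = int(rng.poisson(lam))
    # occupancy cap: keep total arousal below 40% of scored time so events
    # remain placeable without overlap even for extreme overdispersed draws
    n_events = min(n_events, int(0.4 * n_scored_target / mean_dur))
    durs = np.sort(_log_uniform(rng, d_lo, d_hi, n_events))[::-1]
    arousal_mask = np.zeros(n, dtype=bool)
    for start, dur in _place_events(rng, free, durs):
        labels[start : start + dur] = 1
        stages[start : start + dur] = _STAGE["Arousal"]
        arousal_mask[start : start + dur] = True

    # --- signals -------------------------------------------------------
    x = np.empty((len(CANONICAL_CHANNELS), n))
    eeg_boost = 1.0 + config.effect_eeg_shift
    for c in EEG_INDICES:
        low = _band_noise(rng, n, sr, 0.3, 4.0)
        high = _band_noise(rng, n, sr, 4.0, 10.0) * 0.5
        high = np.where(arousal_mask, high * eeg_boost, high)
        x[c] = low + high
    x[EOG_INDEX] = _band_noise(rng, n, sr, 0.1, 1.0)

    def emg(gain_in_arousal: float) -> np.ndarray:
        envelope = 0.6 + 0.8 * np.abs(_band_noise(rng, n, sr, 0.05, 0.5))
        carrier = rng.standard_normal(n)
        sig = envelope * carrier
        return np.where(arousal_mask, sig * gain_in_arousal, sig)

    x[CHIN_INDEX] = emg(1.0)
    x[ABD_INDEX] = emg(config.effect_emg_gain)
    x[CHEST_INDEX] = emg(config.effect_emg_gain)

    x[10] = np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi)) \
        + 0.3 * _band_noise(rng, n, sr, 0.05, 1.0)                     # Airflow
    x[11] = 96.0 + 0.8 * _band_noise(rng, n, sr, 0.01, 0.08) \
        + 0.05 * rng.standard_normal(n)                                # SaO2
    period = int(rng.uniform(0.8, 1.1) * sr)
    ecg = 0.1 * rng.standard_normal(n)
    ecg[int(rng.integers(0, period))::period] += 5.0
    x[12] = ecg

    gain = rng.uniform(*config.noise_gain_range)
    x *= gain

    record = PolysomnogramRecord(record_id, sr, CANONICAL_CHANNELS, x)
    n_scored = int((labels >= 0).sum())
    info = {
        "record_id": record_id,
        "n_samples": n,
        "n_scored": n_scored,
        "n_events": n_events,
        "arousal_fraction": float((labels == 1).sum() / max(n_scored, 1)),
        "gain": float(gain),
    }
    return record, LabelTrack(labels), StageTrack(stages), info


def generate_dataset(config: SynthConfig):
    """Generate ``config.n_records`` records with independent sub-seeds
    derived from the master seed.

    Returns ``(items, manifest)`` where ``items`` is a list of
    ``(record, labels, stages)`` tuples and ``manifest`` a per-record
    DataFrame (event counts, arousal fractions, gains).
    """
    if config.n_records < 1:
        raise ParameterError("n_records must be >= 1")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_records)
    items, rows = [], []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        record, labels, stages, info = generate_record(
            config, rng, record_id=f"syn-{i:04d}"
        )
        items.append((record, labels, stages))
        rows.append(info)
    return items, pd.DataFrame(rows)
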