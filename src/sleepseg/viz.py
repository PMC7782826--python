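"""Track visualization: stacked stage band, arousal label band, continuous
prediction curve and an optional per-sample cross-entropy loss strip over a
shared time axis, with zooming to a sample interval."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .errors import ShapeError
from .records import STAGE_CATEGORIES, LabelTrack, StageTrack
from .training import PredictionTrack, per_sample_cross_entropy

_STAGE_COLORS = [
    "#f2c037",  # Arousal
    "#bbbbbb",  # Undefined
    "#7e57c2",  # REM
    "#90caf9",  # N1
    "#42a5f5",  # N2
    "#1565c0",  # N3
    "#ef9a9a",  # Wake
    "#8d6e63",  # Apnea
]
# label band: -1 gray, 0 blue, 1 yellow
_LABEL_COLORS = ["#9e9e9e", "#3949ab", "#f2c037"]


def plot_tracks(
    labels: LabelTrack,
    stages: Optional[StageTrack],
    predictions: PredictionTrack,
    losses: Optional[np.ndarray] = None,
    out: str | Path = "tracks.png",
    interval: Optional[tuple[int, int]] = None,
    sampling_rate: Optional[float] = None,
) -> Path:
    """Render the annotation/prediction tracks to a PNG.

    ``interval=(start, end)`` (in samples) zooms the view; ``losses`` may be
    precomputed or is derived as the per-sample cross-entropy when omitted.
    """
    y = labels.values if hasattr(labels, "values") else np.asarray(labels)
    p = (predictions.probabilities
         if hasattr(predictions, "probabilities") else np.asarray(predictions))
    if y.shape != p.shape:
        raise ShapeError("labels and predictions differ in length")
    s = None
    if stages is not None:
        s = stages.values if hasattr(stages, "values") else np.asarray(stages)
        if s.shape != y.shape:
            raise ShapeError("stages and labels differ in length")
    if losses is None:
        losses = per_sample_cross_entropy(y, p)
    losses = np.asarray(losses, dtype=np.float64)
    if losses.shape != y.shape:
        raise ShapeError("losses and labels differ in length")

    lo, hi = interval if interval is not None else (0, y.shape[0])
    sl = slice(lo, hi)
    n_rows = 3 + (s is not None)
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(12, 1.2 * n_rows + 1), sharex=True,
        gridspec_kw={"height_ratios": [1] * (n_rows - 2) + [2, 1]},
    )
    axes = np.atleast_1d(axes)
    extent = (lo, hi, 0, 1)
    row = 0
    if s is not None:
        axes[row].imshow(
            s[sl][None, :], aspect="auto", extent=extent,
            cmap=ListedColormap(_STAGE_COLORS), vmin=-0.5,
            vmax=len(STAGE_CATEGORIES) - 0.5, interpolation="nearest",
        )
        axes[row].set_yticks([])
        axes[row].set_ylabel("stage", rotation=0, ha="right", va="center")
        row += 1
    axes[row].imshow(
        (y[sl][None, :] + 1), aspect="auto", extent=extent,
        cmap=ListedColormap(_LABEL_COLORS), vmin=-0.5, vmax=2.5,
        interpolation="nearest",
    )
    axes[row].set_yticks([])
    axes[row].set_ylabel("label", rotation=0, ha="right", va="center")
    row += 1
    xs = np.arange(lo, hi)
    axes[row].plot(xs, p[sl], lw=0.7, color="#1565c0")
    axes[row].set_ylim(-0.05, 1.05)
    axes[row].set_ylabel("prediction", rotation=0, ha="right", va="center")
    row += 1
    axes[row].imshow(
        losses[sl][None, :], aspect="auto", extent=extent, cmap="Reds",
        vmin=0.0, interpolation="nearest",
    )
    axes[row].set_yticks([])
    axes[row].set_ylabel("CE loss", rotation=0, ha="right", va="center")
    axes[row].set_xlabel(
        "time (samples)" if sampling_rate is None
        else f"time (samples @ {sampling_rate:g} Hz)"
    )
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
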