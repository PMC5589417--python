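"""Diagnostic figures: trial rasters and temporal-generalization matrices."""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt

from .network import TrialTrace
from .decoding import GeneralizationMatrix

__all__ = ["plot_trial", "plot_generalization"]


def plot_trial(trace: TrialTrace, ax=None, cmap: str = "magma"):
    """Firing-rate raster (time x preferred angle) with event markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    extent = [trace.times[0], trace.times[-1], -np.pi, np.pi]
    im = ax.imshow(trace.raster.T, origin="lower", aspect="auto",
                   extent=extent, cmap=cmap)
    for name, (onset, offset) in trace.events.items():
        ax.axvline(onset, color="w", lw=0.6, ls="--")
        ax.text(onset, np.pi * 1.02, name, fontsize=7, ha="left")
    if trace.target_angle is not None:
        ax.axhline(trace.target_angle, color="cyan", lw=0.5, ls=":")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("preferred angle (rad)")
    plt.colorbar(im, ax=ax, label="rate (Hz)")
    return ax


def plot_generalization(gm: GeneralizationMatrix, ax=None,
                        cmap: str = "RdBu_r"):
    """Train-time x test-time decoding matrix, centered on chance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    chance = 0.5 if gm.metric == "auc" else 0.0
    span = np.nanmax(np.abs(gm.scores - chance))
    extent = [gm.test_times[0], gm.test_times[-1],
              gm.train_times[0], gm.train_times[-1]]
    im = ax.imshow(gm.scores, origin="lower", aspect="auto", extent=extent,
                   cmap=cmap, vmin=chance - span, vmax=chance + span)
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("train time (s)")
    plt.colorbar(im, ax=ax, label=gm.metric)
    return ax
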