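"""Minimal plotting helpers for decode results and modulation maps."""

from __future__ import annotations

import numpy as np


def plot_confusion(result, ax=None):
    """Row-normalised confusion matrix heatmap of a DecodeResult."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(result.confusion, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(result.classes)), result.classes, rotation=90)
    ax.set_yticks(range(len(result.classes)), result.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(
        f"{result.model_name}: {100 * result.mean:.1f}% "
        f"(chance {100 * result.chance:.1f}%)"
    )
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_modulation_map(mod, ax=None):
    """Channels x conditions z-score heatmap with the significance gate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    vmax = max(1.0, np.nanpercentile(np.abs(mod.z[np.isfinite(mod.z)]), 99))
    im = ax.imshow(mod.z, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(
        range(len(mod.conditions)),
        [f"{j}\n{d}" for j, d in mod.conditions],
        fontsize=7,
    )
    ax.set_ylabel("channel")
    ax.set_title(f"modulation z-score (gate z > {mod.z_threshold})")
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax
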