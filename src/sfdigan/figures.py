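"""Static figure export: NMAE scatter plots, difference maps, loss curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import DifferenceMap, NMAEReport

__all__ = ["nmae_scatter", "loss_curves", "difference_map_figure"]


def nmae_scatter(report: NMAEReport, path, envelope_pct: float | None = None):
    """Per-image absorption vs scattering NMAE scatter for a validation set."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(100 * report.per_image["nmae_abs"], 100 * report.per_image["nmae_sct"],
               s=18, alpha=0.8)
    if envelope_pct is not None:
        ax.axvline(envelope_pct, ls="--", c="grey", lw=0.8)
        ax.axhline(envelope_pct, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("absorption NMAE (%)")
    ax.set_ylabel("reduced scattering NMAE (%)")
    ax.set_title(report.label or "validation NMAE")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def loss_curves(history, path):
    """Training losses and validation error per epoch (linear and log)."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, scale in zip(axes, ("linear", "log")):
        ax.plot(history["epoch"], history["val_mse"], label="validation MSE")
        ax.plot(history["epoch"], history["g_l1"], label="train L1")
        ax.set_yscale(scale)
        ax.set_xlabel("epoch")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("loss")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def difference_map_figure(dm: DifferenceMap, path, vmax: float = 25.0):
    """Per-pixel percentage-error map with masked pixels greyed out."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    shown = np.ma.masked_invalid(dm.values)
    im = ax.imshow(shown, vmin=0, vmax=vmax, cmap="inferno")
    fig.colorbar(im, ax=ax, label="|error| (%)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
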