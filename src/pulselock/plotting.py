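"""Basic summary figures: weight matrices and tongue-scan maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_weight_matrix(W: np.ndarray, path: str | Path, title: str = "synaptic weights"):
    """Heatmap of a weight matrix (postsynaptic rows, presynaptic columns)."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(W, vmin=0.0, vmax=1.0, cmap="viridis", origin="upper")
    ax.set_xlabel("presynaptic j")
    ax.set_ylabel("postsynaptic i")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=r"$W_{ij}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tongue_scan(scan, path: str | Path):
    """Locked region of a scan over the (period-ratio, coupling) plane."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.pcolormesh(
        scan.ratios, scan.gs, scan.locked.astype(float), shading="nearest",
        cmap="Blues", vmin=0, vmax=1,
    )
    ax.set_xlabel(r"$T_2 / T_1$")
    ax.set_ylabel("g")
    label = "with STDP" if scan.with_stdp else "frozen weights"
    ax.set_title(f"mode {scan.mode} locking ({label})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
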