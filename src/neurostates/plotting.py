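"""Connectivity-matrix heat maps and scalp-network renders (matplotlib)."""

from __future__ import annotations

import numpy as np

from .connectivity import PLIMatrix
from .montage import MontageSpec, standard_30_channel_montage
from .network import BinaryGraph

__all__ = ["plot_connectivity_matrix", "plot_network"]

# Approximate 2-D scalp coordinates (top view, nose up, left hemisphere on
# the left) for the standard 30-channel layout.
_SCALP_XY = {
    "Fp1": (-0.3, 0.95), "Fp2": (0.3, 0.95),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.6), "Fz": (0.0, 0.6),
    "F4": (0.4, 0.6), "F8": (0.8, 0.6),
    "FC5": (-0.7, 0.3), "FC1": (-0.25, 0.3), "FC2": (0.25, 0.3), "FC6": (0.7, 0.3),
    "T7": (-0.95, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T8": (0.95, 0.0),
    "CP5": (-0.7, -0.3), "CP1": (-0.25, -0.3), "CP2": (0.25, -0.3), "CP6": (0.7, -0.3),
    "P7": (-0.8, -0.6), "P3": (-0.4, -0.6), "Pz": (0.0, -0.6),
    "P4": (0.4, -0.6), "P8": (0.8, -0.6),
    "PO3": (-0.35, -0.8), "PO4": (0.35, -0.8),
    "O1": (-0.3, -0.95), "Oz": (0.0, -0.95), "O2": (0.3, -0.95),
}

_LOBE_ORDER = ("frontal", "central", "temporal", "parietal", "occipital")
_HEMI_ORDER = ("left", "midline", "right")


def _channel_order(montage: MontageSpec, ordering: str) -> list[int]:
    names = montage.channel_names
    if ordering == "front_to_back":
        return list(range(len(names)))
    if ordering == "hemisphere":
        return sorted(
            range(len(names)),
            key=lambda i: (_HEMI_ORDER.index(montage.hemisphere_of[names[i]]), i),
        )
    raise ValueError(f"unknown ordering {ordering!r}")


def plot_connectivity_matrix(
    matrix: PLIMatrix,
    ordering: str = "front_to_back",
    ax=None,
):
    """Heat map of the lower triangle, channels ordered front-to-back or
    grouped left hemisphere / midline / right hemisphere."""
    import matplotlib.pyplot as plt

    montage = standard_30_channel_montage()
    order = _channel_order(montage, ordering)
    values = matrix.values[np.ix_(order, order)]
    shown = np.tril(values)
    names = [montage.channel_names[i] for i in order]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(shown, vmin=0, vmax=max(shown.max(), 1e-9), cmap="viridis")
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
    ax.set_yticks(range(len(names)), names, fontsize=6)
    label = f"PLI ({matrix.band.name} band"
    if matrix.condition:
        label += f", {matrix.condition}"
    ax.set_title(label + ")")
    ax.figure.colorbar(im, ax=ax, label="PLI")
    return ax


def plot_network(
    graph: BinaryGraph,
    montage: MontageSpec | None = None,
    ax=None,
):
    """Top-view scalp render: left hemisphere left, occipital at bottom."""
    import matplotlib.pyplot as plt

    montage = montage or standard_30_channel_montage()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for i, j in graph.edge_list():
        xi, yi = _SCALP_XY[montage.channel_names[i]]
        xj, yj = _SCALP_XY[montage.channel_names[j]]
        ax.plot([xi, xj], [yi, yj], color="tab:blue", lw=0.8, alpha=0.6, zorder=1)
    for name in montage.channel_names:
        x, y = _SCALP_XY[name]
        ax.scatter([x], [y], s=60, color="0.2", zorder=2)
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(0, 6),
                    ha="center", fontsize=7)
    circle = plt.Circle((0, 0), 1.1, fill=False, color="0.5")
    ax.add_patch(circle)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    if graph.sparsity is not None:
        ax.set_title(f"binary graph at sparsity {graph.sparsity:.0%}")
    return ax
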