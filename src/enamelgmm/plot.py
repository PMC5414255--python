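"""Minimal phylomorphospace scatter (tips, internal nodes, tree edges)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .phylo import Phylomorphospace


def plot_phylomorphospace(
    pms: Phylomorphospace, path: str | Path, title: str = ""
) -> None:
    """Scatter of PC1/PC2 with the projected tree; writes SVG or PNG."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for parent, child in pms.edges:
        a = pms.coords(parent)
        b = pms.coords(child)
        ax.plot([a[0], b[0]], [a[1], b[1]], color="0.6", lw=0.8, zorder=1)
    for label, c in pms.tip_coords.items():
        ax.scatter(c[0], c[1], s=28, color="tab:blue", zorder=3)
        ax.annotate(label, (c[0], c[1]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    for nid, c in pms.node_coords.items():
        marker = "*" if nid == pms.root_id else "o"
        ax.scatter(c[0], c[1], s=30 if nid == pms.root_id else 10,
                   color="tab:red", marker=marker, zorder=2)
    frac = pms.pca.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * frac[0]:.1f}%)")
    if len(frac) > 1:
        ax.set_ylabel(f"PC2 ({100 * frac[1]:.1f}%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
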