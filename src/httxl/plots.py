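"""Arc-diagram and schematic figures for contact networks.

Contacts are drawn as semicircular arcs over the primary sequence,
colored by range category (short green, mid blue, long red); sub-domain
spans are drawn as a bar underneath. Pairwise allelic comparisons use
the unique-contact palette (cyan / pink / orange).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Arc

from httxl.classify import RangeThresholds, classify_range
from httxl.domains import DomainPartition
from httxl.xlink_io import SitePair

CATEGORY_COLORS = {"short": "#2ca02c", "mid": "#1f77b4", "long": "#d62728"}
UNIQUE_COLORS = ("#17becf", "#e377c2", "#ff7f0e")  # cyan, pink, orange


def arc_diagram(
    contacts: Iterable[SitePair],
    chain_length: int,
    thresholds: RangeThresholds | None = None,
    partition: DomainPartition | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Fig-style arc diagram of one contact set."""
    pairs = getattr(contacts, "pairs", contacts)
    if ax is None:
        fig, ax = plt.subplots(figsize=(10, 3.2))
    else:
        fig = ax.figure
    for p in pairs:
        mid = (p.i + p.j) / 2.0
        width = p.j - p.i
        color = CATEGORY_COLORS[classify_range(p, thresholds)]
        ax.add_patch(
            Arc((mid, 0), width, width * 0.6, theta1=0, theta2=180,
                color=color, lw=0.7, alpha=0.8)
        )
    if partition is not None:
        for k, (name, start, end) in enumerate(partition.segments):
            ax.axvspan(start, end, ymin=0.0, ymax=0.04,
                       color=plt.cm.tab10(k), alpha=0.6)
            ax.text((start + end) / 2, -0.07 * chain_length, name,
                    ha="center", va="top", fontsize=7)
    ax.set_xlim(0, chain_length)
    ax.set_ylim(-0.12 * chain_length, 0.45 * chain_length)
    ax.set_yticks([])
    ax.set_xlabel("residue (Q23 numbering)")
    label = getattr(contacts, "allele_label", "")
    if label:
        ax.set_title(f"Lys–Lys contacts, {label}")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax
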