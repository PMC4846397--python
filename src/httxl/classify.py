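"""Sequence-separation contact categories.

Lys–Lys contacts are grouped by the spacing of the linked residues in
the primary sequence: short-range (within 200 residues, likely within
one secondary-structure element), mid-range (201–1000) and long-range
(> 1000). Separation is always computed in Q23 reference numbering,
with no renumbering for longer polyglutamine tracts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from httxl.xlink_io import SitePair

__all__ = ["RangeThresholds", "CATEGORIES", "classify_range", "categorize_set", "classification_table"]

CATEGORIES = ("short", "mid", "long")


@dataclass(frozen=True)
class RangeThresholds:
    """Category boundaries in residues: short ≤ short_max < mid ≤ mid_max < long."""

    short_max: int = 200
    mid_max: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.short_max < self.mid_max:
            raise ValueError(
                f"need 1 <= short_max < mid_max, got {self.short_max}, {self.mid_max}"
            )


def classify_range(
    pair: SitePair, thresholds: RangeThresholds | None = None
) -> str:
    """Classify one contact; total over all separations ≥ 1."""
    thresholds = thresholds or RangeThresholds()
    sep = pair.separation
    if sep <= thresholds.short_max:
        return "short"
    if sep <= thresholds.mid_max:
        return "mid"
    return "long"


def categorize_set(
    contacts: Iterable[SitePair], thresholds: RangeThresholds | None = None
) -> dict[str, int]:
    """Counts per category; values sum to the number of contacts."""
    counts = Counter(classify_range(p, thresholds) for p in contacts)
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


def classification_table(
    contacts: Iterable[SitePair], thresholds: RangeThresholds | None = None
) -> pd.DataFrame:
    """Per-pair table (i, j, separation, category, support) for CSV export."""
    rows = [
        {
            "i": p.i,
            "j": p.j,
            "separation": p.separation,
            "category": classify_range(p, thresholds),
            "support": p.support,
        }
        for p in contacts
    ]
    return pd.DataFrame(rows, columns=["i", "j", "separation", "category", "support"])
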