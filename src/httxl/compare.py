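"""Contact-network comparison across the polyglutamine allelic series.

All alleles (Q2–Q78) are numbered in the Q23 reference frame, so a
contact is identified across alleles by exact residue-pair equality.
Subtracting the contacts shared by two alleles leaves the networks that
are relatively specific to each — e.g. amino-terminal (NTD-I) contacts
with CTD-I for the short tract versus CTD-II contacts with CTD-I for
the expanded tract. The counting unit is the unique residue pair, not
the PSM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from httxl.domains import DomainPartition
from httxl.xlink_io import SitePair

__all__ = [
    "ContactSet",
    "shared_links",
    "unique_links",
    "pairwise_matrix",
    "domain_pair_summary",
]


@dataclass
class ContactSet:
    """Per-allele collection of unique, canonicalized site pairs."""

    allele_label: str
    pairs: frozenset[SitePair] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)

    @classmethod
    def from_pairs(cls, allele_label: str, pairs: Iterable[SitePair]) -> "ContactSet":
        return cls(allele_label, frozenset(pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs, key=lambda p: (p.i, p.j)))


def shared_links(a: ContactSet, b: ContactSet) -> frozenset[SitePair]:
    """Contacts present in both alleles (exact (i, j) intersection).

    Symmetric in its arguments; support counts, which may differ between
    alleles, are taken from ``a``.
    """
    return a.pairs & b.pairs


def unique_links(a: ContactSet, b: ContactSet) -> frozenset[SitePair]:
    """Contacts of ``a`` not observed in ``b``.

    Satisfies |a| = |shared(a, b)| + |unique(a, b)|.
    """
    return a.pairs - b.pairs


def pairwise_matrix(sets: Sequence[ContactSet]) -> pd.DataFrame:
    """Shared/unique counts for every unordered allele pair.

    One row per pair with columns (allele_i, allele_j, n_shared,
    n_unique_i, n_unique_j), consistent with :func:`shared_links` and
    :func:`unique_links` by construction.
    """
    if len(sets) < 2:
        raise ValueError("pairwise comparison needs at least two contact sets")
    rows = []
    for a, b in combinations(sets, 2):
        rows.append(
            {
                "allele_i": a.allele_label,
                "allele_j": b.allele_label,
                "n_shared": len(shared_links(a, b)),
                "n_unique_i": len(unique_links(a, b)),
                "n_unique_j": len(unique_links(b, a)),
            }
        )
    return pd.DataFrame(rows)


def domain_pair_summary(
    contacts: ContactSet | Iterable[SitePair], partition: DomainPartition
) -> pd.DataFrame:
    """Contact counts per unordered sub-domain pair.

    Each site pair is assigned to the cell (domain(i), domain(j)); the
    matrix is symmetric by construction and stored in the upper triangle
    (domain order of the partition), so the grand total of the returned
    frame equals the number of contacts.

    Raises
    ------
    ValueError
        If a contact endpoint falls outside the partition span.
    """
    names = [name for name, _, _ in partition.segments]
    index = {name: k for k, name in enumerate(names)}
    mat = np.zeros((len(names), len(names)), dtype=int)
    pairs = contacts.pairs if isinstance(contacts, ContactSet) else contacts
    for p in pairs:
        di = index[partition.domain_of(p.i)]
        dj = index[partition.domain_of(p.j)]
        lo, hi = min(di, dj), max(di, dj)
        mat[lo, hi] += 1
    return pd.DataFrame(mat, index=names, columns=names)
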