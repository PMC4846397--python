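"""Crosslink identification tables: ingest, filtering, site-pair collapse.

Consumes xQuest-style search results — one row per crosslinked
peptide-spectrum match (PSM) with its confidence metrics — applies the
identification filters used for the huntingtin DSS crosslink lists, and
collapses surviving PSMs to unique residue-level Lys–Lys pairs in Q23
reference numbering.

xQuest's own spectral scoring and FDR estimation are upstream of this
module; the score cut-off (default 17, corresponding to an estimated
FDR < 5% in the original search) stands in for the FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CrosslinkPSM",
    "FilterCriteria",
    "SitePair",
    "DEFAULT_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "apply_identification_filters",
    "collapse_to_site_pairs",
]

#: Canonical column layout for crosslink PSM tables. A ``dialect`` mapping
#: (canonical name -> actual header) adapts real xQuest exports.
DEFAULT_COLUMNS: tuple[str, ...] = (
    "allele",
    "spectrum_id",
    "score",
    "delta_score",
    "mass_error_ppm",
    "tic",
    "bond_cleavages",
    "len_a",
    "len_b",
    "site_a",
    "site_b",
    "protein",
)

_NUMERIC_COLUMNS = {
    "score": float,
    "delta_score": float,
    "mass_error_ppm": float,
    "tic": float,
    "bond_cleavages": int,
    "len_a": int,
    "len_b": int,
    "site_a": int,
    "site_b": int,
}


@dataclass(frozen=True)
class CrosslinkPSM:
    """One crosslinked peptide-spectrum identification.

    Residue positions are absolute, 1-based, in the Q23 reference
    numbering regardless of the allele's polyglutamine length; mapping
    peptide-level positions onto the protein is the producer's job.
    """

    allele_label: str
    spectrum_id: str
    score: float
    delta_score: float
    mass_error: float  # ppm
    tic_fraction: float  # percent of total ion current
    min_bond_cleavages: int  # per-peptide minimum for the pair
    peptide_len_a: int
    peptide_len_b: int
    site_a: int
    site_b: int
    target_protein: str = "huntingtin"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score in spectrum {self.spectrum_id!r}")
        if not math.isfinite(self.mass_error):
            raise ValueError(f"non-finite mass error in spectrum {self.spectrum_id!r}")
        if self.peptide_len_a < 1 or self.peptide_len_b < 1:
            raise ValueError("peptide lengths must be >= 1")
        if self.site_a < 1 or self.site_b < 1:
            raise ValueError("residue positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class FilterCriteria:
    """Identification filter thresholds for xQuest crosslink PSMs.

    Defaults are the criteria applied to the huntingtin DSS search
    results: mass error strictly below 4 ppm, peptides of at least 6
    residues, delta score below 0.9, %TIC of at least 0.1, at least 4
    bond cleavages per peptide, and an ld-score of at least 17.
    """

    max_mass_error_ppm: float = 4.0
    min_peptide_length: int = 6
    max_delta_score: float = 0.9
    min_tic: float = 0.1
    min_bond_cleavages: int = 4
    min_score: float = 17.0

    def __post_init__(self) -> None:
        for name in (
            "max_mass_error_ppm",
            "max_delta_score",
            "min_tic",
            "min_score",
        ):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")

    def passes(self, psm: CrosslinkPSM) -> bool:
        """True iff ``psm`` satisfies every criterion.

        Comparisons follow the printed criteria exactly: mass error is a
        strict upper bound; all other thresholds are inclusive.
        """
        return (
            abs(psm.mass_error) < self.max_mass_error_ppm
            and psm.peptide_len_a >= self.min_peptide_length
            and psm.peptide_len_b >= self.min_peptide_length
            and psm.delta_score < self.max_delta_score
            and psm.tic_fraction >= self.min_tic
            and psm.min_bond_cleavages >= self.min_bond_cleavages
            and psm.score >= self.min_score
        )


@dataclass(frozen=True)
class SitePair:
    """A unique unordered Lys–Lys contact at residue level, i < j.

    ``support`` counts the PSMs collapsed into the pair and is excluded
    from equality/hash so pairs compare on (i, j) identity, which is what
    the allelic subtraction operates on.
    """

    i: int
    j: int
    support: int = field(default=1, compare=False)

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"SitePair requires i < j, got ({self.i}, {self.j})")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def separation(self) -> int:
        """Sequence separation j − i in residues (Q23 numbering)."""
        return self.j - self.i


class ColumnError(KeyError):
    """A required column is missing from a PSM table."""


def _resolve_columns(
    df: pd.DataFrame, dialect: Mapping[str, str] | None
) -> pd.DataFrame:
    dialect = dict(dialect or {})
    rename = {dialect.get(canon, canon): canon for canon in DEFAULT_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in DEFAULT_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnError(
            f"PSM table is missing required column(s): {', '.join(missing)}"
        )
    return df


def read_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[CrosslinkPSM], pd.DataFrame]:
    """Read a TSV/CSV crosslink PSM table.

    Parameters
    ----------
    path
        Table with one row per crosslinked PSM.
    dialect
        Optional mapping from canonical column names
        (:data:`DEFAULT_COLUMNS`) to the headers actually present, so
        real xQuest exports can be adapted without rewriting files.
    sep
        Field separator; inferred from the extension by default
        (``.csv`` → comma, otherwise tab).

    Returns
    -------
    (psms, dropped)
        Parsed records and a DataFrame of rows with unparseable required
        fields, each annotated with a ``drop_reason`` column. Bad rows
        are reported, never silently discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = _resolve_columns(raw, dialect)

    psms: list[CrosslinkPSM] = []
    dropped_rows: list[dict] = []
    for _, row in raw.iterrows():
        try:
            values = {
                col: caster(float(row[col]) if caster is float else row[col])
                for col, caster in _NUMERIC_COLUMNS.items()
            }
            psms.append(
                CrosslinkPSM(
                    allele_label=str(row["allele"]),
                    spectrum_id=str(row["spectrum_id"]),
                    score=values["score"],
                    delta_score=values["delta_score"],
                    mass_error=values["mass_error_ppm"],
                    tic_fraction=values["tic"],
                    min_bond_cleavages=values["bond_cleavages"],
                    peptide_len_a=values["len_a"],
                    peptide_len_b=values["len_b"],
                    site_a=values["site_a"],
                    site_b=values["site_b"],
                    target_protein=str(row["protein"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rec = dict(row)
            rec["drop_reason"] = str(exc)
            dropped_rows.append(rec)
    dropped = pd.DataFrame(dropped_rows, columns=[*DEFAULT_COLUMNS, "drop_reason"])
    return psms, dropped


def write_psm_table(
    psms: Iterable[CrosslinkPSM], path: str | Path, sep: str = "\t"
) -> None:
    """Write PSMs in the canonical table layout (round-trips with
    :func:`read_psm_table`)."""
    rows = [
        {
            "allele": p.allele_label,
            "spectrum_id": p.spectrum_id,
            "score": p.score,
            "delta_score": p.delta_score,
            "mass_error_ppm": p.mass_error,
            "tic": p.tic_fraction,
            "bond_cleavages": p.min_bond_cleavages,
            "len_a": p.peptide_len_a,
            "len_b": p.peptide_len_b,
            "site_a": p.site_a,
            "site_b": p.site_b,
            "protein": p.target_protein,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=DEFAULT_COLUMNS).to_csv(path, sep=sep, index=False)


def apply_identification_filters(
    psms: Sequence[CrosslinkPSM], criteria: FilterCriteria | None = None
) -> list[CrosslinkPSM]:
    """Keep the PSMs that satisfy every identification criterion.

    Input order is preserved; an empty input yields an empty output.
    Filtering is idempotent and monotone in each threshold.
    """
    criteria = criteria or FilterCriteria()
    return [p for p in psms if criteria.passes(p)]


def collapse_to_site_pairs(
    psms: Sequence[CrosslinkPSM],
) -> tuple[list[SitePair], list[CrosslinkPSM]]:
    """Collapse PSMs to unique residue-level site pairs.

    Pairs are canonicalized to (min, max); duplicate observations merge
    with ``support`` incremented. Self-links (site_a == site_b), which
    carry no distance information, are excluded and returned separately
    rather than silently dropped.

    Raises
    ------
    ValueError
        If the PSMs carry more than one allele label — pairs from
        different alleles must be collapsed separately.
    """
    labels = {p.allele_label for p in psms}
    if len(labels) > 1:
        raise ValueError(
            f"mixed allele labels in input: {sorted(labels)}; collapse per allele"
        )
    support: dict[tuple[int, int], int] = {}
    self_links: list[CrosslinkPSM] = []
    for p in psms:
        if p.site_a == p.site_b:
            self_links.append(p)
            continue
        key = (min(p.site_a, p.site_b), max(p.site_a, p.site_b))
        support[key] = support.get(key, 0) + 1
    pairs = [SitePair(i, j, n) for (i, j), n in sorted(support.items())]
    return pairs, self_links
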