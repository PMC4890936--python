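"""Cross-kinase PTM mapping via multiple sequence alignment.

A PTM observed on any kinase is transferred to a reference kinase (PKA or
ZAP-70) through the shared column of a user-supplied multiple sequence
alignment; a site whose column has a gap in the reference is omitted from
the mapping.  The same alignment drives the conservation statistics: a
residue is "conserved" when the same amino acid occupies its column in more
than a threshold number of kinases (default 40, against a kinome alignment
of ~832 sequences), and a modification position is "conserved" when more
than 5 distinct kinases are modified at its reference column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

GAP_CHARS = set("-.")

#: default conservation thresholds (strict 'greater than')
RESIDUE_CONSERVATION_THRESHOLD = 40
MODIFICATION_CONSERVATION_THRESHOLD = 5


class MultipleAlignment:
    """Gapped sequences with residue <-> column maps for each entry.

    Residue positions are 1-based; columns are 0-based internally.
    """

    def __init__(self, entries: list[tuple[str, str]]):
        if not entries:
            raise ValueError("alignment has no entries")
        width = len(entries[0][1])
        for name, seq in entries:
            if len(seq) != width:
                raise ValueError(f"entry {name!r} has length {len(seq)}, "
                                 f"expected {width}")
        self.entries = [(name, seq.upper()) for name, seq in entries]
        self.names = [name for name, _ in self.entries]
        self.width = width
        self._by_name = dict(self.entries)
        # residue (1-based) -> column, strictly increasing, and its inverse
        self._res2col: dict[str, list[int]] = {}
        self._col2res: dict[str, dict[int, int]] = {}
        for name, seq in self.entries:
            cols = [c for c, aa in enumerate(seq) if aa not in GAP_CHARS]
            self._res2col[name] = cols
            self._col2res[name] = {c: i + 1 for i, c in enumerate(cols)}

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "MultipleAlignment":
        """Read an aligned FASTA or Clustal file."""
        aln = AlignIO.read(path, fmt)
        return cls([(rec.id, str(rec.seq)) for rec in aln])

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, name: str) -> str:
        """Ungapped sequence of one entry."""
        return "".join(aa for aa in self._by_name[name] if aa not in GAP_CHARS)

    def column_of(self, name: str, residue_index: int) -> int:
        """Alignment column (0-based) holding this entry's residue (1-based)."""
        if name not in self._by_name:
            raise KeyError(f"entry {name!r} not in alignment")
        cols = self._res2col[name]
        if not 1 <= residue_index <= len(cols):
            raise IndexError(f"residue {residue_index} outside {name!r} "
                             f"(length {len(cols)})")
        return cols[residue_index - 1]

    def residue_at(self, name: str, column: int) -> int | None:
        """1-based residue of ``name`` at a column, or None for a gap."""
        if name not in self._by_name:
            raise KeyError(f"entry {name!r} not in alignment")
        return self._col2res[name].get(column)


def map_site_to_reference(aln: MultipleAlignment, reference: str,
                          protein: str, residue_index: int) -> int | None:
    """Reference residue occupying the same column, or None if the reference
    has a gap there (the site is then omitted from reference-mapped
    statistics).  A protein absent from the alignment is an error, distinct
    from an absent mapping."""
    col = aln.column_of(protein, residue_index)
    return aln.residue_at(reference, col)


@dataclass
class ReferenceMap:
    """Per-site mapping onto one reference kinase's numbering."""

    reference_name: str
    mapping: dict[tuple[str, int], int | None]

    def mapped(self) -> dict[tuple[str, int], int]:
        return {k: v for k, v in self.mapping.items() if v is not None}

    def to_frame(self) -> pd.DataFrame:
        rows = [(acc, res, ref) for (acc, res), ref in sorted(self.mapping.items())]
        return pd.DataFrame(rows, columns=["protein_accession", "residue_index",
                                           f"{self.reference_name}_residue"])


def build_reference_map(aln: MultipleAlignment, reference: str,
                        sites) -> ReferenceMap:
    """Map every (protein, residue) site onto the reference numbering."""
    mapping: dict[tuple[str, int], int | None] = {}
    for s in sites:
        key = (s.protein_accession, s.residue_index)
        mapping[key] = map_site_to_reference(aln, reference,
                                             s.protein_accession,
                                             s.residue_index)
    return ReferenceMap(reference, mapping)


def residue_conservation(aln: MultipleAlignment, column: int,
                         amino_acid: str = "K",
                         threshold: int = RESIDUE_CONSERVATION_THRESHOLD,
                         ) -> tuple[int, bool]:
    """Count of entries with ``amino_acid`` at a column; conserved iff
    strictly more than ``threshold``."""
    if not 0 <= column < aln.width:
        raise IndexError(f"column {column} outside alignment width {aln.width}")
    count = sum(1 for _, seq in aln.entries if seq[column] == amino_acid.upper())
    return count, count > threshold


def conservation_flags(aln: MultipleAlignment, sites, amino_acid: str = "K",
                       threshold: int = RESIDUE_CONSERVATION_THRESHOLD,
                       ) -> dict[tuple[str, int], bool]:
    """Per-site conserved-residue flags for joining into site summaries."""
    flags = {}
    col_cache: dict[int, bool] = {}
    for s in sites:
        col = aln.column_of(s.protein_accession, s.residue_index)
        if col not in col_cache:
            _, col_cache[col] = residue_conservation(aln, col, amino_acid,
                                                     threshold)
        flags[(s.protein_accession, s.residue_index)] = col_cache[col]
    return flags


def modification_conservation(aln: MultipleAlignment, sites,
                              threshold: int = MODIFICATION_CONSERVATION_THRESHOLD,
                              ):
    """Per-column distinct-kinase modification counts and conserved flags.

    Multiple sites from one protein landing on one column count once.
    Returns ``(per_column, per_site_flags)`` where ``per_column`` maps an
    alignment column to ``(count, conserved)`` and ``per_site_flags`` maps
    each (protein, residue) to its column's flag.
    """
    kinases_per_column: dict[int, set[str]] = {}
    site_columns: dict[tuple[str, int], int] = {}
    for s in sites:
        col = aln.column_of(s.protein_accession, s.residue_index)
        kinases_per_column.setdefault(col, set()).add(s.protein_accession)
        site_columns[(s.protein_accession, s.residue_index)] = col
    per_column = {col: (len(ks), len(ks) > threshold)
                  for col, ks in kinases_per_column.items()}
    per_site = {key: per_column[col][1] for key, col in site_columns.items()}
    return per_column, per_site


@dataclass
class DensityProfile:
    """Normalized site frequency per reference kinase-domain position."""

    category: str
    positions: list[int]
    frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size and not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("density profile must sum to 1 over the domain")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions,
                             "frequency": self.frequencies,
                             "category": self.category})


def density_profile(reference_map: ReferenceMap, category: str,
                    kinase_domain_range: tuple[int, int],
                    site_filter=None) -> DensityProfile:
    """Per-position site frequency on the reference, normalized over the
    kinase domain.  Each mapped site counts individually (density reflects
    site counts, not distinct kinases).  Zero mapped sites yield an empty
    profile."""
    lo, hi = kinase_domain_range
    items = reference_map.mapped().items()
    if site_filter is not None:
        items = [(k, v) for k, v in items if site_filter(k)]
    counts: dict[int, int] = {}
    for _, ref_pos in items:
        if lo <= ref_pos <= hi:
            counts[ref_pos] = counts.get(ref_pos, 0) + 1
    if not counts:
        return DensityProfile(category, [], np.array([]))
    total = sum(counts.values())
    positions = sorted(counts)
    freqs = np.array([counts[p] / total for p in positions])
    return DensityProfile(category, positions, freqs)


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.entries:
            fh.write(f">{name}\n{seq}\n")
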