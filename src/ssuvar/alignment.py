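"""Aligned-sequence containers, region annotation, and per-column statistics.

The central object is :class:`MultipleAlignment`, a rectangular block of
nucleotide rows (IUPAC codes plus ``-`` for gaps) with unique taxon ids.
Everything downstream — coverage filtering, constant/variable classification,
gap bookkeeping, hypervariable-region lookup — operates on it.

Coordinates in all public I/O are 1-based inclusive alignment columns, the
convention used by region tables for SSU rRNA; internal numpy arrays are
0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC nucleotide codes mapped to their component states (N = fully ambiguous).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

VALID_CHARS = frozenset(IUPAC) | {GAP}

_STATES = "ACGT"

# 4-bit component-state mask per byte value; gap and N are 0 here because both are
# excluded from the constant/variable decision (N carries no state preference).
_STATE_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _comp in IUPAC.items():
    if _c == "N":
        continue
    _STATE_MASK_LUT[ord(_c)] = sum(1 << _STATES.index(s) for s in _comp)

CONSTANT, VARIABLE, INSUFFICIENT = "constant", "variable", "insufficient_coverage"


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, illegal characters, empty file)."""


def _normalize_row(row: str) -> str:
    return row.upper().replace("U", "T").replace(".", GAP)


class MultipleAlignment:
    """Equal-length nucleotide rows keyed by unique taxon ids.

    Rows are normalised to uppercase with U converted to T. Illegal characters
    raise :class:`AlignmentError` naming the offending taxon and column.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        ids: list[str] = []
        rows: list[str] = []
        for taxon, row in records:
            ids.append(str(taxon))
            rows.append(_normalize_row(str(row)))
        if not ids:
            raise AlignmentError("alignment contains no records")
        if len(set(ids)) != len(ids):
            dupes = sorted({t for t in ids if ids.count(t) > 1})
            raise AlignmentError(f"duplicate taxon ids: {dupes}")
        length = len(rows[0])
        for taxon, row in zip(ids, rows):
            if len(row) != length:
                raise AlignmentError(
                    f"row for taxon {taxon!r} has length {len(row)}, expected {length}"
                )
        bad: list[str] = []
        for taxon, row in zip(ids, rows):
            for col, ch in enumerate(row, start=1):
                if ch not in VALID_CHARS:
                    bad.append(f"{taxon!r} column {col}: {ch!r}")
        if bad:
            shown = "; ".join(bad[:10])
            more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
            raise AlignmentError(f"illegal characters: {shown}{more}")
        self.ids: list[str] = ids
        self.rows: list[str] = rows
        self.length: int = length
        self._chars: np.ndarray | None = None

    # -- basic container protocol -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ids

    def __len__(self) -> int:
        return self.n_taxa

    @property
    def chars(self) -> np.ndarray:
        """Byte matrix of shape (n_taxa, length), dtype uint8 (ASCII codes)."""
        if self._chars is None:
            self._chars = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_taxa, self.length)
        return self._chars

    def column(self, col: int) -> str:
        """Characters of 1-based column `col`, in taxon order."""
        return "".join(row[col - 1] for row in self.rows)


def read_aligned_fasta(path) -> MultipleAlignment:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return MultipleAlignment(records)


def write_aligned_fasta(aln: MultipleAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(recs, str(path), "fasta")


# -- group labels -----------------------------------------------------------------

class GroupAssignment:
    """Mapping taxon id -> clade label (e.g. Bdelloidea / Monogononta / ...)."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)

    def __getitem__(self, taxon: str) -> str:
        return self.mapping[taxon]

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.mapping.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> list[str]:
        return [t for t, lab in self.mapping.items() if lab == label]

    def validate_for(self, aln: MultipleAlignment) -> None:
        missing = [t for t in aln.ids if t not in self.mapping]
        if missing:
            raise ValueError(f"taxa without group label: {missing[:5]}")


def read_groups_tsv(path) -> GroupAssignment:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "clade"], comment="#")
    return GroupAssignment(dict(zip(df["taxon"].astype(str), df["clade"].astype(str))))


def write_groups_tsv(groups: GroupAssignment, path) -> None:
    pd.DataFrame(groups.mapping.items(), columns=["taxon", "clade"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# -- regions ----------------------------------------------------------------------

NON_HYPERVARIABLE = "non-hypervariable"


@dataclass(frozen=True)
class Region:
    name: str
    start: int   # 1-based inclusive
    length: int

    @property
    def end(self) -> int:
        """1-based inclusive end column."""
        return self.start + self.length - 1


class RegionSet:
    """Named, mutually non-overlapping column intervals (hypervariable regions)."""

    def __init__(self, regions: Iterable[Region | tuple[str, int, int]]):
        self.regions = [r if isinstance(r, Region) else Region(*r) for r in regions]
        for r in self.regions:
            if r.start < 1 or r.length < 1:
                raise ValueError(f"bad region {r}")
        spans = sorted((r.start, r.end, r.name) for r in self.regions)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1} and {n2} overlap")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def region_of(self, column: int) -> str:
        """Region name containing 1-based `column`, or the pooled non-hypervariable label."""
        for r in self.regions:
            if r.start <= column <= r.end:
                return r.name
        return NON_HYPERVARIABLE

    def labels(self, length: int) -> np.ndarray:
        """Object array of region names per column (length = alignment length)."""
        out = np.full(length, NON_HYPERVARIABLE, dtype=object)
        for r in self.regions:
            if r.end > length:
                raise ValueError(f"region {r.name} extends past alignment length {length}")
            out[r.start - 1 : r.end] = r.name
        return out

    def remap(self, column_map: Mapping[int, int]) -> "RegionSet":
        """Project regions through an old->new 1-based column map (after compaction).

        A region's new interval spans the surviving columns; regions losing all
        columns are dropped.
        """
        new_regions = []
        for r in self.regions:
            cols = [column_map[c] for c in range(r.start, r.end + 1) if c in column_map]
            if cols:
                new_regions.append(Region(r.name, min(cols), max(cols) - min(cols) + 1))
        return RegionSet(new_regions)


def region_of(regions: RegionSet, column: int) -> str:
    return regions.region_of(column)


def read_regions_tsv(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    return RegionSet(
        Region(str(row["name"]), int(row["start"]), int(row["length"]))
        for _, row in df.iterrows()
    )


def write_regions_tsv(regions: RegionSet, path) -> None:
    pd.DataFrame(
        [(r.name, r.start, r.length) for r in regions],
        columns=["name", "start", "length"],
    ).to_csv(path, sep="\t", index=False)


def rotifera_v_regions() -> RegionSet:
    """The V1-V9 interval table for the aligned rotifer data set (printed coordinates)."""
    import importlib.resources as resources

    ref = resources.files("ssuvar").joinpath("data/rotifera_v_regions.tsv")
    with resources.as_file(ref) as p:
        return read_regions_tsv(p)


# -- subsetting -------------------------------------------------------------------

def subset_and_compact(
    aln: MultipleAlignment, keep: Iterable[str]
) -> tuple[MultipleAlignment, dict[int, int]]:
    """Restrict to `keep` taxa and drop columns that are gap-only afterwards.

    Returns the compacted alignment and a 1-based old->new column map covering
    exactly the surviving columns.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep set is empty")
    unknown = keep_set - set(aln.ids)
    if unknown:
        raise ValueError(f"taxa not in alignment: {sorted(unknown)[:5]}")
    idx = [i for i, t in enumerate(aln.ids) if t in keep_set]
    sub = aln.chars[idx]
    keep_cols = np.flatnonzero((sub != ord(GAP)).any(axis=0))
    column_map = {int(old) + 1: new + 1 for new, old in enumerate(keep_cols)}
    records = [
        (aln.ids[i], sub[k][keep_cols].tobytes().decode("ascii"))
        for k, i in enumerate(idx)
    ]
    return MultipleAlignment(records), column_map


# -- terminal gaps & gap statistics ------------------------------------------------

@dataclass
class TerminalGapMask:
    """Maximal leading/trailing gap spans per row (incomplete-sequence proxy)."""

    leading: np.ndarray   # int per taxon
    trailing: np.ndarray
    all_gap: np.ndarray   # bool per taxon (degenerate all-gap rows)
    ids: list[str] = field(default_factory=list)

    def is_terminal(self, taxon_index: int, col0: int, length: int) -> bool:
        """True if 0-based column `col0` lies in the taxon's terminal span."""
        return bool(
            col0 < self.leading[taxon_index]
            or col0 >= length - self.trailing[taxon_index]
        )

    def mask_matrix(self, length: int) -> np.ndarray:
        """Boolean (n_taxa, length) matrix of terminal-gap cells."""
        cols = np.arange(length)
        return (cols[None, :] < self.leading[:, None]) | (
            cols[None, :] >= length - self.trailing[:, None]
        )

    @property
    def terminal_cells(self) -> int:
        return int(self.leading.sum() + self.trailing.sum())


def terminal_gap_mask(aln: MultipleAlignment) -> TerminalGapMask:
    gap = aln.chars == ord(GAP)
    n, L = gap.shape
    leading = np.zeros(n, dtype=int)
    trailing = np.zeros(n, dtype=int)
    all_gap = gap.all(axis=1)
    for i in range(n):
        if all_gap[i]:
            leading[i], trailing[i] = L, 0  # whole row masked once, not twice
            continue
        nz = np.flatnonzero(~gap[i])
        leading[i] = nz[0]
        trailing[i] = L - 1 - nz[-1]
    return TerminalGapMask(leading, trailing, all_gap, list(aln.ids))


@dataclass
class GapStatistics:
    aligned_length: int
    n_taxa: int
    total_cells: int
    terminal_gap_cells: int
    assessed_cells: int
    internal_gap_cells: int
    pct_gaps: float | None  # None when no cell is assessed

    def as_dict(self) -> dict:
        return {
            "aligned_length": self.aligned_length,
            "internal_gap_cells": self.internal_gap_cells,
            "assessed_cells": self.assessed_cells,
            "pct_gaps": self.pct_gaps,
        }


def gap_statistics(
    aln: MultipleAlignment, mask: TerminalGapMask | None = None
) -> GapStatistics:
    """Internal-gap fraction with terminal gaps removed from the denominator.

    ``pct = internal '-' cells / (total cells - terminal-gap cells)``. N is
    treated as sequence data, not as a gap.
    """
    if mask is None:
        mask = terminal_gap_mask(aln)
    gap = aln.chars == ord(GAP)
    total = aln.n_taxa * aln.length
    terminal = mask.terminal_cells
    assessed = total - terminal
    internal = int(gap.sum()) - terminal
    pct = None if assessed == 0 else internal / assessed
    return GapStatistics(aln.length, aln.n_taxa, total, terminal, assessed, internal, pct)


# -- coverage & constant/variable classification -----------------------------------

def site_coverage(aln: MultipleAlignment) -> np.ndarray:
    """Per-column fraction of taxa with an informative character (not '-', not N)."""
    chars = aln.chars
    informative = (chars != ord(GAP)) & (chars != ord("N"))
    return informative.mean(axis=0)


@dataclass
class SiteClassification:
    classes: np.ndarray       # object array of CONSTANT/VARIABLE/INSUFFICIENT
    coverage: np.ndarray
    threshold: float

    @property
    def passing(self) -> np.ndarray:
        return self.classes != INSUFFICIENT

    @property
    def n_constant(self) -> int:
        return int((self.classes == CONSTANT).sum())

    @property
    def n_variable(self) -> int:
        return int((self.classes == VARIABLE).sum())

    @property
    def n_insufficient(self) -> int:
        return int((self.classes == INSUFFICIENT).sum())


def classify_sites(aln: MultipleAlignment, threshold: float = 0.15) -> SiteClassification:
    """Constant / variable / insufficient-coverage call per column.

    A column is constant when some single nucleotide state is compatible with
    every informative character there (ambiguity codes are compatible with each
    of their component states; gaps and N are excluded). Columns whose coverage
    falls below `threshold` are flagged insufficient instead.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    chars = aln.chars
    masks = _STATE_MASK_LUT[chars]              # 0 for gap and N
    informative = masks != 0
    # AND-reduce component masks over informative taxa; neutral element 0b1111.
    masks_or_neutral = np.where(informative, masks, np.uint8(0b1111))
    common = np.bitwise_and.reduce(masks_or_neutral, axis=0)
    has_info = informative.any(axis=0)
    constant = (common != 0) & has_info
    coverage = site_coverage(aln)
    classes = np.where(constant, CONSTANT, VARIABLE).astype(object)
    classes[coverage < threshold] = INSUFFICIENT
    return SiteClassification(classes, coverage, threshold)


def constant_variable_counts(
    classif: SiteClassification, regions: RegionSet
) -> pd.DataFrame:
    """Constant/variable counts partitioned into hypervariable vs pooled non-hypervariable.

    Insufficient-coverage columns are excluded, so the 'all' row totals the
    passing columns only.
    """
    labels = regions.labels(len(classif.classes))
    hyper = labels != NON_HYPERVARIABLE
    rows = []
    for name, sel in (
        (NON_HYPERVARIABLE, ~hyper),
        ("hypervariable", hyper),
        ("all", np.ones_like(hyper)),
    ):
        cls = classif.classes[sel]
        rows.append(
            {
                "region": name,
                "total": int((cls != INSUFFICIENT).sum()),
                "constant": int((cls == CONSTANT).sum()),
                "variable": int((cls == VARIABLE).sum()),
            }
        )
    return pd.DataFrame(rows)
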