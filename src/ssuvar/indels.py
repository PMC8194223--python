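"""Indel-run statistics per region and detection of windowed deletion motifs.

An indel here is a maximal run of gap columns in one taxon's row of the group
alignment. Runs crossing a hypervariable-region boundary are split at the
boundary so that, per region, nucleotides + gapped columns always equal the
region length. Terminal gap runs (incomplete sequences, not real indels) can
be excluded for the pooled non-hypervariable region only (the default,
matching how such summaries are usually corrected), everywhere, or nowhere.

Deletion motifs are defined inside a fixed alignment window (for the rotifer
data: the last 14 columns of V3 plus the 78 columns beyond it, 92 in total).
Each taxon's motif class is the exact set of gap spans it expresses inside the
window, so equal-length deletions at different positions are distinct classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .alignment import (
    GAP,
    NON_HYPERVARIABLE,
    GroupAssignment,
    MultipleAlignment,
    RegionSet,
    terminal_gap_mask,
)

TerminalPolicy = Literal["non_hypervariable", "all", "none"]


@dataclass(frozen=True)
class IndelRecord:
    taxon_id: str
    region: str
    start: int      # 1-based alignment column
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal '-' runs as (1-based start, length)."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i - start))
            start = None
    if start is not None:
        runs.append((start + 1, len(row) - start))
    return runs


def _split_at_regions(
    start: int, length: int, regions: RegionSet
) -> list[tuple[str, int, int]]:
    """Split a run at region boundaries -> [(region name, start, length)]."""
    bounds = sorted(
        {start, start + length}
        | {r.start for r in regions if start < r.start < start + length}
        | {r.end + 1 for r in regions if start < r.end + 1 < start + length}
    )
    out = []
    for a, b in zip(bounds, bounds[1:]):
        out.append((regions.region_of(a), a, b - a))
    return out


def indel_runs(
    aln: MultipleAlignment,
    taxon: str,
    regions: RegionSet,
    terminal_policy: TerminalPolicy = "non_hypervariable",
) -> list[IndelRecord]:
    """Maximal gap runs of one taxon, split at region boundaries.

    ``terminal_policy`` controls which sub-runs overlapping the taxon's
    terminal-gap span are dropped: those falling in the pooled
    non-hypervariable region (default), all of them, or none.
    """
    if taxon not in aln:
        raise ValueError(f"taxon {taxon!r} not in alignment")
    t = aln.ids.index(taxon)
    mask = terminal_gap_mask(aln)
    lead, trail = int(mask.leading[t]), int(mask.trailing[t])
    records = []
    for start, length in gap_runs(aln.rows[t]):
        for name, s, ln in _split_at_regions(start, length, regions):
            terminal = s <= lead or (s + ln - 1) > aln.length - trail
            if terminal and (
                terminal_policy == "all"
                or (terminal_policy == "non_hypervariable" and name == NON_HYPERVARIABLE)
            ):
                continue
            records.append(IndelRecord(taxon, name, s, ln))
    return records


def region_indel_summary(
    aln: MultipleAlignment,
    taxon: str,
    regions: RegionSet,
    terminal_policy: TerminalPolicy = "non_hypervariable",
) -> pd.DataFrame:
    """Per-region nucleotide count, indel count and mean indel length for one taxon.

    Rows cover each named region plus the pooled non-hypervariable remainder;
    ``mean_indel_length`` is NaN when there is no indel (reported n/a).
    """
    runs = indel_runs(aln, taxon, regions, terminal_policy)
    row = aln.row(taxon)
    labels = regions.labels(aln.length)
    names = regions.names() + [NON_HYPERVARIABLE]
    rows = []
    for name in names:
        cols = np.flatnonzero(labels == name)
        nt = sum(1 for c in cols if row[c] != GAP)
        lens = [r.length for r in runs if r.region == name]
        rows.append(
            {
                "region": name,
                "region_length": len(cols),
                "nucleotides": nt,
                "n_indels": len(lens),
                "mean_indel_length": float(np.mean(lens)) if lens else float("nan"),
                "gap_columns": int(sum(lens)),
            }
        )
    return pd.DataFrame(rows)


# -- windowed deletion motifs ------------------------------------------------------

@dataclass(frozen=True)
class DeletionMotif:
    taxon_id: str
    spans: tuple[tuple[int, int], ...]   # (start, length) clipped to the window
    expressed_length: int                # gapped columns inside the window
    motif_class: str


def deletion_window_from_regions(
    regions: RegionSet, region_name: str = "V3", tail: int = 14, extension: int = 78
) -> tuple[int, int]:
    """Window covering the last `tail` columns of a region plus `extension`
    following columns (default 14 + 78 = 92)."""
    r = regions.get(region_name)
    return (r.end - tail + 1, tail + extension)


def detect_deletion(
    aln: MultipleAlignment,
    window: tuple[int, int],
    groups: GroupAssignment | None = None,
    restrict_to: str | None = None,
) -> list[DeletionMotif]:
    """Gap-span motifs inside `window` = (1-based start, length) per taxon.

    Class labels are assigned deterministically: 'absent' for no gap in the
    window, then 'motif_01', 'motif_02', ... ordered by (expressed length,
    span coordinates). Identical span sets share a class. With `restrict_to`,
    only taxa of that group label are examined (and the result is unaffected
    by any other taxon).
    """
    start, length = window
    if start < 1 or start + length - 1 > aln.length:
        raise ValueError(f"window {window} outside alignment of length {aln.length}")
    end = start + length - 1
    taxa = aln.ids
    if restrict_to is not None:
        if groups is None:
            raise ValueError("restrict_to requires a group assignment")
        taxa = [t for t in taxa if groups[t] == restrict_to]
    per_taxon: dict[str, tuple[tuple[int, int], ...]] = {}
    for taxon in taxa:
        spans = []
        for s, ln in gap_runs(aln.row(taxon)):
            e = s + ln - 1
            if e < start or s > end:
                continue
            cs, ce = max(s, start), min(e, end)
            spans.append((cs, ce - cs + 1))
        per_taxon[taxon] = tuple(spans)
    distinct = sorted(
        {sp for sp in per_taxon.values() if sp},
        key=lambda sp: (sum(l for _, l in sp), sp),
    )
    label_of = {(): "absent"}
    for k, sp in enumerate(distinct, start=1):
        label_of[sp] = f"motif_{k:02d}"
    return [
        DeletionMotif(taxon, sp, sum(l for _, l in sp), label_of[sp])
        for taxon, sp in per_taxon.items()
    ]


def deletion_report(motifs: Iterable[DeletionMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": m.taxon_id,
                "class": m.motif_class,
                "expressed_length": m.expressed_length,
                "spans": ";".join(f"{s}+{l}" for s, l in m.spans) or ".",
            }
            for m in motifs
        ]
    )
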