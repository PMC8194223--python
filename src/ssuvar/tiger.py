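"""TIGER site-specific relative rates from site-pattern congruence.

At each alignment column the taxa are partitioned into groups by character
state (an ambiguity code places its taxon in every component state's group;
terminal gaps and N carry no information and are excluded). The agreement
pa(i, j) between two columns is the fraction of column j's groups that nest
inside some group of column i after restriction to column i's scored taxa;
groups whose restriction is empty count in neither numerator nor denominator.
A column's relative rate is the mean of pa(i, j) over all other columns that
pass the coverage threshold. Constant columns score exactly 1 (slow); low
values indicate site patterns incongruent with the rest of the alignment
(fast). No tree is involved, which is the point: the rate is relative and
assumption-free.

Taxon groups are packed into 64-bit words so the quadratic column loop runs as
vectorised bit operations; alignments of ~2000 columns x 200 taxa finish in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .alignment import (
    CONSTANT,
    GAP,
    INSUFFICIENT,
    IUPAC,
    MultipleAlignment,
    SiteClassification,
    classify_sites,
    terminal_gap_mask,
)

_STATES = "ACGT"
GapMode = Literal["missing", "state"]


@dataclass(frozen=True)
class SitePartition:
    """Taxon groups by state at one column (taxa as integer indices)."""

    column: int                       # 1-based
    scored_taxa: frozenset[int]
    state_sets: tuple[frozenset[int], ...]

    def __post_init__(self):
        union: set[int] = set()
        for s in self.state_sets:
            if not s:
                raise ValueError("empty state set")
            union |= s
        if union != set(self.scored_taxa):
            raise ValueError("state sets must cover exactly the scored taxa")


def site_partition(
    aln: MultipleAlignment,
    column: int,
    gap_mode: GapMode = "missing",
    mask=None,
) -> SitePartition:
    """Partition of taxa by state at 1-based `column`.

    Terminal gaps and N never contribute. Internal gaps are missing data by
    default; ``gap_mode="state"`` instead treats them as a fifth shared state
    (sensitivity analysis).
    """
    if not 1 <= column <= aln.length:
        raise ValueError(f"column {column} outside alignment")
    if mask is None:
        mask = terminal_gap_mask(aln)
    sets: dict[str, set[int]] = {}
    scored: set[int] = set()
    for t in range(aln.n_taxa):
        ch = aln.rows[t][column - 1]
        if ch == "N":
            continue
        if ch == GAP:
            if gap_mode == "missing" or mask.is_terminal(t, column - 1, aln.length):
                continue
            scored.add(t)
            sets.setdefault(GAP, set()).add(t)
            continue
        scored.add(t)
        for s in IUPAC[ch]:
            sets.setdefault(s, set()).add(t)
    return SitePartition(
        column,
        frozenset(scored),
        tuple(frozenset(v) for _, v in sorted(sets.items())),
    )


def partition_agreement(p_i: SitePartition, p_j: SitePartition) -> float:
    """pa(i, j): fraction of j's groups nesting in some group of i (NaN if no
    group of j survives restriction to i's scored taxa)."""
    num = den = 0
    for a in p_j.state_sets:
        restricted = a & p_i.scored_taxa
        if not restricted:
            continue
        den += 1
        if any(restricted <= s for s in p_i.state_sets):
            num += 1
    if den == 0:
        return float("nan")
    return num / den


@dataclass
class SiteRateTable:
    """Per-column TIGER rate with coverage and constant/variable class."""

    rates: np.ndarray            # float, NaN where insufficient coverage
    classification: SiteClassification
    threshold: float

    @property
    def length(self) -> int:
        return len(self.rates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.length + 1),
                "coverage": self.classification.coverage,
                "class": self.classification.classes,
                "rate": self.rates,
            }
        )

    def write_tsv(self, path, rolling_window: int | None = None) -> None:
        df = self.to_frame()
        if rolling_window:
            df["rolling_mean"] = rolling_average(self.rates, rolling_window)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _pack_state_masks(
    aln: MultipleAlignment, gap_mode: GapMode
) -> tuple[np.ndarray, np.ndarray]:
    """Bit-packed taxon sets per (column, state): returns (S, T) with
    S shape (L, n_states, W) uint64 and T = union over states, shape (L, W)."""
    n, L = aln.n_taxa, aln.length
    W = (n + 63) // 64
    mask = terminal_gap_mask(aln)
    chars = aln.chars
    state_list = list(_STATES) + ([GAP] if gap_mode == "state" else [])
    members = np.zeros((len(state_list), n, L), dtype=bool)
    for k, s in enumerate(state_list):
        if s == GAP:
            members[k] = (chars == ord(GAP)) & ~mask.mask_matrix(L)
        else:
            codes = [c for c, comp in IUPAC.items() if s in comp and c != "N"]
            for c in codes:
                members[k] |= chars == ord(c)
    S = np.zeros((L, len(state_list), W), dtype=np.uint64)
    for w in range(W):
        block = members[:, w * 64 : (w + 1) * 64, :]
        for bit in range(block.shape[1]):
            S[:, :, w] |= (block[:, bit, :].T.astype(np.uint64)) << np.uint64(bit)
    T = np.bitwise_or.reduce(S, axis=1)
    return S, T


def tiger_rates(
    aln: MultipleAlignment,
    threshold: float = 0.15,
    gap_mode: GapMode = "missing",
) -> SiteRateTable:
    """TIGER relative rate per column; columns below the coverage threshold are
    flagged and excluded from both roles (focal and comparison)."""
    classif = classify_sites(aln, threshold)
    passing = np.flatnonzero(classif.passing)
    if len(passing) < 2:
        raise ValueError("need at least two columns passing the coverage threshold")
    S, T = _pack_state_masks(aln, gap_mode)
    L = aln.length
    n_states = S.shape[1]
    sum_pa = np.zeros(L)
    cnt = np.zeros(L, dtype=np.int64)
    Tp = T[passing]                     # (P, W)
    Sp = S[passing]                     # (P, n_states, W)
    notSp = ~Sp
    for j in passing:
        num = np.zeros(len(passing))
        den = np.zeros(len(passing))
        for k in range(n_states):
            A = S[j, k]
            if not A.any():
                continue
            R = Tp & A[None, :]                        # (P, W)
            nonempty = (R != 0).any(axis=1)
            sub = np.zeros(len(passing), dtype=bool)
            for s in range(n_states):
                sub |= ((R & notSp[:, s, :]) == 0).all(axis=1)
            num += nonempty & sub
            den += nonempty
        defined = den > 0
        pa = np.zeros(len(passing))
        pa[defined] = num[defined] / den[defined]
        sum_pa[passing[defined]] += pa[defined]
        cnt[passing[defined]] += 1
    # remove each column's self term pa(j, j) = 1
    sum_pa[passing] -= 1.0
    cnt[passing] -= 1
    rates = np.full(L, np.nan)
    ok = np.zeros(L, dtype=bool)
    ok[passing] = True
    ok &= cnt > 0
    rates[ok] = sum_pa[ok] / cnt[ok]
    return SiteRateTable(rates, classif, threshold)


@dataclass
class RateSummary:
    mean: float
    se: float
    n: int


def summarize_rates(
    table: SiteRateTable, subset: Literal["all", "variable_only"] = "all"
) -> RateSummary:
    """Mean +/- SE of rates over rated columns, optionally variable columns only."""
    sel = np.isfinite(table.rates)
    if subset == "variable_only":
        sel &= table.classification.classes == "variable"
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    vals = table.rates[sel]
    n = len(vals)
    if n == 0:
        return RateSummary(float("nan"), float("nan"), 0)
    se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return RateSummary(float(vals.mean()), se, n)


def rolling_average(rates: np.ndarray, window: int = 35) -> np.ndarray:
    """Centred rolling mean of defined rates; the window truncates at the series
    ends and skips undefined (insufficient-coverage) positions."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return (
        pd.Series(np.asarray(rates, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def rate_histogram(table: SiteRateTable, bin_width: float = 0.05) -> pd.DataFrame:
    """Binned rate counts plus an insufficient-coverage bin.

    Bins are left-closed, right-open ([k*w, (k+1)*w)), so a rate of exactly 1.0
    falls in the bin starting at 1.0. Counts over all bins plus the n/a bin sum
    to the alignment length.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    finite = table.rates[np.isfinite(table.rates)]
    idx = np.floor(finite / bin_width).astype(int)
    n_bins = int(np.floor(1.0 / bin_width)) + 1
    counts = np.bincount(idx, minlength=n_bins)
    rows = [
        {"bin_start": k * bin_width, "bin_end": (k + 1) * bin_width, "count": int(c)}
        for k, c in enumerate(counts)
    ]
    rows.append(
        {"bin_start": float("nan"), "bin_end": float("nan"),
         "count": int(np.isnan(table.rates).sum())}
    )
    return pd.DataFrame(rows)
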