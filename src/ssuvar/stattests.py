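"""Nonparametric test battery for site-rate comparisons.

All tests use midranks for ties, tie-corrected normal or chi-square
approximations, and two-sided p-values; no multiple-testing correction is
applied (each test is read at a nominal alpha of 0.05). Conventions:

* Wilcoxon signed rank: zero differences are dropped (the non-zero count is
  reported next to the total), W is the sum of positive-difference ranks, and
  Z = (W - n(n+1)/4) / sigma with the tie term n(n+1)(2n+1)/24 - sum(t^3-t)/48.
* Mann-Whitney: U is reported as min(U1, U2); Z uses the tie-corrected
  variance n1 n2 ((N+1) - sum(t^3-t)/(N(N-1))) / 12, no continuity correction.
* Kruskal-Wallis: tie-corrected H with a chi-square approximation on k-1 df
  (delegated to scipy).
* 2x2 chi-square: Pearson statistic without continuity correction.

Exact p-values from full enumeration are available below a sample-size cutoff
for the rank tests (``exact=True``).

To avoid pseudoreplication when comparing stems against loops, each
base-paired position pair enters once, represented by the mean of its two
rates (:func:`collapse_paired`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import INSUFFICIENT, NON_HYPERVARIABLE, RegionSet
from .tiger import SiteRateTable

EXACT_N = 25


@dataclass
class TestResult:
    test: str
    statistic: float
    z: float | None = None
    df: int | None = None
    p: float | None = None
    n: tuple = ()
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "z": self.z,
            "df": self.df,
            "p": self.p,
            "n": "/".join(str(x) for x in self.n),
            "note": self.note,
        }


# -- pseudoreplication-aware stem/loop sets ----------------------------------------

@dataclass
class PairedRateSet:
    """Rates split by structural role, with each base pair collapsed to one value."""

    pair_rates: list[tuple[float, float]]   # (r_i, r_j) for rated pairs
    stems: np.ndarray                       # collapsed (mean) rate per pair
    loops: np.ndarray                       # rates of definite unpaired positions


def collapse_paired(table: SiteRateTable, partner: np.ndarray) -> PairedRateSet:
    """Build stem/loop rate sets from a per-column partner array.

    `partner` holds, per alignment column (0-based), the 0-based partner
    column, -1 for a definitely-unpaired position and -2 for positions with no
    structural assignment (e.g. gaps in the exemplar carrying the map). Pairs
    with either member unrated are excluded; loops exclude unrated positions.
    """
    if len(partner) != table.length:
        raise ValueError("partner array length != rate table length")
    rates = table.rates
    pair_rates = []
    for i in np.flatnonzero(partner >= 0):
        j = partner[i]
        if i < j:
            if np.isfinite(rates[i]) and np.isfinite(rates[j]):
                pair_rates.append((float(rates[i]), float(rates[j])))
    loop_idx = np.flatnonzero(partner == -1)
    loops = rates[loop_idx]
    loops = loops[np.isfinite(loops)]
    stems = np.array([(a + b) / 2 for a, b in pair_rates])
    return PairedRateSet(pair_rates, stems, loops)


# -- individual tests --------------------------------------------------------------

def wilcoxon_signed_rank(x, y, exact: bool | None = None) -> TestResult:
    """Paired-sample signed-rank test; W = sum of positive-difference ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    total = len(d)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon_signed_rank", float("nan"), n=(0, total),
                          note="all differences zero; no test")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    z = (w - mean) / np.sqrt(var) if var > 0 else 0.0
    if exact is None:
        exact = n < EXACT_N
    if exact:
        p = _wilcoxon_exact_p(d, w)
        note = "exact (sign-flip enumeration)"
    else:
        p = 2 * stats.norm.sf(abs(z))
        note = "normal approximation, tie-corrected, no continuity correction"
    return TestResult("wilcoxon_signed_rank", w, z=float(z), p=float(p),
                      n=(n, total), note=note)


def _wilcoxon_exact_p(d: np.ndarray, w_obs: float) -> float:
    """Two-sided p from the full 2^n sign-flip distribution of W."""
    ranks = stats.rankdata(np.abs(d))
    n = len(ranks)
    mean = n * (n + 1) / 4
    dev = abs(w_obs - mean)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= dev - 1e-12:
            count += 1
    return count / 2**n


def mann_whitney_u(a, b, exact: bool | None = None) -> TestResult:
    """Two-sample rank-sum test; U reported as min(U1, U2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mean = n1 * n2 / 2
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 * ((N + 1) - tie) / 12
    z = (u1 - mean) / np.sqrt(var) if var > 0 else 0.0
    if exact is None:
        exact = N < EXACT_N
    if exact:
        p = _mann_whitney_exact_p(pooled, n1, u1)
        note = "exact (label enumeration)"
    else:
        p = 2 * stats.norm.sf(abs(z))
        note = "normal approximation, tie-corrected, no continuity correction"
    return TestResult("mann_whitney_u", float(u), z=float(z), p=float(p),
                      n=(n1, n2), note=note)


def _mann_whitney_exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided p from all C(N, n1) group labellings of the pooled values."""
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean = n1 * (N - n1) / 2
    dev = abs(u_obs - mean)
    count = total = 0
    for comb in itertools.combinations(range(N), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean) >= dev - 1e-12:
            count += 1
    return count / total


def kruskal_wallis(groups) -> TestResult:
    """k-sample rank test with tie-corrected H and chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ns = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, df=len(groups) - 1, p=1.0, n=ns,
                          note="all observations identical")
    h, p = stats.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), df=len(groups) - 1, p=float(p), n=ns)


def chi2_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("chi2_2x2", float(chi2), df=int(df), p=float(p),
                      n=tuple(int(x) for x in table.sum(axis=1)))


# -- the battery -------------------------------------------------------------------

def run_battery(
    table: SiteRateTable,
    regions: RegionSet,
    partner: np.ndarray | None = None,
) -> list[TestResult]:
    """The five-test battery for one data set.

    1. paired-vs-paired Wilcoxon on the two rates of each base pair;
    2. stems-vs-loops Mann-Whitney on collapsed pair rates vs loop rates;
    3. chi-square on constant/variable counts x hypervariable/non-hypervariable;
    4. hypervariable-vs-non Mann-Whitney on site rates;
    5. Kruskal-Wallis across the individual hypervariable regions plus the
       pooled non-hypervariable sites.

    Without a structure map (`partner` None) the two structural tests are
    reported as explicit gaps rather than silently omitted.
    """
    results: list[TestResult] = []
    if partner is not None:
        ps = collapse_paired(table, partner)
        if ps.pair_rates:
            x = np.array([a for a, _ in ps.pair_rates])
            y = np.array([b for _, b in ps.pair_rates])
            results.append(wilcoxon_signed_rank(x, y, exact=False))
        else:
            results.append(TestResult("wilcoxon_signed_rank", float("nan"),
                                      note="no rated base pairs"))
        if len(ps.stems) and len(ps.loops):
            results.append(mann_whitney_u(ps.stems, ps.loops, exact=False))
        else:
            results.append(TestResult("mann_whitney_u", float("nan"),
                                      note="empty stem or loop sample"))
    else:
        for name in ("wilcoxon_signed_rank", "mann_whitney_u"):
            results.append(TestResult(name, float("nan"), note="no structure map"))

    labels = regions.labels(table.length)
    hyper = labels != NON_HYPERVARIABLE
    cls = table.classification.classes
    rated = np.isfinite(table.rates)
    passing = cls != INSUFFICIENT
    cont = np.array(
        [
            [(passing & ~hyper & (cls == "constant")).sum(),
             (passing & ~hyper & (cls == "variable")).sum()],
            [(passing & hyper & (cls == "constant")).sum(),
             (passing & hyper & (cls == "variable")).sum()],
        ]
    )
    results.append(chi2_2x2(cont))
    non_rates = table.rates[rated & ~hyper]
    hyp_rates = table.rates[rated & hyper]
    if len(non_rates) and len(hyp_rates):
        results.append(mann_whitney_u(non_rates, hyp_rates, exact=False))
    else:
        results.append(TestResult("mann_whitney_u", float("nan"),
                                  note="empty region sample"))
    groups = [non_rates] + [
        table.rates[rated & (labels == r.name)] for r in regions
    ]
    group_names = [NON_HYPERVARIABLE] + regions.names()
    keep = [(g, nm) for g, nm in zip(groups, group_names) if len(g)]
    results.append(kruskal_wallis([g for g, _ in keep]))
    results[-1].note = (results[-1].note + " groups=" +
                        ",".join(nm for _, nm in keep)).strip()
    return results
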