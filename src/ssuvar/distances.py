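"""Pairwise sequence distances: uncorrected p and GTR maximum likelihood.

Distances use pairwise deletion: only columns where both rows carry an
unambiguous A/C/G/T enter a comparison; ambiguity codes, N and gaps are
treated as missing. A pair with no shared informative column has an undefined
distance (NaN), mirroring how non-overlapping partial sequences behave.

The GTR distance is the branch length t maximising the likelihood of the
pairwise count matrix under a general time-reversible rate matrix Q shared
across all pairs (estimated once from the whole alignment); P(t) = exp(Qt) is
evaluated through the symmetrised eigendecomposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import GroupAssignment, MultipleAlignment

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i

#: unordered state pairs indexing the six exchangeabilities
PAIR_ORDER = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT

_T_MAX = 20.0  # substitutions/site above which the optimum is treated as saturated


def encode(aln: MultipleAlignment) -> np.ndarray:
    """uint8 codes A=0 C=1 G=2 T=3, 255 for anything non-informative."""
    return _CODE[aln.chars]


@dataclass
class PairwiseDistanceMatrix:
    model: str                # "p" or "GTR"
    ids: list[str]
    d: np.ndarray             # (n, n) float, NaN = undefined
    n_sites: np.ndarray       # (n, n) int overlapping informative sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites over shared informative columns (NaN if none)."""
    a = _CODE[np.frombuffer(row_a.upper().replace("U", "T").encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_b.upper().replace("U", "T").encode(), dtype=np.uint8)]
    ov = (a < 4) & (b < 4)
    n = int(ov.sum())
    if n == 0:
        return float("nan")
    return float(((a != b) & ov).sum() / n)


def p_distance_matrix(aln: MultipleAlignment) -> PairwiseDistanceMatrix:
    codes = encode(aln)
    valid = codes < 4
    n = aln.n_taxa
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for i in range(n):
        ov = valid[i] & valid
        cnt = ov.sum(axis=1)
        diff = ((codes != codes[i]) & ov).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(cnt > 0, diff / np.maximum(cnt, 1), np.nan)
        ns[i] = cnt
    np.fill_diagonal(d, 0.0)
    return PairwiseDistanceMatrix("p", list(aln.ids), d, ns)


# -- GTR model ---------------------------------------------------------------------

@dataclass
class GTRParams:
    """Six relative exchangeabilities (GT fixed at 1) and four base frequencies."""

    rates: np.ndarray   # order AC, AG, AT, CG, CT, GT
    freqs: np.ndarray   # order A, C, G, T

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or (self.rates <= 0).any():
            raise ValueError("need 6 positive exchangeability rates")
        if self.freqs.shape != (4,) or (self.freqs <= 0).any():
            raise ValueError("need 4 positive base frequencies")
        self.freqs = self.freqs / self.freqs.sum()

    @classmethod
    def jc(cls) -> "GTRParams":
        return cls(np.ones(6), np.full(4, 0.25))

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero, scaled to one expected substitution/site."""
        Q = np.zeros((4, 4))
        for (a, b), s in zip(PAIR_ORDER, self.rates):
            Q[a, b] = s * self.freqs[b]
            Q[b, a] = s * self.freqs[a]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        return Q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, left factor, right factor) such that
        P(t) = left @ diag(exp(lam t)) @ right."""
        Q = self.rate_matrix()
        sq = np.sqrt(self.freqs)
        B = (sq[:, None] * Q) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        left = V / sq[:, None]
        right = V.T * sq[None, :]
        return lam, left, right

    def transition(self, t: float) -> np.ndarray:
        lam, left, right = self.eigen()
        P = (left * np.exp(lam * t)) @ right
        return np.clip(P, 1e-300, None)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (a, b), s in zip(PAIR_ORDER, self.rates):
                fh.write(f"rate_{'ACGT'[a]}{'ACGT'[b]}\t{s:.10g}\n")
            for i, c in enumerate("ACGT"):
                fh.write(f"freq_{c}\t{self.freqs[i]:.10g}\n")

    @classmethod
    def from_file(cls, path) -> "GTRParams":
        vals = {}
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    k, v = line.split()
                    vals[k] = float(v)
        rates = [vals[f"rate_{'ACGT'[a]}{'ACGT'[b]}"] for a, b in PAIR_ORDER]
        freqs = [vals[f"freq_{c}"] for c in "ACGT"]
        return cls(np.array(rates), np.array(freqs))


def _pooled_pair_counts(codes: np.ndarray) -> np.ndarray:
    """Symmetric 4x4 count matrix summed over all unordered row pairs.

    Uses per-column state totals: the number of ordered cross-row (a, b)
    co-occurrences at one column is cnt_a * cnt_b (minus self-pairs on the
    diagonal), which pools all pairs in O(n L).
    """
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)]).astype(float)
    F = counts @ counts.T
    F[np.diag_indices(4)] -= counts.sum(axis=1)
    F = (F + F.T) / 2  # symmetrise; halves ordered pairs into unordered
    return F


def estimate_gtr_params(
    aln: MultipleAlignment, freqs: np.ndarray | None = None
) -> GTRParams:
    """GTR frequencies from empirical counts; exchangeabilities by maximising the
    likelihood of the pooled pairwise count matrix (single shared divergence).
    """
    codes = encode(aln)
    if freqs is None:
        base_counts = np.array([(codes == s).sum() for s in range(4)], dtype=float)
        if (base_counts == 0).any():
            missing = [c for c, n in zip("ACGT", base_counts) if n == 0]
            raise ValueError(
                f"base(s) {missing} absent from alignment; supply frequencies "
                "explicitly to fit a GTR model"
            )
        freqs = base_counts / base_counts.sum()
    F = _pooled_pair_counts(codes)
    if F.sum() == 0:
        raise ValueError("no overlapping informative sites in alignment")

    def negll(theta: np.ndarray) -> float:
        rates = np.append(np.exp(theta[:5]), 1.0)
        t = np.exp(theta[5])
        params = GTRParams(rates, freqs)
        P = params.transition(t)
        return -float((F * np.log(freqs[:, None] * P)).sum())

    x0 = np.zeros(6)
    x0[5] = np.log(0.1)
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
    rates = np.append(np.exp(res.x[:5]), 1.0)
    return GTRParams(rates / rates[-1], freqs)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ov = (a < 4) & (b < 4)
    if not ov.any():
        return np.zeros((4, 4))
    return np.bincount(4 * a[ov].astype(int) + b[ov], minlength=16).reshape(4, 4).astype(float)


def _gtr_mle_t(N: np.ndarray, params: GTRParams,
               eig: tuple | None = None) -> float:
    total = N.sum()
    if total == 0:
        return float("nan")
    if N.trace() == total:
        return 0.0
    lam, left, right = eig if eig is not None else params.eigen()
    logpi = np.log(params.freqs)[:, None]

    def negll(t: float) -> float:
        P = np.clip((left * np.exp(lam * t)) @ right, 1e-300, None)
        return -float((N * (logpi + np.log(P))).sum())

    res = minimize_scalar(negll, bounds=(1e-9, _T_MAX), method="bounded",
                          options={"xatol": 1e-10})
    t = float(res.x)
    if t > 0.99 * _T_MAX:      # likelihood still rising at the bound: saturated
        return float("nan")
    return t


def gtr_distance(row_a: str, row_b: str, params: GTRParams) -> float:
    """ML branch length between two aligned rows under the shared GTR model."""
    a = _CODE[np.frombuffer(row_a.upper().replace("U", "T").encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_b.upper().replace("U", "T").encode(), dtype=np.uint8)]
    return _gtr_mle_t(_pair_counts(a, b), params)


def gtr_distance_matrix(
    aln: MultipleAlignment, params: GTRParams | None = None
) -> PairwiseDistanceMatrix:
    if params is None:
        params = estimate_gtr_params(aln)
    codes = encode(aln)
    eig = params.eigen()
    n = aln.n_taxa
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        N = _pair_counts(codes[i], codes[j])
        ns[i, j] = ns[j, i] = int(N.sum())
        d[i, j] = d[j, i] = _gtr_mle_t(N, params, eig)
    return PairwiseDistanceMatrix("GTR", list(aln.ids), d, ns)


# -- group summaries ---------------------------------------------------------------

def group_summary(
    matrix: PairwiseDistanceMatrix, groups: GroupAssignment
) -> pd.DataFrame:
    """Mean +/- SE of defined pairwise distances within and between group pairs.

    SE is the sample standard deviation over distances divided by sqrt(count);
    cells with no defined comparison report NaN with count 0.
    """
    labels = [groups[t] for t in matrix.ids]
    uniq = []
    for lab in labels:
        if lab not in uniq:
            uniq.append(lab)
    idx_of = {lab: [i for i, l in enumerate(labels) if l == lab] for lab in uniq}
    rows = []
    for a, b in itertools.combinations_with_replacement(uniq, 2):
        vals = []
        if a == b:
            members = idx_of[a]
            pairs = itertools.combinations(members, 2)
        else:
            pairs = itertools.product(idx_of[a], idx_of[b])
        for i, j in pairs:
            v = matrix.d[i, j]
            if np.isfinite(v):
                vals.append(v)
        count = len(vals)
        if count == 0:
            mean = se = float("nan")
        else:
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(count)) if count > 1 else 0.0
        rows.append({"group1": a, "group2": b, "mean": mean, "se": se, "count": count})
    return pd.DataFrame(rows)


def overall_summary(matrix: PairwiseDistanceMatrix,
                    taxa: list[str] | None = None) -> dict:
    """Mean +/- SE over all defined pairwise comparisons among `taxa` (default all)."""
    if taxa is None:
        idx = list(range(len(matrix.ids)))
    else:
        idx = [matrix.ids.index(t) for t in taxa]
    vals = [
        matrix.d[i, j]
        for i, j in itertools.combinations(idx, 2)
        if np.isfinite(matrix.d[i, j])
    ]
    n = len(vals)
    return {
        "mean": float(np.mean(vals)) if n else float("nan"),
        "se": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "count": n,
    }
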