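"""Secondary-structure maps and the two-step core-structure transfer.

The workflow mirrors how a conserved SSU rRNA core is carried onto new
sequences when the full molecule (with pseudoknots) cannot be folded in one
pass:

1. a consensus constraint is built from reference structures sharing one
   backbone alignment — positions consistently paired across the references
   keep their pairing, consistently unpaired positions are pinned unpaired
   ('x'), hypervariable regions and pseudoknotted/nested positions are pinned
   unpaired so they fold later, and everything else is left free ('.');
2. each hypervariable region is folded on its own inside a short 2-bp
   "bracket" stem that supplies basal context (taken from the adjacent
   sequence, from the region's own ends, or appended artificially and removed
   afterwards), and the resulting hairpins are spliced back into the core;
   pseudoknot pairings are finally transferred from a reference by homologous
   coordinates into a separate layer that may cross the primary structure.

A built-in folding engine (dynamic-programming base-pair maximisation with
canonical pairs, a minimum hairpin loop of three and hard 'x' constraints)
makes the whole pipeline self-contained and exactly testable; an external
minimum-free-energy program can be swapped in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_LOOP = 3
_NEG = -(10**9)

_LAYERS = ["()", "[]", "{}", "<>"]


class StructureError(ValueError):
    pass


def _norm_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class StructureMap:
    """Pairing map over a sequence: a non-crossing primary layer plus a
    pseudoknot layer whose pairings may cross the primary ones."""

    seq: str
    pairs: dict[int, int] = field(default_factory=dict)   # 0-based, symmetric
    knots: list[tuple[int, int]] = field(default_factory=list)  # 0-based (i < j)

    def __post_init__(self):
        self.seq = _norm_seq(self.seq)
        sym = {}
        for i, j in self.pairs.items():
            sym[i] = j
            sym[j] = i
        self.pairs = sym
        self.knots = [tuple(sorted(k)) for k in self.knots]
        self.validate()

    # -- invariants ---------------------------------------------------------------
    def validate(self) -> None:
        n = len(self.seq)
        for i, j in self.pairs.items():
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(f"bad pair ({i}, {j})")
            if self.pairs.get(j) != i:
                raise StructureError("primary pairing is not an involution")
        plist = self.pair_list()
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                (i1, j1), (i2, j2) = plist[a], plist[b]
                if i1 < i2 < j1 < j2 or i2 < i1 < j2 < j1:
                    raise StructureError(
                        f"crossing pairs {plist[a]} / {plist[b]} in primary layer"
                    )
        seen: set[int] = set()
        for i, j in self.knots:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(f"bad knot pair ({i}, {j})")
            if i in seen or j in seen:
                raise StructureError("knot layer is not an involution")
            seen.update((i, j))

    def pair_list(self) -> list[tuple[int, int]]:
        return sorted({(min(i, j), max(i, j)) for i, j in self.pairs.items()})

    def all_pairs(self) -> list[tuple[int, int]]:
        return sorted(set(self.pair_list()) | set(self.knots))

    def partner_array(self, include_knots: bool = False) -> np.ndarray:
        """0-based partner per position, -1 when unpaired."""
        out = np.full(len(self.seq), -1, dtype=int)
        for i, j in self.pairs.items():
            out[i] = j
        if include_knots:
            for i, j in self.knots:
                out[i], out[j] = j, i
        return out

    def n_pairs(self) -> int:
        return len(self.pair_list())

    def noncanonical_pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i, j in self.all_pairs()
            if (self.seq[i], self.seq[j]) not in CANONICAL
        ]

    # -- dot-bracket --------------------------------------------------------------
    def to_dotbracket(self) -> str:
        out = ["."] * len(self.seq)
        for i, j in self.pair_list():
            out[i], out[j] = "(", ")"
        layers: list[list[tuple[int, int]]] = []
        for i, j in sorted(self.knots):
            for layer in layers:
                if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                    layer.append((i, j))
                    break
            else:
                layers.append([(i, j)])
        if len(layers) > len(_LAYERS) - 1:
            raise StructureError("too many mutually crossing knot layers to encode")
        for li, layer in enumerate(layers, start=1):
            op, cl = _LAYERS[li]
            for i, j in layer:
                out[i], out[j] = op, cl
        return "".join(out)

    @classmethod
    def from_dotbracket(cls, seq: str, struct: str) -> "StructureMap":
        if len(seq) != len(struct):
            raise StructureError(
                f"sequence length {len(seq)} != structure length {len(struct)}"
            )
        stacks: dict[str, list[int]] = {op: [] for op, _ in _LAYERS}
        closer_of = {cl: op for op, cl in _LAYERS}
        pairs: dict[int, int] = {}
        knots: list[tuple[int, int]] = []
        for pos, ch in enumerate(struct):
            if ch in closer_of.values() and ch in [op for op, _ in _LAYERS]:
                stacks[ch].append(pos)
            elif ch in closer_of:
                op = closer_of[ch]
                if not stacks[op]:
                    raise StructureError(f"unbalanced {ch!r} at position {pos + 1}")
                i = stacks[op].pop()
                if op == "(":
                    pairs[i] = pos
                else:
                    knots.append((i, pos))
            elif ch not in ".,:_-":
                raise StructureError(f"unknown structure symbol {ch!r} at {pos + 1}")
        for op, st in stacks.items():
            if st:
                raise StructureError(f"unbalanced {op!r} at position {st[-1] + 1}")
        return cls(seq, pairs, knots)


def read_vienna(path) -> list[tuple[str, StructureMap]]:
    """Read FASTA-style records of the form >name / sequence / dot-bracket."""
    out = []
    name, seq, struct = None, [], []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise StructureError(f"truncated record {name!r}")
        seq, struct = lines[i + 1], lines[i + 2].split()[0]
        out.append((name, StructureMap.from_dotbracket(seq, struct)))
        i += 3
    return out


def write_vienna(records: Iterable[tuple[str, StructureMap]], path) -> None:
    with open(path, "w") as fh:
        for name, m in records:
            fh.write(f">{name}\n{m.seq}\n{m.to_dotbracket()}\n")


# -- constraints -------------------------------------------------------------------

def parse_constraint(constraint: str) -> dict[int, int]:
    """Matched '('/')' pairs of a constraint string (0-based i -> j, i < j)."""
    stack: list[int] = []
    forced: dict[int, int] = {}
    for pos, ch in enumerate(constraint):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at constraint position {pos + 1}")
            forced[stack.pop()] = pos
        elif ch not in ".x":
            raise StructureError(f"bad constraint symbol {ch!r} at {pos + 1}")
    if stack:
        raise StructureError(f"unbalanced '(' at constraint position {stack[-1] + 1}")
    return forced


#: engine signature: (sequence, constraint or None, enforce) -> (StructureMap, score)
FoldingEngine = Callable[[str, "str | None", bool], tuple[StructureMap, float]]


def reference_fold(
    seq: str, constraint: str | None = None, enforce: bool = False
) -> tuple[StructureMap, float]:
    """Base-pair maximisation honouring constraints; the built-in engine.

    Canonical pairs only (AU/AT, GC, GU/GT), minimum hairpin loop of three
    unpaired bases. 'x' positions are never paired. With `enforce`, matched
    '('/')' constraint pairs must be realised (their base identity is not
    checked — a transferred pair may be non-canonical in the target); without
    it they are treated as unconstrained. Ties are broken deterministically:
    the 5'-most pairable position pairs first, with its nearest partner.
    """
    seq = _norm_seq(seq)
    n = len(seq)
    if constraint is None:
        constraint = "." * n
    if len(constraint) != n:
        raise StructureError("constraint length != sequence length")
    forced = parse_constraint(constraint) if enforce else {}
    forced_partner = {}
    for i, j in forced.items():
        forced_partner[i] = j
        forced_partner[j] = i

    blocked = np.array([c == "x" for c in constraint])
    if enforce:
        for i in forced_partner:
            if blocked[i]:
                raise StructureError(f"position {i + 1} both forced paired and 'x'")

    # partner lists: k > i, canonical (or forced), respecting 'x' and min loop
    partners: list[np.ndarray] = []
    for i in range(n):
        ks = []
        for k in range(i + MIN_LOOP + 1, n):
            if blocked[i] or blocked[k]:
                continue
            if i in forced_partner or k in forced_partner:
                if forced_partner.get(i) == k:
                    ks.append(k)
                continue
            if (seq[i], seq[k]) in CANONICAL:
                ks.append(k)
        partners.append(np.array(ks, dtype=int))

    fp = sorted((i, j) for i, j in forced.items())

    def window_ok(i: int, j: int) -> bool:
        # no forced pair may straddle a subproblem boundary
        return all((i <= a <= j) == (i <= b <= j) for a, b in fp)

    # N[i][jj] with jj = j + 1 (so N[i][i] = empty interval = 0)
    N = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if not window_ok(i, j):
                N[i][j + 1] = _NEG
                continue
            must_pair = enforce and i in forced_partner
            best = _NEG if must_pair else N[i + 1][j + 1]
            ks = partners[i]
            ks = ks[ks <= j]
            if len(ks):
                cand = 1 + N[i + 1][ks] + N[ks + 1, j + 1]
                best = max(best, int(cand.max()))
            N[i][j + 1] = best
    if N[0][n] < 0:
        raise StructureError("constraints are unsatisfiable")

    pairs: dict[int, int] = {}

    def trace(i: int, j: int) -> None:
        while i <= j:
            target = N[i][j + 1]
            must_pair = enforce and i in forced_partner
            if not must_pair and N[i + 1][j + 1] == target:
                # only leave i unpaired when no pairing of i attains the optimum
                ks = partners[i]
                ks = ks[ks <= j]
                paired_best = (
                    int((1 + N[i + 1][ks] + N[ks + 1, j + 1]).max()) if len(ks) else _NEG
                )
                if paired_best < target:
                    i += 1
                    continue
            ks = partners[i]
            ks = ks[ks <= j]
            vals = 1 + N[i + 1][ks] + N[ks + 1, j + 1]
            k = int(ks[np.flatnonzero(vals == target)[0]])  # nearest partner first
            pairs[i] = k
            trace(i + 1, k - 1)
            i = k + 1

    trace(0, n - 1)
    return StructureMap(seq, pairs), float(N[0][n])


def rnafold_engine(seq: str, constraint: str | None = None,
                   enforce: bool = False) -> tuple[StructureMap, float]:
    """Optional adapter running the external RNAfold program via dot-bracket text.

    Satisfies the same contract as :func:`reference_fold` but scores by minimum
    free energy. Requires the RNAfold executable on PATH.
    """
    import re
    import subprocess

    args = ["RNAfold", "--noPS"]
    inp = seq
    if constraint is not None:
        args.append("-C")
        if enforce:
            args.append("--enforceConstraint")
        inp = f"{seq}\n{constraint}"
    res = subprocess.run(args, input=inp, text=True, capture_output=True, check=True)
    lines = res.stdout.strip().splitlines()
    struct_line = lines[-1]
    m = re.match(r"([().]+)\s+\(\s*(-?\d+\.?\d*)\)", struct_line)
    if not m:
        raise StructureError(f"unparseable RNAfold output: {struct_line!r}")
    return StructureMap.from_dotbracket(_norm_seq(seq), m.group(1)), float(m.group(2))


# -- step 1: consensus constraint --------------------------------------------------

def build_consensus_constraint(
    ref_maps: Sequence[StructureMap],
    hyper,
    knot_pairs: Iterable[tuple[int, int]] = (),
    nested_pairs: Iterable[tuple[int, int]] = (),
) -> str:
    """Consensus constraint over a common backbone from >= 2 aligned reference maps.

    `ref_maps` share one coordinate system (their sequences are the aligned
    rows, '-' where a reference is absent); `hyper` is a RegionSet in backbone
    coordinates (1-based); knot/nested pairs are 1-based backbone coordinate
    pairs. Rules: positions paired with the same partner in every reference
    present everywhere -> '(' / ')'; consistently unpaired -> 'x'; anything
    else (disagreement or any reference gap) -> '.'. Hypervariable, pseudoknot
    and nested-pairing positions are overridden to 'x' so they form unresolved
    loops; a consensus pair losing an endpoint to such an override keeps '.'
    at the surviving endpoint.
    """
    if len(ref_maps) < 2:
        raise StructureError("need at least two reference maps")
    n = len(ref_maps[0].seq)
    if any(len(m.seq) != n for m in ref_maps):
        raise StructureError("reference maps must share one backbone length")
    present = np.array([[c != "-" for c in m.seq] for m in ref_maps])
    partners = np.stack([m.partner_array() for m in ref_maps])
    all_present = present.all(axis=0)
    out = ["."] * n
    consensus_pairs = []
    for i in range(n):
        if not all_present[i]:
            continue
        ps = partners[:, i]
        if (ps == -1).all():
            out[i] = "x"
        elif (ps == ps[0]).all() and ps[0] > i and all_present[ps[0]]:
            consensus_pairs.append((i, int(ps[0])))
    forced_x = np.zeros(n, dtype=bool)
    for r in hyper:
        forced_x[r.start - 1 : r.end] = True
    for i, j in list(knot_pairs) + list(nested_pairs):
        forced_x[i - 1] = forced_x[j - 1] = True
    for i, j in consensus_pairs:
        if forced_x[i] or forced_x[j]:
            if not forced_x[i]:
                out[i] = "."
            if not forced_x[j]:
                out[j] = "."
        else:
            out[i], out[j] = "(", ")"
    for pos in np.flatnonzero(forced_x):
        out[pos] = "x"
    constraint = "".join(out)
    parse_constraint(constraint)  # verifies balance
    return constraint


def project_constraint(constraint: str, aligned_target: str) -> tuple[str, dict[int, int]]:
    """Project a backbone-coordinate constraint onto a target sequence.

    `aligned_target` is the target row in backbone coordinates ('-' = absent).
    Returns the constraint in ungapped target coordinates plus a 1-based
    backbone->target column map. Constraint pairs with either partner deleted
    in the target degrade to '.' at the surviving position; target positions
    are kept as-is otherwise.
    """
    if len(constraint) != len(aligned_target):
        raise StructureError("constraint/backbone length mismatch")
    colmap: dict[int, int] = {}
    tpos = 0
    for col, ch in enumerate(aligned_target, start=1):
        if ch != "-":
            tpos += 1
            colmap[col] = tpos
    forced = parse_constraint(constraint)
    out = []
    for col, ch in enumerate(aligned_target, start=1):
        if ch == "-":
            continue
        sym = constraint[col - 1]
        out.append(sym if sym in ".x" else ".")
    for i, j in forced.items():
        if (i + 1) in colmap and (j + 1) in colmap:
            out[colmap[i + 1] - 1] = "("
            out[colmap[j + 1] - 1] = ")"
    return "".join(out), colmap


# -- step 2: hypervariable folding, splicing, knots --------------------------------

BracketMode = Literal["adjacent", "internal", "artificial"]


def fold_hypervariable_region(
    seq: str,
    region: tuple[int, int],
    bracket_mode: BracketMode,
    engine: FoldingEngine | None = None,
    bracket: tuple[str, str] = ("GG", "CC"),
) -> StructureMap:
    """Fold one hypervariable region with a 2-bp bracketing stem for context.

    `seq` is the full (ungapped) molecule, `region` a 1-based (start, length)
    interval within it. Bracket modes: 'adjacent' borrows the two flanking
    bases on each side of the region and strips them afterwards; 'internal'
    forces the region's own first/last two positions to pair; 'artificial'
    appends `bracket` (default GG/CC) and removes it after folding. The
    returned map is in region-local coordinates and contains no pairing at any
    stripped bracket position.
    """
    engine = engine or reference_fold
    start, length = region
    if start < 1 or start + length - 1 > len(seq):
        raise StructureError(f"region {region} outside sequence")
    if length < 2 * 2 + MIN_LOOP:
        raise StructureError(f"region of length {length} too short to bracket")
    s0, s1 = start - 1, start - 1 + length
    sub = seq[s0:s1]

    if bracket_mode == "internal":
        constraint = "((" + "." * (length - 4) + "))"
        folded, _ = engine(sub, constraint, True)
        return folded
    if bracket_mode == "adjacent":
        if s0 < 2 or s1 + 2 > len(seq):
            raise StructureError("no adjacent sequence available for bracketing")
        ext = seq[s0 - 2 : s0] + sub + seq[s1 : s1 + 2]
        offset = 2
    elif bracket_mode == "artificial":
        left, right = bracket
        if len(left) < 2 or len(right) < 2:
            raise StructureError("artificial bracket needs >= 2 bases per side")
        ext = left + sub + right
        offset = len(left)
    else:
        raise StructureError(f"unknown bracket mode {bracket_mode!r}")
    constraint = "((" + "." * (len(ext) - 4) + "))"
    folded, _ = engine(ext, constraint, True)
    pairs = {
        i - offset: j - offset
        for i, j in folded.pair_list()
        if offset <= i < offset + length and offset <= j < offset + length
    }
    return StructureMap(sub, pairs)


def splice(core: StructureMap, sub: StructureMap, region: tuple[int, int]) -> StructureMap:
    """Splice a region-local sub-structure into the core map.

    The core must be unpaired throughout the region; a position paired in both
    maps is a collision error. The primary layer of the result is re-validated
    (involution, non-crossing).
    """
    start, length = region
    if len(sub.seq) != length:
        raise StructureError("sub-structure length != region length")
    if core.seq[start - 1 : start - 1 + length] != sub.seq:
        raise StructureError("sub-structure sequence disagrees with core region")
    merged = dict(core.pairs)
    for i, j in sub.pair_list():
        gi, gj = i + start - 1, j + start - 1
        for g in (gi, gj):
            if g in merged:
                raise StructureError(f"splice collision at position {g + 1}")
        merged[gi] = gj
        merged[gj] = gi
    return StructureMap(core.seq, merged, list(core.knots))


def transfer_pseudoknots(
    ref_map: StructureMap,
    ref_aligned: str,
    target_aligned: str,
    target: StructureMap,
) -> tuple[StructureMap, list[tuple[int, int]]]:
    """Carry the reference's knot-layer pairings to homologous target positions.

    `ref_aligned` / `target_aligned` are the two rows of a pairwise alignment
    of the reference and target molecules. Knot pairs whose either partner
    maps to a gap in the target are returned in the unmapped list (1-based
    reference coordinates) rather than silently dropped.
    """
    ref_ungapped = ref_aligned.replace("-", "")
    if _norm_seq(ref_ungapped) != ref_map.seq:
        raise StructureError("reference row does not match reference map sequence")
    if _norm_seq(target_aligned.replace("-", "")) != target.seq:
        raise StructureError("target row does not match target map sequence")
    ref2col: dict[int, int] = {}
    rpos = 0
    for col, ch in enumerate(ref_aligned):
        if ch != "-":
            ref2col[rpos] = col
            rpos += 1
    col2tgt: dict[int, int] = {}
    tpos = 0
    for col, ch in enumerate(target_aligned):
        if ch != "-":
            col2tgt[col] = tpos
            tpos += 1
    new_knots = list(target.knots)
    unmapped: list[tuple[int, int]] = []
    occupied = {p for k in target.knots for p in k}
    for i, j in ref_map.knots:
        ti = col2tgt.get(ref2col[i])
        tj = col2tgt.get(ref2col[j])
        if ti is None or tj is None:
            unmapped.append((i + 1, j + 1))
            continue
        if ti in occupied or tj in occupied:
            unmapped.append((i + 1, j + 1))
            continue
        new_knots.append((ti, tj))
        occupied.update((ti, tj))
    return StructureMap(target.seq, dict(target.pairs), new_knots), unmapped
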