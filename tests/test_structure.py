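"""Structure maps, constrained folding, consensus transfer, splicing, knots.

The folding oracle enumerates every legal structure of a short sequence
recursively and returns the full set of maximal-pair structures; the DP
engine must always produce a member of that set.
"""

import itertools

import numpy as np
import pytest

import ssuvar as sv
from ssuvar.structure import (
    CANONICAL,
    MIN_LOOP,
    StructureError,
    StructureMap,
    build_consensus_constraint,
    parse_constraint,
    project_constraint,
    reference_fold,
)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(seq, constraint=None):
    """All legal pair sets (canonical, min loop 3, non-crossing, 'x' respected)."""
    n = len(seq)
    seq = seq.upper().replace("U", "T")
    constraint = constraint or "." * n

    def pairable(i, j):
        if constraint[i] == "x" or constraint[j] == "x":
            return False
        return (seq[i], seq[j]) in CANONICAL and j - i > MIN_LOOP

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        # i unpaired
        yield from rec(rest)
        for j in rest:
            if not pairable(i, j):
                continue
            inside = tuple(p for p in rest if i < p < j)
            outside = tuple(p for p in rest if p > j)
            for a in rec(inside):
                for b in rec(outside):
                    yield a | b | {(i, j)}

    return set(rec(tuple(range(n))))


def optimal_structures(seq, constraint=None):
    structs = enumerate_structures(seq, constraint)
    best = max(len(s) for s in structs)
    return best, {s for s in structs if len(s) == best}


# ---------------------------------------------------------------------------
# dot-bracket / vienna I/O
# ---------------------------------------------------------------------------

class TestDotBracket:
    def test_simple_hairpin(self):
        m = StructureMap.from_dotbracket("GGAATC", "((..))")
        assert m.pair_list() == [(0, 5), (1, 4)]

    def test_pseudoknot_layers(self):
        m = StructureMap.from_dotbracket("GGAAUUCCGGAAUU", "((..[[..))..]]")
        assert m.pair_list() == [(0, 9), (1, 8)]
        assert sorted(m.knots) == [(4, 13), (5, 12)]
        assert m.to_dotbracket() == "((..[[..))..]]"

    def test_unbalanced_reports_position(self):
        with pytest.raises(StructureError, match="position 3"):
            StructureMap.from_dotbracket("AAAAA", "..)).")
        with pytest.raises(StructureError):
            StructureMap.from_dotbracket("AAAA", "((..")

    def test_crossing_in_primary_layer_rejected(self):
        with pytest.raises(StructureError, match="crossing"):
            StructureMap("ACGTACGTAC", {0: 6, 4: 9})

    def test_vienna_roundtrip(self, tmp_path):
        maps = [
            ("hairpin", StructureMap.from_dotbracket("GGGAAACCC", "(((...)))")),
            ("knotted", StructureMap.from_dotbracket("GGAAUUCCGGAAUU", "((..[[..))..]]")),
        ]
        p = tmp_path / "maps.vienna"
        sv.write_vienna(maps, p)
        back = sv.read_vienna(p)
        assert [(n, m.seq, m.pair_list(), sorted(m.knots)) for n, m in back] == [
            (n, m.seq, m.pair_list(), sorted(m.knots)) for n, m in maps
        ]


# ---------------------------------------------------------------------------
# the folding engine
# ---------------------------------------------------------------------------

class TestReferenceFold:
    def test_no_complementarity_no_pairs(self):
        m, score = reference_fold("AAAA")
        assert score == 0 and m.pair_list() == []

    def test_known_hairpin(self):
        m, score = reference_fold("GGGAAACCC")
        assert score == 3
        assert m.pair_list() == [(0, 8), (1, 7), (2, 6)]

    def test_all_x_constraint_beats_everything(self):
        m, score = reference_fold("GGGAAACCC", "x" * 9)
        assert score == 0 and m.pair_list() == []

    def test_matches_enumeration_on_seeded_cases(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 11))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            best, optima = optimal_structures(seq)
            m, score = reference_fold(seq)
            assert score == best
            assert frozenset(m.pair_list()) in optima

    def test_respects_x_in_random_constraints(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(6, 12))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            constraint = "".join(rng.choice(list("..x"), size=n))
            m, score = reference_fold(seq, constraint)
            blocked = {i for i, c in enumerate(constraint) if c == "x"}
            assert not any(i in blocked or j in blocked for i, j in m.pair_list())
            best, optima = optimal_structures(seq, constraint)
            assert score == best and frozenset(m.pair_list()) in optima

    def test_enforced_pairs_are_realised(self):
        m, _ = reference_fold("GGAAAACCAA", "((....))..", enforce=True)
        assert {(0, 7), (1, 6)} <= set(m.pair_list())

    def test_unenforced_parentheses_are_free(self):
        # without enforce, '()' marks are treated as unconstrained positions
        m1, s1 = reference_fold("GGGAAACCC", "((.....))", enforce=False)
        m2, s2 = reference_fold("GGGAAACCC")
        assert s1 == s2 and m1.pair_list() == m2.pair_list()

    def test_deterministic_tie_break(self):
        seq = "GCAAAAGCAAAAGC"  # several equally good single-stem options
        first = reference_fold(seq)[0].pair_list()
        for _ in range(3):
            assert reference_fold(seq)[0].pair_list() == first


# ---------------------------------------------------------------------------
# consensus constraints (step 1)
# ---------------------------------------------------------------------------

def _hairpin_map(seq, pairs):
    return StructureMap(seq, dict(pairs))


class TestConsensusConstraint:
    BACKBONE = "GGGAAACCCAAAAAATTTT"  # hairpin at 0-8, tail 9-18

    def _refs(self, n=3):
        pairs = {0: 8, 1: 7, 2: 6}
        return [_hairpin_map(self.BACKBONE, pairs) for _ in range(n)]

    def test_identical_refs_mirror_structure(self):
        constraint = build_consensus_constraint(self._refs(), sv.RegionSet([]))
        assert constraint == "((( x x x)))" .replace(" ", "") + "x" * 10

    def test_single_disagreeing_ref_gives_dot(self):
        refs = self._refs()
        refs[2] = _hairpin_map(self.BACKBONE, {0: 8, 1: 7})  # pair (2,6) missing
        constraint = build_consensus_constraint(refs, sv.RegionSet([]))
        assert constraint[0] == "(" and constraint[8] == ")"
        assert constraint[2] == "." and constraint[6] == "."

    def test_hypervariable_and_knot_positions_forced_unpaired(self):
        hyper = sv.RegionSet([("V1", 10, 6)])  # columns 10..15
        constraint = build_consensus_constraint(
            self._refs(), hyper, knot_pairs=[(17, 19)]
        )
        assert constraint[9:15] == "xxxxxx"
        assert constraint[16] == "x" and constraint[18] == "x"

    def test_pair_into_forced_region_degrades_to_dot(self):
        # a consensus pair with one end inside the hypervariable window keeps
        # '.' at the surviving end rather than an unbalanced parenthesis
        seq = "GGAAAAACCAA"
        refs = [_hairpin_map(seq, {0: 8, 1: 7}) for _ in range(3)]
        hyper = sv.RegionSet([("V1", 8, 2)])   # columns 8..9 -> positions 7, 8
        constraint = build_consensus_constraint(refs, hyper)
        assert constraint[7] == "x" and constraint[8] == "x"
        assert constraint[0] == "." and constraint[1] == "."
        parse_constraint(constraint)

    def test_reference_gap_positions_are_unconstrained(self):
        seq_full = "GGGAAACCC"
        seq_gap = "GGGAAACC-"
        refs = [
            _hairpin_map(seq_full, {0: 8, 1: 7, 2: 6}),
            _hairpin_map(seq_full, {0: 8, 1: 7, 2: 6}),
            _hairpin_map(seq_gap, {1: 7, 2: 6}),
        ]
        constraint = build_consensus_constraint(refs, sv.RegionSet([]))
        assert constraint[8] == "."   # ref absent there -> no consensus
        assert constraint[0] == "."   # its partner loses the pair too

    def test_needs_two_refs(self):
        with pytest.raises(StructureError):
            build_consensus_constraint(self._refs(1), sv.RegionSet([]))

    def test_projection_onto_target(self):
        constraint = "(((xxx)))....x"
        aligned_target = "GGG-AACCCAA-AT"
        projected, colmap = project_constraint(constraint, aligned_target)
        assert len(projected) == 12
        # the '(' at backbone column 1 still pairs with ')' at column 9
        assert projected[0] == "(" and projected[colmap[9] - 1] == ")"
        assert projected[colmap[14] - 1] == "x"

    def test_projection_drops_half_mapped_pairs(self):
        constraint = "((...))"
        aligned_target = "GG...-C"   # 3' partner of the outer pair deleted
        projected, _ = project_constraint(constraint.replace(".", "x"), "GGAAA-C")
        assert "(" in projected or projected.count("(") == projected.count(")")
        parse_constraint(projected)


# ---------------------------------------------------------------------------
# hypervariable folding, splicing, knots (step 2)
# ---------------------------------------------------------------------------

class TestHypervariableFolding:
    def test_artificial_bracket_removed(self):
        sub = sv.fold_hypervariable_region(
            "AAAAAAAAAAAA", (1, 12), "artificial"
        )
        assert len(sub.seq) == 12
        assert sub.pair_list() == []   # nothing pairs once the bracket is gone

    def test_internal_bracket_forces_terminal_stem(self):
        sub = sv.fold_hypervariable_region("GGAAAAAACC", (1, 10), "internal")
        assert {(0, 9), (1, 8)} <= set(sub.pair_list())

    def test_adjacent_bracket_uses_flanks_and_strips_them(self):
        seq = "GGAAATTTCAA" + "CC"
        #      ^ flanks GG (0-1)   region 3..9   flanks CC
        sub = sv.fold_hypervariable_region(seq, (3, 9), "adjacent")
        assert len(sub.seq) == 9
        for i, j in sub.pair_list():
            assert 0 <= i < j < 9

    def test_region_too_short(self):
        with pytest.raises(StructureError):
            sv.fold_hypervariable_region("GGAAACC", (1, 5), "internal")

    def test_palindromic_region_matches_enumeration(self):
        seq = "GGGGAAAACCCC"
        sub = sv.fold_hypervariable_region(seq, (1, 12), "internal")
        best, optima = optimal_structures(seq)
        # bracketing is a constraint, so the result can't beat the free optimum
        assert len(sub.pair_list()) <= best
        assert {(0, 11), (1, 10)} <= set(sub.pair_list())


class TestSplice:
    def test_splice_into_unpaired_core(self):
        core = StructureMap("AAGGGAAACCCAA", {})
        sub, _ = reference_fold("GGGAAACCC")
        out = sv.splice(core, sub, (3, 9))
        assert out.pair_list() == [(2, 10), (3, 9), (4, 8)]

    def test_splice_empty_sub_is_identity(self):
        core = StructureMap("GGAAACCAAAA", {0: 6, 1: 5})
        out = sv.splice(core, StructureMap("AAAA", {}), (8, 4))
        assert out.pair_list() == core.pair_list()

    def test_collision_error(self):
        core = StructureMap("GGGAAACCC", {0: 8})
        sub = StructureMap("GGGAAACCC", {0: 8})
        with pytest.raises(StructureError, match="collision"):
            sv.splice(core, sub, (1, 9))

    def test_union_matches_pair_list_merge(self):
        core = StructureMap("GGAAAAAACCGAAACA", {0: 9, 1: 8})
        sub, _ = reference_fold("GAAAC")
        out = sv.splice(core, sub, (11, 5))
        merged = sorted(core.pair_list() + [(i + 10, j + 10) for i, j in sub.pair_list()])
        assert out.pair_list() == merged


class TestPseudoknotTransfer:
    def test_identity_alignment_keeps_coordinates(self):
        ref = StructureMap("GGGAAACCCAAAG", {}, [(3, 12)])
        target = StructureMap("GGGAAACCCAAAG", {})
        out, unmapped = sv.transfer_pseudoknots(ref, ref.seq, target.seq, target)
        assert out.knots == [(3, 12)] and unmapped == []

    def test_insertion_shifts_coordinates(self):
        ref_row = "--GGGAAACCCAAAG"
        tgt_row = "CCGGGAAACCCAAAG"
        ref = StructureMap("GGGAAACCCAAAG", {}, [(3, 12)])
        target = StructureMap("CCGGGAAACCCAAAG", {})
        out, unmapped = sv.transfer_pseudoknots(ref, ref_row, tgt_row, target)
        assert out.knots == [(5, 14)] and unmapped == []

    def test_deleted_partner_reported_unmapped(self):
        ref_row = "GGGAAACCCAAAG"
        tgt_row = "GGGAAACCCAAA-"
        ref = StructureMap("GGGAAACCCAAAG", {}, [(3, 12)])
        target = StructureMap("GGGAAACCCAAA", {})
        out, unmapped = sv.transfer_pseudoknots(ref, ref_row, tgt_row, target)
        assert out.knots == [] and unmapped == [(4, 13)]  # 1-based report

    def test_row_mismatch_errors(self):
        ref = StructureMap("GGGAAACCC", {})
        target = StructureMap("GGGAAACCC", {})
        with pytest.raises(StructureError):
            sv.transfer_pseudoknots(ref, "GGGAAACCT", "GGGAAACCC", target)


class TestEndToEndToy:
    """Full two-step transfer on a toy molecule with a hairpin backbone, one
    hypervariable window and one pseudoknot."""

    SEQ = "GGGAAACCC" + "TT" + "GGCAAAAGCC" + "TT" + "GAAAC" + "TTTT"
    #      core hairpin  |     hyper 12..21   |    tail hairpin   knot tail

    def test_hand_assembled_expectation(self):
        n = len(self.SEQ)
        hyper = sv.RegionSet([("V1", 12, 10)])
        refs = [
            StructureMap(self.SEQ, {0: 8, 1: 7, 2: 6, 23: 27}, [(9, 30)])
            for _ in range(3)
        ]
        constraint = build_consensus_constraint(
            refs, hyper, knot_pairs=[(10, 31)]
        )
        core, score = reference_fold(self.SEQ, constraint, enforce=True)
        assert {(0, 8), (1, 7), (2, 6), (23, 27)} <= set(core.pair_list())
        assert not any(11 <= i <= 20 or 11 <= j <= 20 for i, j in core.pair_list())
        sub = sv.fold_hypervariable_region(self.SEQ, (12, 10), "internal")
        spliced = sv.splice(core, sub, (12, 10))
        assert {(11, 20), (12, 19)} <= set(spliced.pair_list())
        final, unmapped = sv.transfer_pseudoknots(
            refs[0], self.SEQ, self.SEQ, spliced
        )
        assert final.knots == [(9, 30)] and unmapped == []
        # constraint supremacy end to end: 'x' positions stay unpaired
        for pos, c in enumerate(constraint):
            if c == "x" and not (11 <= pos <= 20):
                assert pos not in final.pairs
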