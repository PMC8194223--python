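# Methods notes

This note records what each component computes, the conventions and numerical
choices behind it, what the synthetic generator does and does not emulate, and
the design decisions taken where more than one reading was defensible.

## Alignment conventions

Rows are uppercase nucleotides over the IUPAC alphabet plus `-`; `U` is
normalised to `T`. All public coordinates are 1-based inclusive alignment
columns. Terminal gap spans (maximal leading/trailing `-` runs) are treated
as missing sequence, not as indels: they are excluded from the gap-percentage
denominator and from site partitions. An all-gap row is flagged degenerate
and its cells counted once, not twice.

*Gap percentage.* `internal gap cells / (total cells − terminal gap cells)`.
`N` counts as sequence data (unknown state), not as a gap; this is the
conservative reading since `N` usually reflects base-calling, not indels.

*Coverage.* Fraction of taxa whose character is neither `-` nor `N`.
Ambiguity codes count toward coverage (they carry partial state information).

*Constant vs variable.* A column is constant when a single state is
compatible with every informative character, where an ambiguity code is
compatible with each of its component states and gaps/`N` are excluded. This
mirrors the ambiguity policy used in the rate estimation, so "constant"
columns are exactly the columns whose relative rate is 1. Columns under the
coverage threshold are a third, explicit class. Note that published summaries
of comparable data sets have quoted constant-site percentages on two slightly
different denominators (all passing columns vs a subtly different base); this
package always uses constant / passing columns.

*Sub-datasets.* Clade subsets are produced by restricting the master
alignment and dropping columns that become gap-only ("subset and compact"),
never by re-aligning; the old→new column map is returned so region
annotations can be projected (`RegionSet.remap` keeps the span of surviving
columns). This is deterministic and exactly invertible on the kept rows.

## TIGER relative rates

The partition of taxa at a column assigns every taxon with an informative
character to the group(s) of its (component) states. Internal gaps are
missing data by default — the molecule-level analyses here provide no gap
character state — but a fifth-state mode (`gap_mode="state"`) is available
for sensitivity analysis; terminal gaps and `N` are always ignored.

Agreement is directional: pa(i, j) asks how well the *other* column's groups
nest inside the focal column's groups, restricted to the focal column's
scored taxa; groups whose restriction is empty are dropped from both
numerator and denominator, and a comparison where every group vanishes is
skipped entirely (the focal column's mean is taken over the remaining
columns). This convention makes constant columns score exactly 1 against
every other column, matching the "high value = slow" reading of the rate
scale. Rates are reported raw (no binning), as mean ± SE with no correction
for the non-independence of paired sites.

The implementation packs taxon sets into 64-bit words; pa over all ordered
column pairs is evaluated as vectorised bit operations, ~O(L²·s·W/64). The
same quantity is recomputed in the test suite by a naive double loop over
plain sets, and the two must agree to 1e-12 on hundreds of random alignments.

*Rolling average.* Centred window (default 35 columns, matching the common
smoothing for such variability tracks), truncated at the series ends,
undefined positions skipped. *Histogram.* Left-closed right-open bins of
width 0.05 by default, so a rate of exactly 1.0 occupies its own bin, plus an
explicit insufficient-coverage bin; counts always total the alignment length.

## Distances

*p distance.* Proportion of differing sites over columns where both rows have
an unambiguous A/C/G/T. Ambiguity codes are treated as missing here (unlike
in the rate estimation) because a fractional-match convention would make the
"distances undefined when sequences do not overlap" rule ambiguous. A pair
with no shared informative column is undefined (`NA` in output) and excluded
from, but counted against, the group summaries.

*GTR distance.* A single Q is estimated on the whole alignment — base
frequencies from empirical counts, exchangeabilities by maximising the
likelihood of the pooled symmetric pair-count matrix under one shared
divergence (Nelder–Mead on log parameters) — and shared across pairs, since
per-pair estimation from two sequences is unstable. Pooling all pairs at a
single shared divergence attenuates the spread of the estimated
exchangeabilities when the data mix very shallow and very deep pairs; the
frequencies are unbiased, the AG/CT transition bias is preserved, and the
resulting distances behave correctly (they equal the Jukes–Cantor closed form
in the equal-rates limit and never fall below p before saturation), which is
what the distance summaries need. Per pair, the branch length maximises
Σ n_ab log(π_a P_ab(t)) with P(t) from the symmetrised eigendecomposition,
by bounded scalar optimisation on t ∈ (0, 20]; an optimum at the bound is
flagged saturated and reported undefined. SE of a group cell is the sample
standard deviation of its defined distances over √count, unweighted by
overlap length.

## Indels and the deletion window

An indel is a maximal gap run in one row of the group alignment. Runs are
split at hypervariable-region boundaries and counted in each region they
touch, which keeps the identity nucleotides + gap columns = region length
exact per region (the alternative majority-overlap assignment is not used).
Terminal-gap-overlapping runs are excluded for the pooled non-hypervariable
region by default (policy `non_hypervariable`; `all`/`none` available),
because incomplete sequences otherwise masquerade as long terminal indels.

The deletion window defaults to the last 14 columns of V3 plus the following
78 columns (92 total), and is fully configurable since its aligned
coordinates depend on the data set. A taxon's motif is the exact set of gap
spans clipped to the window; classes are defined by span coordinates, not
lengths, so convergent equal-length deletions at different positions are
distinct. Class labels are deterministic (sorted by expressed length, then
span coordinates), and detection per taxon is independent of all other rows.

## Structure transfer

The two-step protocol avoids folding a pseudoknotted molecule in one pass.
Step 1 derives a consensus constraint over a common backbone from at least
two reference structure maps: positions paired with the same partner in every
reference → `(`/`)`; consistently unpaired → `x`; disagreement or any
reference gap → `.` (unconstrained). All hypervariable, pseudoknot and other
nested-pairing positions are overridden to `x` so they fold as unresolved
loops first; which positions constitute "nested pairings" is configuration
input, not hard-coded. A consensus pair losing one endpoint to an override
keeps `.` at the surviving endpoint (its pairing status is then genuinely
unknown). Target-only insertions inherit `.` outside and `x` inside
hypervariable regions when the constraint is projected onto a target row.

Step 2 folds each hypervariable region separately inside a bracketing stem of
two forced pairs providing basal context: taken from the adjacent sequence
(V2, V4, V5, V9), from the region's own ends (V1, V6, V7, V8), or appended
artificially and stripped afterwards (V3; the artificial bracket sequence is
configurable, default GG/CC — any strongly pairing frame works since the
bracket never appears in output). For V4 only the 5′ portion ahead of its
pseudoknots is folded (default: the first half; configurable). Sub-structures
are spliced into the core where those regions were held unpaired (a position
paired in both maps is a hard collision error), and pseudoknot pairings are
finally transferred from a reference through a pairwise alignment into a
separate layer that may cross the primary structure; pairs whose partner maps
to a target gap are reported in an unmapped list, never silently dropped.

*Built-in engine.* Base-pair maximisation (Nussinov-style dynamic
programming) with canonical pairs (AU/AT, GC, GU/GT), minimum hairpin loop of
three, hard `x` constraints, and optional strict enforcement of `(`/`)` pairs
(enforced pairs are exempt from the canonical check, since a transferred pair
may be non-canonical in the target). Ties are broken deterministically: the
5′-most position pairs first, with its nearest admissible partner. The engine
trades free-energy realism for exact testability — it is verified against
exhaustive enumeration of all legal structures for short sequences — and the
protocol is engine-agnostic: an adapter for the external RNAfold program
(minimum free energy) implements the same contract for real molecules, where
it is also much faster than the O(n³) reference DP on full-length sequences.

*Vienna I/O.* Multi-layer dot-bracket with `()` for the primary layer and
`[]{}<>` for crossing layers; reading and writing round-trip exactly.

## Statistical battery

Conventions chosen to match how such batteries are conventionally reported:
Wilcoxon W is the sum of positive-difference ranks after dropping zero
differences (both the non-zero and total counts are reported); its Z uses the
tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48, no continuity
correction. Mann–Whitney U is reported as min(U₁, U₂) with the tie-corrected
normal approximation. Kruskal–Wallis H is tie-corrected with a χ²(k−1)
p-value. The 2×2 test is Pearson's without continuity correction — the
convention verified to reproduce the published worked examples to two
decimals. Exact p-values by full enumeration (sign flips / label
combinations) replace the normal approximation below n = 25. Stems and loops
are proxied by paired and unpaired positions of the exemplar structure map;
positions where the exemplar is gapped have no structural assignment and
enter neither sample, and each base pair contributes a single averaged rate
to the stem sample to avoid pseudoreplication. Two-sided tests at nominal
alpha 0.05, no multiple-comparison correction.

## Synthetic data: what it does and does not emulate

The generator produces three clades radiating from a common ancestor (stem
branches 0.36/0.30/0.42 expected substitutions/site, crown branches 0.015),
chosen so that realised divergences land in the regime of interest: ~2%
within clades, ~17–21% between. 60% of sites are invariant; the rest draw
gamma(shape 2) rate multipliers, tripled inside the nine default
hypervariable regions (the V1–V9 layout scaled proportionally into the
simulated length). Substitutions follow a GTR model with a transition bias
(AG and CT exchangeabilities highest). Short deletion-type indels (geometric
lengths, mean 1.5) are injected at ~8× higher per-column rate inside
hypervariable regions; a long deletion anchored at the 3′ end of the
92-column window is expressed in 60% of clade-1 taxa at one of five lengths
(20–68 columns, so no carrier expresses the full window); and 20% of taxa are
terminally truncated to emulate incomplete sequences. Expected p distances
are computed exactly from the realised multipliers and the model's
eigendecomposition — they are predictions, not fitted targets — and the
recovery checks use a ±3 SE band with the single-pair binomial SE
√(p(1−p)/L), which is deliberately generous for means over correlated pairs.

Not emulated: insertion columns (all gaps are deletions on a fixed coordinate
system, keeping truth coordinates exact), compensatory stem covariation,
rate autocorrelation along the molecule, and alignment error. Passing tests
on this generator therefore demonstrate correctness of the computations and
recoverability under the stated conditions, not robustness to misalignment
or to covarying stem evolution.

Default problem sizes used by the test suite and the acceptance script —
60 taxa × 1800 sites for the study conditions, 24 × 600 for shared fixtures,
random alignments up to 20 × 50 against the brute-force rate oracle, and
sequences up to 12 nt against the folding enumeration oracle — were chosen so
each oracle comparison stays exhaustive and the whole suite runs in seconds.

## Known limitations

- GTR exchangeabilities from the pooled single-divergence fit are compressed
  toward 1 on strongly clade-structured data (see above); supply parameters
  via `GTRParams.from_file` when an external estimate is preferred.
- The built-in folding engine maximises pair counts, not free energy; on real
  molecules the RNAfold adapter should be used for the folds themselves,
  with the built-in engine retained for protocol testing.
- Region remapping after subsetting spans the surviving columns of a region;
  if a region's interior columns vanish entirely the region contracts, which
  slightly changes the pooled non-hypervariable complement on heavily gapped
  subsets.
- Exact rank-test p-values enumerate 2^n or C(N, n1) cases and are capped at
  n < 25 by design.
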