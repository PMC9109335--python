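# Methods

## Model

A bi-alignment of two objects *a* and *b*, each given as a residue
sequence plus a same-length per-position structure annotation, is a
4-way alignment `A` with rows (seq a, seq b, struct a, struct b).  Each
column is a pair `(c, d)` of pairwise gap patterns — `c` over rows 1–2
(the sequence alignment `U`), `d` over rows 3–4 (the structure alignment
`V`) — interpreted numerically (letter = 1, gap = 0).  The all-gap
column is excluded, leaving 15 column types; `c = (0,0)` is a column
present only in `V` (an insertion in the column alignment `W`),
`d = (0,0)` one present only in `U`.  Projections remove all-gap
columns of the selected row pair; the self-pairs (1,3) and (2,4) relate
each object's two representations, and an indel column there is a shift
column.  Per column, `|c1−d1| + |c2−d2|` counts the shifted objects, and
summing it over `A` equals the number of indel columns of the two
projected self-alignments — the invariant the test suite asserts on both
enumerated and engine-produced alignments.

The score decomposes column-wise as `u(U) + v(V) + shift`:

* `u`: substitution score for `c = (1,1)` columns, affine gap cost for
  indel columns, 0 for `c = (0,0)`;
* `v`: a flat bonus for equal structure symbols (mismatches score a
  configurable value, 0 by default — a bonus-only model; nothing in the
  scoring ties structure states to positions within an element);
* `shift`: each indel column of a self-pair costs `shift_extend`, plus
  `shift_open` at the start of a run when shifts are affine.

Gap and shift opening is charged whenever an indel column's pattern
differs from the *end column type* of its pair — the gap pattern of the
last non-all-gap column of that projection.  This is Gotoh's three-state
semantics applied per pair: a deletion run directly following an
insertion run opens anew, and the empty alignment counts as ending in a
match column, so leading gaps and shifts pay their opening cost.
Alignments are global; no terminal columns are free.

## Dynamic programs

All four cost models run through one banded DP kernel (numba-compiled).
Cells are `(x1, x2, y1, y2)` prefix lengths of the four rows; a column
`(c, d)` steps from `(x−c, y−d)`.  The state is the tuple of end column
types of the pairs that carry affine opening costs:

| mode         | tracked pairs            | states |
|--------------|--------------------------|--------|
| linear       | none                     | 1      |
| affine_gap   | (1,2), (3,4)             | 9      |
| affine_shift | (1,3), (2,4)             | 9      |
| affine_both  | all four                 | 51     |

The state update keeps a pair's pattern when the column is all-gap in
that pair and overwrites it otherwise.  For the general model the 3⁴ =
81 candidate tuples shrink to the 51 reachable ones; this set is
computed at import time as the closure of the update rule from the
all-match origin state, not hard-coded, and the acceptance script
cross-checks it against exhaustive enumeration (all 23,917 4-way
alignments of a (2,2) instance already realize every reachable tuple).
Untracked pairs are pinned to the match pattern; their opening cost is
zero in the corresponding modes, so this loses nothing.

Banding: the shift limit λ bounds the per-cell displacement of each
sequence against its own structure, `|x1−y1| ≤ λ` and `|x2−y2| ≤ λ`
(cells, not cumulative run lengths; this is what makes the table
O(n²λ²)).  Tables are dense over `(x, offset)` with offsets limited to
the band, i.e. only banded cells are ever allocated.  λ defaults to 2;
`lambda_max=None` removes the band (exact O(n⁴)).

Optimization is lexicographic in (score, −shift count): among
score-co-optimal alignments the engine returns one with the fewest
shift columns ("simpler shifts"), which the suite verifies against the
set of brute-force co-optima.  Remaining ties fall to a fixed column
order — W-match columns before W-indel columns, each group in
descending numeric order — making tracebacks deterministic; the engines
use no randomness anywhere.  Scores are float64; with integer-valued
parameters all arithmetic is exact, so tie detection is too.

## Pairwise aligners

`nw_align` (linear) and `gotoh_align` (affine) are conventional and
double as limit-case oracles for the 4-way engine.  `subadditive_align`
scores each maximal indel run `w(ℓ) = a + bℓ + c·ln ℓ` (natural log,
`w(1) = a + b`, length-only with a hook for custom run costs) in two
independent formulations: direct jumps over whole runs (correct when one
long run never scores worse than two shorter ones covering it, i.e.
`a ≤ 0`, `c ≤ 0`, `|c| ≤ −a/ln 2`), and run-length-annotated end states
`⟨p, ℓ⟩` whose per-column increment `w(ℓ) − w(ℓ−1)` telescopes to
`w(ℓ)` over a run and is exact for arbitrary run costs.  The run-length
recursion maximizes over all `ℓ ≥ 1` and all `p' ≠ p` when a run
switches.  Both are cubic time; the run-length variant also cubic
space.  The 4-index sub-additive bi-alignment generalization is out of
scope.

## Oracle and fixtures

The brute-force oracle enumerates every column sequence spelling the
inputs and scores each candidate by scanning maximal runs on the four
projections — no DP, no state tables — so any disagreement with the
engine localizes the bug.  Enumeration counts grow fast (75 alignments
for lengths (1,1); 23,917 for (2,2); 401,679 for (3,2); 10,681,263 for
(3,3)), so the oracle refuses instances beyond a candidate cap and the
equivalence suite samples lengths 0–3 while rejecting pairs that exceed
25,000 candidates: the tractable envelope keeps (2,2) and (3,1) but not
(3,2) or (3,3).  The 200-instance sweep scores all four modes from one
projection scan per candidate.

The fixture generator emulates incongruent evolution in its simplest
detectable form: b's sequence is a's with point substitutions (rate 0.1)
and b's structure annotation is a's with one contiguous block displaced
by a small magnitude, the vacated hole filled with the coil state.  The
planted 4-way alignment (identity `U`, one insertion/deletion pair of
the implanted magnitude in `V`) is constructed explicitly, giving an
exact planted score the engine's optimum must reach.

Default conditions: length 60, structure runs of 2–4 states, block
length 16, one shift of magnitude 1, λ = 2, scored with BLOSUM62,
structure bonus 800, gaps −200/−50, shift −210.  Two properties of the
scoring landscape drove these choices.  First, a magnitude-k
displacement of run-structured annotation is only visible where the
block crosses run boundaries (~k mismatched positions per boundary), so
detectability requires a boundary-dense block; real secondary-structure
elements are longer, which means real magnitude-1 helix shifts can be
score-invisible — a genuine property of the bonus-only structure score,
not of the implementation.  Second, for magnitude ≥ 2 under the
demonstration parameters an ordinary explanation that gaps `U` and `V`
jointly (cost 4 openings + 2k extensions + a small sequence-identity
loss) undercuts the shift explanation (2 openings + 2k·(extension +
shift)), so the engine correctly prefers it; magnitude 1 is the regime
where the shift event is the uniquely optimal explanation.  Passing the
recovery suite therefore shows the engines find planted shifts when
shifts are optimal — it does not calibrate shift costs for real
proteins, which remains an open modeling question.

## Numerical and scale choices

* Origin cell: all-match state 0, every other state −∞; unreachable
  cells stay −∞ and tracebacks refuse to cross them.
* The traceback encodes (column type, predecessor state) per cell-state;
  corrupt or truncated tables raise instead of returning garbage.
* Problem sizes in the suite: exhaustive equivalence at lengths ≤ 3
  (200 instances, all modes), reductions on 100 instances each,
  recovery on 100 seeded fixtures of length 60, and one 300-residue
  banded run (λ = 2, affine_gap, 9 states ≈ 2.3M cells) as the
  medium-scale check.
* Kernel state/transition/fixed-cost tables are precomputed per
  (mode, parameters) and cached; the substitution and structure score
  matrices are materialized per call (n₁×n₂ float64).

## Known limitations

* The structure score is position-independent (flat bonus); scoring that
  distinguishes positions within an element would change where shifts
  are optimal.
* Local or semi-global variants, banding on ordinary indels, and
  poly-alignments of more than two representations are not implemented.
* The fixture generator does not simulate indels between the two
  sequences, realistic amino-acid composition, or structure prediction;
  conclusions from the synthetic suite transfer to real data only where
  the shift signal is strong enough to dominate, as discussed above.
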