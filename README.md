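# bialignment

Exact bi-alignments of biopolymers: joint sequence- and structure-based
alignment with explicit, affine-cost **shift events**.

## The problem

Sequence elements and structural features usually evolve congruently, so
one alignment can represent both similarity relations at once.
Occasionally they do not: a conserved secondary-structure element can
*slide* against its underlying sequence (helix shifts in protein
evolution, intron sliding, binding-site turnover).  Under such
incongruent evolution no single pairwise alignment is right — a
sequence-optimal alignment misplaces the structure and a
structure-optimal alignment destroys sequence similarity.

A **bi-alignment** `A ≅ (U, V, W)` resolves this by aligning two
alignments of the same objects *a* and *b*: a sequence alignment `U`, a
structure alignment `V` (one annotation symbol per residue, e.g.
H/E/T/C secondary-structure states), and an alignment `W` of the columns
of `U` with the columns of `V`.  Equivalently, `A` is a 4-way alignment
with rows (seq a, seq b, struct a, struct b); `U` and `V` are its
projections onto rows (1,2) and (3,4).  The projections onto rows (1,3)
and (2,4) are self-alignments of each object; an indel column there
means that object's structure is displaced against its own sequence —
a shift event.  Writing `(c1,c2)` and `(d1,d2)` for the numeric gap
patterns (letter = 1, gap = 0) of a column's U part and V part, the
column shifts

    s(α) = |c1 − d1| + |c2 − d2|            (0, 1 or 2 objects)

objects, and the total shift count of `A` equals the number of indel
columns in the two projected self-alignments.  The optimization problem
is

    max  score(A) = u(U) + v(V) + w(W)

with residue similarity in `u` (substitution matrix), structure
similarity in `v` (match bonus), and shift penalties in `w`.

## What the package computes

* `bialign(seq_a, seq_b, str_a, str_b, cfg)` — globally optimal
  bi-alignment under four cost models (`cfg.mode`):
  * `linear` — every gap and shift column costs its extension score;
  * `affine_gap` — affine gaps in `U` and `V` (run of length ℓ costs
    `gap_open + ℓ·gap_extend`), linear shifts; the DP tracks the 9
    end-column-type pairs (p, q) of `U` and `V` and evaluates 15 column
    types per cell;
  * `affine_shift` — affine shifts, linear gaps (tracks the self-pairs);
  * `affine_both` — both affine; the state is the 4-tuple
    `(p12, p13, p24, p34)` of end column types of all tracked row pairs,
    restricted to the 51 (of 3⁴ = 81) tuples reachable in valid
    bi-alignments, computed constructively at import time.
* Shift banding: only cells with `|x1−y1| ≤ λ` and `|x2−y2| ≤ λ` are
  expanded (each sequence can slide at most λ positions against its own
  structure), giving O(n²λ²) time and space; `lambda_max=None` runs the
  exact O(n⁴) recursion.  Ties are resolved to the fewest shift events.
* Reference pairwise aligners: Needleman–Wunsch, Gotoh, and sub-additive
  run costs `w(ℓ) = a + bℓ + c·ln ℓ` in two independent formulations.
* A brute-force enumeration oracle and a synthetic fixture generator
  with implanted, known shifts (used heavily by the test suite).
* A CLI (`bialignment`) reading FASTA sequences + FASTA-like structure
  strings and any NCBI-format substitution matrix (BLOSUM62 packaged as
  the default).

## Worked example

Align a synthetic pair with one implanted structure shift:

```sh
bialignment --seed-fixture 1
```

```
score:       46547
shift count: 2

shifts synthetic-a                                   >                    <
struct synthetic-a  CCCCHHHEEEETTTCCEEEECCCCTTTHHHCCCCHHCCCEEECCEETTTTCCCC-TTTCC
seq    synthetic-a  FWDKESRSPHESAPQYARKIWEMAAAVAPHQAT-IRSVINIIRLAQVEGLEMTQTHLLWS
seq    synthetic-b  FHDKESRSPHESVPQYANKIWEMAAAVAIHQAW-IRSVIAIIRLAQVEGLEMTQTHLLWS
struct synthetic-b  CCCCHHHEEEETTTCCEEEECCCCTTTHHHCCC-HHCCCEEECCEETTTTCCCCCTTTCC
shifts synthetic-b
```

The score (46547) is the sum of the sequence-alignment term `u`, the
structure-alignment term `v` and the shift term
(`--output json` prints the decomposition: u = 267, v = 46700,
shift = −420).  Two columns are shift events (`shift count: 2`, at
−210 each): between the `>` and `<` marks, object a's structure is
displaced by one position against its own sequence, which lets both the
sequences and the structures align well everywhere else — the
incongruence is explained instead of being averaged away.

Default parameters are the demonstration setting: BLOSUM62, structure
match bonus 800, gap opening/extension −200/−50, shift cost −210 per
column, λ = 2.  All of them are flags (`--gap-open`, `--shift`,
`--max-shift`, ...), and `--output json|tsv` gives machine-readable
results including the four gapped rows and per-column codes.

Library use:

```python
from bialignment import ScoringConfig, bialign, read_matrix

cfg = ScoringConfig(substitution=read_matrix(), lambda_max=2, mode="affine_gap")
res = bialign(seq_a, seq_b, struct_a, struct_b, cfg)
res.score, res.alignment.shift_count, res.alignment.project("U")
```

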