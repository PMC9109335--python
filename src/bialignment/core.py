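"""Core domain model for bi-alignments.

A bi-alignment reconciles two different pairwise alignments of the same
two biopolymers: a *sequence* alignment U (scored by residue similarity)
and a *structure* alignment V (scored by similarity of per-position
structure annotations, e.g. secondary-structure states H/E/T/C).  It is
represented as a single 4-way alignment whose rows are

    row 1: sequence of a        row 3: structure string of a
    row 2: sequence of b        row 4: structure string of b

U is the projection onto rows (1,2), V the projection onto rows (3,4).
The projections onto rows (1,3) and (2,4) are self-alignments of a and of
b; an indel column there means the object's structure has been displaced
against its own sequence -- a *shift event*.  Per column the number of
shifted objects is ``|c1-d1| + |c2-d2|`` where ``(c1,c2)`` / ``(d1,d2)``
are the numeric gap patterns (letter=1, gap=0) of the U part and the V
part of the column.

This module holds the column/state types, the column-wise scoring rule
(with affine gap opening charged against the *end column type* -- the gap
pattern of the last non-all-gap column of each tracked pair), projections
and independent rescoring helpers.  The dynamic programs live in
:mod:`bialignment.engine`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "Pattern",
    "MATCH",
    "DELETION",
    "INSERTION",
    "ALL_GAP",
    "END_PATTERNS",
    "Column4",
    "COLUMN_TYPES",
    "EndState",
    "INITIAL_STATE",
    "END_STATES_UV",
    "SubstitutionTable",
    "ScoringConfig",
    "BiAlignment",
    "BiAlignmentError",
    "InputError",
    "RecordCountError",
    "LengthMismatchError",
    "UnknownSymbolError",
    "MatrixFormatError",
    "InvalidColumnError",
    "shift_contribution",
    "shift_count",
    "column_score",
    "project",
    "score_bialignment",
    "score_pairwise_patterns",
    "decompose",
]

Pattern = tuple[int, int]

MATCH: Pattern = (1, 1)
DELETION: Pattern = (1, 0)
INSERTION: Pattern = (0, 1)
ALL_GAP: Pattern = (0, 0)

#: Gap patterns that can end a projected pairwise alignment (all-gap columns
#: are removed by projection, so they never end one).
END_PATTERNS: tuple[Pattern, ...] = (MATCH, DELETION, INSERTION)


class BiAlignmentError(Exception):
    """Base class for all errors raised by this package."""


class InputError(BiAlignmentError, ValueError):
    """Invalid user input (sequences, structures, matrices, parameters)."""


class RecordCountError(InputError):
    """A FASTA input did not contain exactly the expected number of records."""


class LengthMismatchError(InputError):
    """A structure string does not match the length of its sequence."""


class UnknownSymbolError(InputError):
    """A residue symbol is not covered by the active substitution matrix."""


class MatrixFormatError(InputError):
    """A substitution matrix file could not be parsed."""


class InvalidColumnError(InputError):
    """An all-gap 4-way column, which cannot occur in a valid bi-alignment."""


class Column4(NamedTuple):
    """A 4-row bi-alignment column: ``c`` covers rows 1-2, ``d`` rows 3-4.

    ``c == ALL_GAP`` is an insertion in W (a column present only in V);
    ``d == ALL_GAP`` a deletion in W.  Both all-gap at once is invalid,
    leaving 15 distinct values (see :data:`COLUMN_TYPES`).
    """

    c: Pattern
    d: Pattern

    @property
    def p12(self) -> Pattern:
        return self.c

    @property
    def p34(self) -> Pattern:
        return self.d

    @property
    def p13(self) -> Pattern:
        """Gap pattern of the column in the self-alignment of object a."""
        return (self.c[0], self.d[0])

    @property
    def p24(self) -> Pattern:
        """Gap pattern of the column in the self-alignment of object b."""
        return (self.c[1], self.d[1])

    @property
    def shift(self) -> int:
        """Number of objects shifted in this column: ``|c1-d1| + |c2-d2|``."""
        return abs(self.c[0] - self.d[0]) + abs(self.c[1] - self.d[1])

    @property
    def deltas(self) -> tuple[int, int, int, int]:
        """Prefix-length increments ``(x1, x2, y1, y2)`` consumed by the column."""
        return (self.c[0], self.c[1], self.d[0], self.d[1])

    def code(self) -> str:
        """Four-digit numeric code, rows top to bottom, e.g. ``\"1101\"``."""
        return f"{self.c[0]}{self.c[1]}{self.d[0]}{self.d[1]}"


def _ordered_column_types() -> tuple[Column4, ...]:
    # Canonical (traceback tie-breaking) order: columns that are matches in W
    # (neither part all-gap) before W-indel columns; within each group,
    # descending lexicographic on the numeric 4-tuple, so the all-match
    # column comes first overall.
    matches = [
        Column4(c, d)
        for c in END_PATTERNS
        for d in END_PATTERNS
    ]
    indels = [Column4(c, ALL_GAP) for c in END_PATTERNS]
    indels += [Column4(ALL_GAP, d) for d in END_PATTERNS]
    key = lambda col: col.deltas
    return tuple(sorted(matches, key=key, reverse=True)) + tuple(
        sorted(indels, key=key, reverse=True)
    )


#: The 15 valid 4-way column types in canonical order.
COLUMN_TYPES: tuple[Column4, ...] = _ordered_column_types()

_COLUMN_INDEX: dict[Column4, int] = {col: i for i, col in enumerate(COLUMN_TYPES)}


class EndState(NamedTuple):
    """End column types of the four tracked pairwise projections.

    ``p12``/``p34`` are the end column types of U and V (variant A of the
    DP state, 9 combinations); adding ``p13``/``p24`` (the self-alignment
    pairs) gives the general variant-B state used when shift costs are
    affine.  Of the 3^4 = 81 candidate tuples only a subset is reachable
    in valid bi-alignments (see :func:`bialignment.engine.reachable_states`).
    """

    p12: Pattern
    p13: Pattern
    p24: Pattern
    p34: Pattern

    def update(self, col: Column4) -> "EndState":
        """State after appending ``col``: pairs untouched by the column
        (all-gap in that pair) keep their previous end column type."""
        new = (col.p12, col.p13, col.p24, col.p34)
        return EndState(
            *(n if n != ALL_GAP else o for n, o in zip(new, self))
        )

    @classmethod
    def from_uv(cls, p: Pattern, q: Pattern) -> "EndState":
        """Variant-A state (p, q): end column types of U and V only."""
        return cls(p, MATCH, MATCH, q)


#: State of the empty bi-alignment: every pair ends in a (virtual) match
#: column, so leading gaps and shifts are charged their opening cost.
INITIAL_STATE = EndState(MATCH, MATCH, MATCH, MATCH)

#: The 9 variant-A end states (p, q).
END_STATES_UV: tuple[EndState, ...] = tuple(
    EndState.from_uv(p, q) for p in END_PATTERNS for q in END_PATTERNS
)


@dataclass(frozen=True)
class SubstitutionTable:
    """Residue-pair similarity lookup.

    A thin immutable wrapper over a ``(sym, sym) -> score`` mapping with a
    defined alphabet; unknown symbols raise :class:`UnknownSymbolError`.
    """

    scores: Mapping[tuple[str, str], float]
    alphabet: tuple[str, ...]
    name: str = ""

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            unknown = [s for s in (a, b) if s not in self.alphabet]
            raise UnknownSymbolError(
                f"symbol(s) {unknown!r} not covered by matrix "
                f"{self.name or '<anonymous>'}"
            ) from None

    __call__ = score

    def is_symmetric(self) -> bool:
        return all(
            self.scores.get((a, b)) == self.scores.get((b, a))
            for a in self.alphabet
            for b in self.alphabet
        )

    @classmethod
    def from_dict(
        cls, scores: Mapping[tuple[str, str], float], name: str = ""
    ) -> "SubstitutionTable":
        alphabet = tuple(sorted({s for pair in scores for s in pair}))
        return cls(dict(scores), alphabet, name)

    @classmethod
    def match_mismatch(
        cls, alphabet: str = "AB", match: float = 1.0, mismatch: float = -1.0
    ) -> "SubstitutionTable":
        scores = {
            (a, b): (match if a == b else mismatch)
            for a in alphabet
            for b in alphabet
        }
        return cls(scores, tuple(alphabet), f"match/mismatch({match},{mismatch})")


#: Cost models understood by the engines.  ``subadditive_pairwise`` applies
#: only to :func:`bialignment.pairwise.subadditive_align`.
MODES = ("linear", "affine_gap", "affine_shift", "affine_both", "subadditive_pairwise")


@dataclass(frozen=True)
class ScoringConfig:
    """All scoring parameters of a bi-alignment problem.

    Every parameter is a signed score contribution: penalties are negative.
    Defaults follow the protein demonstration setting: BLOSUM62 residue
    similarity, a flat bonus of 800 for matched structure states, gap
    opening/extension -200/-50, shift cost -210 per shift column, and a
    shift limit (band half-width) of lambda = 2.

    ``mode`` selects which costs are affine: ``linear`` charges neither
    opening cost, ``affine_gap`` only ``gap_open``, ``affine_shift`` only
    ``shift_open``, ``affine_both`` both.
    """

    substitution: SubstitutionTable | None = None
    structure_match: float = 800.0
    structure_mismatch: float = 0.0
    gap_open: float = -200.0
    gap_extend: float = -50.0
    shift_extend: float = -210.0
    shift_open: float = 0.0
    lambda_max: int | None = 2
    mode: str = "affine_gap"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InputError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.lambda_max is not None and self.lambda_max < 0:
            raise InputError("lambda_max must be >= 0 (or None for unbanded)")

    @property
    def gap_open_effective(self) -> float:
        """Gap opening cost actually charged under the selected mode."""
        if self.mode in ("affine_gap", "affine_both", "subadditive_pairwise"):
            return self.gap_open
        return 0.0

    @property
    def shift_open_effective(self) -> float:
        """Shift opening cost actually charged under the selected mode."""
        if self.mode in ("affine_shift", "affine_both"):
            return self.shift_open
        return 0.0


Seqs = tuple[str, str, str, str]  # (seq_a, seq_b, str_a, str_b)


def shift_contribution(col: Column4, cfg: ScoringConfig) -> float:
    """Linear shift score of one column: ``shift_extend * (|c1-d1|+|c2-d2|)``.

    An all-gap U part (or V part) contributes through its zeros: an indel
    in W always shifts.  Affine shift *opening* is charged separately in
    :func:`column_score`.
    """
    if col.c == ALL_GAP and col.d == ALL_GAP:
        raise InvalidColumnError("the all-gap 4-way column is not a valid column")
    return cfg.shift_extend * col.shift


def column_score(
    x: tuple[int, int],
    y: tuple[int, int],
    prev: EndState,
    col: Column4,
    seqs: Seqs,
    cfg: ScoringConfig,
) -> float:
    """Score of a single bi-alignment column.

    ``x = (x1, x2)`` and ``y = (y1, y2)`` are the prefix lengths (1-based
    residue indexing, 0 = empty prefix) *after* the column in U and V
    respectively; ``prev`` is the end state before the column.  The score
    is the sum of the U contribution (substitution for matches, affine gap
    cost for indels, 0 for an all-gap part), the analogous V contribution
    (structure match/mismatch), and the shift contribution of the pairs
    (1,3) and (2,4).  Opening costs are charged whenever an indel pattern
    differs from the stored previous pattern of its pair.
    """
    seq_a, seq_b, str_a, str_b = seqs
    c, d = col.c, col.d
    if c == ALL_GAP and d == ALL_GAP:
        raise InvalidColumnError("the all-gap 4-way column is not a valid column")
    total = 0.0
    if c == MATCH:
        if not (1 <= x[0] <= len(seq_a) and 1 <= x[1] <= len(seq_b)):
            raise InputError(f"U indices {x} out of range")
        if cfg.substitution is None:
            raise InputError("ScoringConfig.substitution is not set")
        total += cfg.substitution.score(seq_a[x[0] - 1], seq_b[x[1] - 1])
    elif c != ALL_GAP:
        total += cfg.gap_extend + (cfg.gap_open_effective if prev.p12 != c else 0.0)
    if d == MATCH:
        if not (1 <= y[0] <= len(str_a) and 1 <= y[1] <= len(str_b)):
            raise InputError(f"V indices {y} out of range")
        total += (
            cfg.structure_match
            if str_a[y[0] - 1] == str_b[y[1] - 1]
            else cfg.structure_mismatch
        )
    elif d != ALL_GAP:
        total += cfg.gap_extend + (cfg.gap_open_effective if prev.p34 != d else 0.0)
    for pat, prev_pat in ((col.p13, prev.p13), (col.p24, prev.p24)):
        if pat in (DELETION, INSERTION):
            total += cfg.shift_extend + (
                cfg.shift_open_effective if prev_pat != pat else 0.0
            )
    return total


_PROJECTIONS: dict[str, Callable[[Column4], Pattern]] = {
    "U": lambda col: col.p12,
    "V": lambda col: col.p34,
    "aa": lambda col: col.p13,
    "bb": lambda col: col.p24,
}


@dataclass
class BiAlignment:
    """A 4-way bi-alignment together with its inputs and score.

    ``columns`` spell the inputs row by row; removing the columns whose
    U part (V part) is all-gap yields the sequence alignment U (structure
    alignment V).  ``score`` is the total under the :class:`ScoringConfig`
    that produced the alignment.
    """

    columns: list[Column4]
    seq_a: str
    seq_b: str
    str_a: str
    str_b: str
    score: float = 0.0

    @property
    def seqs(self) -> Seqs:
        return (self.seq_a, self.seq_b, self.str_a, self.str_b)

    def validate(self) -> None:
        """Check that the columns spell exactly the four input rows."""
        need = (len(self.seq_a), len(self.seq_b), len(self.str_a), len(self.str_b))
        got = [0, 0, 0, 0]
        for col in self.columns:
            if col not in _COLUMN_INDEX:
                raise InvalidColumnError(f"invalid column {col!r}")
            for i, inc in enumerate(col.deltas):
                got[i] += inc
        if tuple(got) != need:
            raise InputError(f"columns consume {tuple(got)}, inputs have {need}")
        if len(self.seq_a) != len(self.str_a) or len(self.seq_b) != len(self.str_b):
            raise LengthMismatchError("structure strings must match sequence lengths")

    @property
    def shift_count(self) -> int:
        """Total number of shift columns, summed over both objects."""
        return sum(col.shift for col in self.columns)

    def shift_positions(self) -> tuple[set[int], set[int]]:
        """0-based sequence positions touched by shift columns, per object.

        For a shift column of object a (an indel in the projected
        self-alignment, rows 1 and 3) the touched position is the residue
        or structure symbol the column consumes; analogously for b.
        """
        pos_a: set[int] = set()
        pos_b: set[int] = set()
        x1 = x2 = y1 = y2 = 0
        for col in self.columns:
            dx1, dx2, dy1, dy2 = col.deltas
            x1 += dx1
            x2 += dx2
            y1 += dy1
            y2 += dy2
            if col.p13 in (DELETION, INSERTION):
                pos_a.add(max(x1, y1) - 1)
            if col.p24 in (DELETION, INSERTION):
                pos_b.add(max(x2, y2) - 1)
        return pos_a, pos_b

    def end_coordinates(self) -> tuple[int, int, int, int]:
        return (len(self.seq_a), len(self.seq_b), len(self.str_a), len(self.str_b))

    def end_state(self) -> EndState:
        state = INITIAL_STATE
        for col in self.columns:
            state = state.update(col)
        return state

    def rows(self) -> tuple[str, str, str, str]:
        """The four gapped rows (seq a, seq b, struct a, struct b)."""
        out = []
        for row_string, selector in (
            (self.seq_a, lambda col: col.c[0]),
            (self.seq_b, lambda col: col.c[1]),
            (self.str_a, lambda col: col.d[0]),
            (self.str_b, lambda col: col.d[1]),
        ):
            chars = []
            pos = 0
            for col in self.columns:
                if selector(col):
                    chars.append(row_string[pos])
                    pos += 1
                else:
                    chars.append("-")
            out.append("".join(chars))
        return tuple(out)  # type: ignore[return-value]

    def project_patterns(self, which: str) -> list[Pattern]:
        """Gap patterns of the projected pairwise alignment (all-gap columns
        removed); ``which`` is one of U, V, aa, bb."""
        try:
            sel = _PROJECTIONS[which]
        except KeyError:
            raise InputError(f"unknown projection {which!r}; expected U, V, aa or bb")
        return [sel(col) for col in self.columns if sel(col) != ALL_GAP]

    def project(self, which: str) -> tuple[str, str]:
        """The projected pairwise alignment as two gapped row strings."""
        rows = self.rows()
        pair = {"U": (0, 1), "V": (2, 3), "aa": (0, 2), "bb": (1, 3)}
        try:
            i, j = pair[which]
        except KeyError:
            raise InputError(f"unknown projection {which!r}; expected U, V, aa or bb")
        top, bottom = rows[i], rows[j]
        keep = [k for k in range(len(top)) if top[k] != "-" or bottom[k] != "-"]
        return "".join(top[k] for k in keep), "".join(bottom[k] for k in keep)


def shift_count(ba: BiAlignment) -> int:
    """Number of shift columns; equals the indel counts of the projected
    self-alignments of a and of b added together."""
    return ba.shift_count


def project(ba: BiAlignment, which: str) -> tuple[str, str]:
    """Extract a pairwise alignment (U, V, aa or bb) from a bi-alignment."""
    return ba.project(which)


def score_bialignment(ba: BiAlignment, cfg: ScoringConfig) -> float:
    """Rescore a bi-alignment column by column (the Eq.-5-style walk).

    Independent of the DP engines; used to verify that an engine's optimum
    really is the score of the alignment it returns.
    """
    state = INITIAL_STATE
    x1 = x2 = y1 = y2 = 0
    total = 0.0
    for col in ba.columns:
        dx1, dx2, dy1, dy2 = col.deltas
        x1 += dx1
        x2 += dx2
        y1 += dy1
        y2 += dy2
        total += column_score((x1, x2), (y1, y2), state, col, ba.seqs, cfg)
        state = state.update(col)
    if (x1, x2, y1, y2) != ba.end_coordinates():
        raise InputError("columns do not spell the inputs")
    return total


def score_pairwise_patterns(
    patterns: Sequence[Pattern],
    match_score: Callable[[int, int], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Score a pairwise alignment given as a gap-pattern list.

    Match columns are scored by ``match_score(i, j)`` on 0-based positions;
    each maximal run of one indel pattern costs ``gap_open + len *
    gap_extend`` (a deletion run directly following an insertion run opens
    anew).  Leading runs are charged the opening cost.
    """
    i = j = 0
    prev: Pattern = MATCH
    total = 0.0
    for pat in patterns:
        if pat == MATCH:
            total += match_score(i, j)
            i += 1
            j += 1
        elif pat == DELETION:
            total += gap_extend + (gap_open if prev != DELETION else 0.0)
            i += 1
        elif pat == INSERTION:
            total += gap_extend + (gap_open if prev != INSERTION else 0.0)
            j += 1
        else:
            raise InvalidColumnError("all-gap column in a projected alignment")
        prev = pat
    return total


def decompose(ba: BiAlignment, cfg: ScoringConfig) -> dict[str, float]:
    """Score decomposition ``u(U) + v(V) + shift`` recomputed from the
    projections (independently of any DP and of the column walk)."""
    if cfg.substitution is None:
        raise InputError("ScoringConfig.substitution is not set")
    sub = cfg.substitution
    u = score_pairwise_patterns(
        ba.project_patterns("U"),
        lambda i, j: sub.score(ba.seq_a[i], ba.seq_b[j]),
        cfg.gap_open_effective,
        cfg.gap_extend,
    )
    v = score_pairwise_patterns(
        ba.project_patterns("V"),
        lambda i, j: (
            cfg.structure_match
            if ba.str_a[i] == ba.str_b[j]
            else cfg.structure_mismatch
        ),
        cfg.gap_open_effective,
        cfg.gap_extend,
    )
    shift = 0.0
    for which in ("aa", "bb"):
        shift += score_pairwise_patterns(
            ba.project_patterns(which),
            lambda i, j: 0.0,
            cfg.shift_open_effective,
            cfg.shift_extend,
        )
    return {"u": u, "v": v, "shift": shift, "total": u + v + shift}
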