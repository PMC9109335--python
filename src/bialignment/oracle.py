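"""Brute-force enumeration oracle for bi-alignments of tiny inputs.

The oracle enumerates *every* sequence of 4-way column types whose rows
spell the inputs and scores each candidate directly from its projections
(maximal gap and shift runs scanned on the projected pairwise alignments
-- no dynamic programming, no state tables).  Any disagreement with
:func:`bialignment.engine.bialign` therefore localizes a bug in the DP.

Enumeration is exponential; :func:`alignment_count` (an independent
closed recurrence for the number of multi-way alignments) is used as a
guard rail against accidentally huge inputs.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from typing import Iterator, Sequence

from .core import (
    ALL_GAP,
    BiAlignment,
    COLUMN_TYPES,
    Column4,
    InputError,
    LengthMismatchError,
    Pattern,
    ScoringConfig,
    score_pairwise_patterns,
)

__all__ = [
    "alignment_count",
    "enumerate_bialignment_columns",
    "enumerate_pairwise_patterns",
    "score_pairwise_runs",
    "brute_force_pairwise",
    "score_columns",
    "score_all_modes",
    "brute_force_bialign",
]

#: Default ceiling on the number of candidate alignments the oracle will
#: enumerate for one instance.
DEFAULT_MAX_ALIGNMENTS = 200_000


@lru_cache(maxsize=None)
def _count(lengths: tuple[int, ...]) -> int:
    if all(n == 0 for n in lengths):
        return 1
    total = 0
    for step in product((0, 1), repeat=len(lengths)):
        if not any(step):
            continue
        rest = tuple(n - s for n, s in zip(lengths, step))
        if any(n < 0 for n in rest):
            continue
        total += _count(rest)
    return total


def alignment_count(*lengths: int) -> int:
    """Number of multi-way alignments of sequences with the given lengths.

    Counts column sequences over all non-empty gap patterns; for a
    bi-alignment of a pair with lengths ``(n1, n2)`` call
    ``alignment_count(n1, n2, n1, n2)``.
    """
    if any(n < 0 for n in lengths):
        raise InputError("lengths must be non-negative")
    return _count(tuple(lengths))


def enumerate_bialignment_columns(
    n1: int, n2: int, max_alignments: int = DEFAULT_MAX_ALIGNMENTS
) -> Iterator[tuple[Column4, ...]]:
    """Yield every valid 4-way column sequence for row lengths (n1, n2, n1, n2).

    Raises :class:`InputError` when the enumeration would exceed
    ``max_alignments`` candidates (the guard rail for the exponential
    search space).
    """
    total = alignment_count(n1, n2, n1, n2)
    if total > max_alignments:
        raise InputError(
            f"refusing to enumerate {total} bi-alignments for lengths "
            f"({n1}, {n2}); limit is {max_alignments}"
        )
    path: list[Column4] = []

    def walk(x1: int, x2: int, y1: int, y2: int) -> Iterator[tuple[Column4, ...]]:
        if x1 == n1 and x2 == n2 and y1 == n1 and y2 == n2:
            yield tuple(path)
            return
        for col in COLUMN_TYPES:
            dx1, dx2, dy1, dy2 = col.deltas
            a, b, c, d = x1 + dx1, x2 + dx2, y1 + dy1, y2 + dy2
            if a <= n1 and b <= n2 and c <= n1 and d <= n2:
                path.append(col)
                yield from walk(a, b, c, d)
                path.pop()

    return walk(0, 0, 0, 0)


def enumerate_pairwise_patterns(
    n1: int, n2: int, max_alignments: int = DEFAULT_MAX_ALIGNMENTS
) -> Iterator[tuple[Pattern, ...]]:
    """Yield every pairwise alignment of lengths (n1, n2) as a pattern tuple."""
    total = alignment_count(n1, n2)
    if total > max_alignments:
        raise InputError(
            f"refusing to enumerate {total} pairwise alignments; "
            f"limit is {max_alignments}"
        )
    steps = ((1, 1), (1, 0), (0, 1))
    path: list[Pattern] = []

    def walk(i: int, j: int) -> Iterator[tuple[Pattern, ...]]:
        if i == n1 and j == n2:
            yield tuple(path)
            return
        for step in steps:
            a, b = i + step[0], j + step[1]
            if a <= n1 and b <= n2:
                path.append(step)
                yield from walk(a, b)
                path.pop()

    return walk(0, 0)


def score_pairwise_runs(patterns, match_score, run_cost) -> float:
    """Score a pairwise alignment with an arbitrary per-run gap cost.

    ``match_score(i, j)`` scores match columns on 0-based positions;
    every maximal run of one indel pattern of length l costs
    ``run_cost(l)``.  Covers the linear (``run_cost = l*g``), affine
    (``open + l*ext``) and sub-additive models with one code path that is
    independent of all the aligners' DPs.
    """
    i = j = 0
    total = 0.0
    run_len = 0
    run_pat: Pattern | None = None
    for pat in patterns:
        if pat != run_pat and run_len:
            total += run_cost(run_len)
            run_len = 0
        if pat == (1, 1):
            total += match_score(i, j)
            i += 1
            j += 1
            run_pat = None
        else:
            run_pat = pat
            run_len += 1
            i += pat[0]
            j += pat[1]
    if run_len:
        total += run_cost(run_len)
    return total


def brute_force_pairwise(
    a: str,
    b: str,
    match_score,
    run_cost,
    max_alignments: int = DEFAULT_MAX_ALIGNMENTS,
) -> float:
    """Exhaustively optimal pairwise alignment score for tiny inputs."""
    return max(
        score_pairwise_runs(p, match_score, run_cost)
        for p in enumerate_pairwise_patterns(len(a), len(b), max_alignments)
    )


def _pair_stats(
    patterns: Sequence[Pattern],
) -> tuple[list[tuple[int, int]], list[int]]:
    """Match positions and maximal-run lengths of a projected alignment.

    Returns the (i, j) 0-based position pairs of match columns and the
    lengths of the maximal indel runs (a run ends when the pattern
    changes, including deletion -> insertion switches).
    """
    matches: list[tuple[int, int]] = []
    runs: list[int] = []
    i = j = 0
    prev: Pattern | None = None
    for pat in patterns:
        if pat == (1, 1):
            matches.append((i, j))
            i += 1
            j += 1
        elif pat == ALL_GAP:
            raise InputError("all-gap column in a projected alignment")
        else:
            if pat == prev:
                runs[-1] += 1
            else:
                runs.append(1)
            i += pat[0]
            j += pat[1]
        prev = pat
    return matches, runs


def score_columns(
    columns: Sequence[Column4],
    seq_a: str,
    seq_b: str,
    str_a: str,
    str_b: str,
    cfg: ScoringConfig,
) -> float:
    """Score one candidate bi-alignment directly from its projections."""
    ba = BiAlignment(list(columns), seq_a, seq_b, str_a, str_b)
    if cfg.substitution is None:
        raise InputError("ScoringConfig.substitution is not set")
    sub = cfg.substitution
    total = score_pairwise_patterns(
        ba.project_patterns("U"),
        lambda i, j: sub.score(seq_a[i], seq_b[j]),
        cfg.gap_open_effective,
        cfg.gap_extend,
    )
    total += score_pairwise_patterns(
        ba.project_patterns("V"),
        lambda i, j: (
            cfg.structure_match if str_a[i] == str_b[j] else cfg.structure_mismatch
        ),
        cfg.gap_open_effective,
        cfg.gap_extend,
    )
    for which in ("aa", "bb"):
        total += score_pairwise_patterns(
            ba.project_patterns(which),
            lambda i, j: 0.0,
            cfg.shift_open_effective,
            cfg.shift_extend,
        )
    return total


def score_all_modes(
    columns: Sequence[Column4],
    seq_a: str,
    seq_b: str,
    str_a: str,
    str_b: str,
    cfg: ScoringConfig,
) -> dict[str, float]:
    """Scores of one candidate under all four bi-alignment cost models.

    Shares one projection scan across the modes (they differ only in which
    opening costs are charged), which keeps exhaustive multi-mode sweeps
    affordable.
    """
    ba = BiAlignment(list(columns), seq_a, seq_b, str_a, str_b)
    if cfg.substitution is None:
        raise InputError("ScoringConfig.substitution is not set")
    sub = cfg.substitution
    u_matches, u_runs = _pair_stats(ba.project_patterns("U"))
    v_matches, v_runs = _pair_stats(ba.project_patterns("V"))
    _, aa_runs = _pair_stats(ba.project_patterns("aa"))
    _, bb_runs = _pair_stats(ba.project_patterns("bb"))
    u_base = sum(sub.score(seq_a[i], seq_b[j]) for i, j in u_matches)
    v_base = sum(
        cfg.structure_match if str_a[i] == str_b[j] else cfg.structure_mismatch
        for i, j in v_matches
    )
    gap_cols = sum(u_runs) + sum(v_runs)
    gap_runs = len(u_runs) + len(v_runs)
    shift_cols = sum(aa_runs) + sum(bb_runs)
    shift_runs = len(aa_runs) + len(bb_runs)
    base = (
        u_base
        + v_base
        + gap_cols * cfg.gap_extend
        + shift_cols * cfg.shift_extend
    )
    return {
        "linear": base,
        "affine_gap": base + gap_runs * cfg.gap_open,
        "affine_shift": base + shift_runs * cfg.shift_open,
        "affine_both": base + gap_runs * cfg.gap_open + shift_runs * cfg.shift_open,
    }


def brute_force_bialign(
    seq_a: str,
    seq_b: str,
    str_a: str,
    str_b: str,
    cfg: ScoringConfig,
    max_alignments: int = DEFAULT_MAX_ALIGNMENTS,
) -> tuple[float, list[BiAlignment]]:
    """Exhaustively optimal bi-alignments of a tiny instance.

    Returns the maximum score under ``cfg.mode`` and *all* optimal
    bi-alignments.  Intended for inputs with lengths up to ~4.
    """
    if len(seq_a) != len(str_a) or len(seq_b) != len(str_b):
        raise LengthMismatchError("structure strings must match sequence lengths")
    best = float("-inf")
    argmax: list[tuple[Column4, ...]] = []
    for cols in enumerate_bialignment_columns(
        len(seq_a), len(seq_b), max_alignments
    ):
        s = score_columns(cols, seq_a, seq_b, str_a, str_b, cfg)
        if s > best:
            best = s
            argmax = [cols]
        elif s == best:
            argmax.append(cols)
    if not argmax:  # only possible for empty inputs handled above; defensive
        best = 0.0
    results = [
        BiAlignment(list(cols), seq_a, seq_b, str_a, str_b, score=best)
        for cols in argmax
    ]
    return best, results
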