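"""Stand-alone pairwise aligners used as deliverables and limit-case oracles.

Three global aligners over the same column-wise view of alignments:

* :func:`nw_align` -- linear gap costs (one score per gap column),
* :func:`gotoh_align` -- affine gap costs (a run of length l costs
  ``gap_open + l * gap_extend``), three states by end column pattern,
* :func:`subadditive_align` -- general sub-additive run costs
  ``w(l) = a + b*l + c_log*ln(l)``, in two independent formulations
  (direct jumps over whole runs, and run-length-annotated end states).

Scores are contributions (penalties negative) and alignments are global;
ties prefer match over deletion over insertion columns, consistently with
the bi-alignment engine's canonical column order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .core import (
    DELETION,
    INSERTION,
    InputError,
    MATCH,
    Pattern,
    ScoringConfig,
)

__all__ = [
    "SubadditiveGapParams",
    "nw_align",
    "gotoh_align",
    "subadditive_align",
]

NEG_INF = float("-inf")

#: Tie-breaking order of pairwise column types.
_PAIR_COLUMNS: tuple[Pattern, ...] = (MATCH, DELETION, INSERTION)


@dataclass(frozen=True)
class SubadditiveGapParams:
    """Parameters of the run cost ``w(l) = a + b*l + c_log*ln(l)``.

    ``a`` is the opening term, ``b`` the per-column term and ``c_log`` the
    logarithmic coefficient (natural logarithm, so ``w(1) = a + b``).  The
    run cost is length-only; position-dependent costs can be supplied to
    the aligners via a custom ``run_cost`` hook.
    """

    a: float
    b: float
    c_log: float = 0.0

    def cost(self, length: int) -> float:
        if length < 0:
            raise InputError("run length must be >= 0")
        if length == 0:
            return 0.0
        return self.a + self.b * length + self.c_log * math.log(length)

    __call__ = cost


def _match_fn(a: str, b: str, cfg: ScoringConfig) -> Callable[[int, int], float]:
    if cfg.substitution is None:
        raise InputError("ScoringConfig.substitution is not set")
    sub = cfg.substitution
    return lambda i, j: sub.score(a[i], b[j])


def _rows_from_patterns(a: str, b: str, patterns: list[Pattern]) -> tuple[str, str]:
    i = j = 0
    top, bottom = [], []
    for p in patterns:
        top.append(a[i] if p[0] else "-")
        bottom.append(b[j] if p[1] else "-")
        i += p[0]
        j += p[1]
    return "".join(top), "".join(bottom)


def nw_align(
    a: str,
    b: str,
    cfg: ScoringConfig,
    score_fn: Callable[[int, int], float] | None = None,
) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment with linear gap costs (Needleman-Wunsch).

    Each gap column costs ``cfg.gap_extend``; ``cfg.gap_open`` is ignored.
    ``score_fn(i, j)`` may replace the substitution lookup (0-based
    positions).  Returns ``(score, (gapped_a, gapped_b))``.
    """
    s = score_fn if score_fn is not None else _match_fn(a, b, cfg)
    g = cfg.gap_extend
    n1, n2 = len(a), len(b)
    M = [[0.0] * (n2 + 1) for _ in range(n1 + 1)]
    for i in range(1, n1 + 1):
        M[i][0] = i * g
    for j in range(1, n2 + 1):
        M[0][j] = j * g
    for i in range(1, n1 + 1):
        row, above = M[i], M[i - 1]
        for j in range(1, n2 + 1):
            row[j] = max(above[j - 1] + s(i - 1, j - 1), above[j] + g, row[j - 1] + g)
    # traceback, preferring match > deletion > insertion on ties
    patterns: list[Pattern] = []
    i, j = n1, n2
    while i > 0 or j > 0:
        here = M[i][j]
        if i > 0 and j > 0 and here == M[i - 1][j - 1] + s(i - 1, j - 1):
            patterns.append(MATCH)
            i -= 1
            j -= 1
        elif i > 0 and here == M[i - 1][j] + g:
            patterns.append(DELETION)
            i -= 1
        else:
            patterns.append(INSERTION)
            j -= 1
    patterns.reverse()
    return M[n1][n2], _rows_from_patterns(a, b, patterns)


def gotoh_align(
    a: str,
    b: str,
    cfg: ScoringConfig,
    score_fn: Callable[[int, int], float] | None = None,
) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment with affine gap costs (Gotoh).

    A maximal gap run of length l costs ``gap_open + l * gap_extend``; a
    deletion run immediately following an insertion run (or vice versa)
    opens anew.  Three DP states, indexed by the end column pattern; the
    empty alignment counts as ending in a match, so leading gaps are
    charged the opening cost.
    """
    s = score_fn if score_fn is not None else _match_fn(a, b, cfg)
    go, ge = cfg.gap_open, cfg.gap_extend
    n1, n2 = len(a), len(b)
    # state order mirrors _PAIR_COLUMNS: 0 match, 1 deletion, 2 insertion
    M = [[[NEG_INF] * 3 for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    BP = [[[-1] * 3 for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    M[0][0][0] = 0.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for ci, col in enumerate(_PAIR_COLUMNS):
                pi, pj = i - col[0], j - col[1]
                if pi < 0 or pj < 0:
                    continue
                if col == MATCH:
                    add = s(i - 1, j - 1)
                else:
                    add = ge
                for cpi in range(3):
                    v = M[pi][pj][cpi]
                    if v == NEG_INF:
                        continue
                    total = v + add
                    if col != MATCH and cpi != ci:
                        total += go
                    if total > M[i][j][ci]:
                        M[i][j][ci] = total
                        BP[i][j][ci] = cpi
    finals = M[n1][n2]
    best_state = max(range(3), key=lambda ci: (finals[ci], -ci))
    best = finals[best_state]
    patterns: list[Pattern] = []
    i, j, ci = n1, n2, best_state
    while i > 0 or j > 0:
        col = _PAIR_COLUMNS[ci]
        patterns.append(col)
        cpi = BP[i][j][ci]
        i -= col[0]
        j -= col[1]
        ci = cpi
    patterns.reverse()
    return best, _rows_from_patterns(a, b, patterns)


def _subadditive_direct(
    a: str,
    b: str,
    w: Callable[[int], float],
    s: Callable[[int, int], float],
) -> float:
    """Whole-run formulation: jump over insertions/deletions of any length.

    Correct whenever ``w`` is sub-additive (one long run never scores worse
    than two shorter runs covering it); cubic time, quadratic space.
    """
    n1, n2 = len(a), len(b)
    M = [[NEG_INF] * (n2 + 1) for _ in range(n1 + 1)]
    M[0][0] = 0.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            best = M[i][j]
            if i > 0 and j > 0:
                best = max(best, M[i - 1][j - 1] + s(i - 1, j - 1))
            for l in range(1, i + 1):
                best = max(best, M[i - l][j] + w(l))
            for l in range(1, j + 1):
                best = max(best, M[i][j - l] + w(l))
            M[i][j] = best
    return M[n1][n2]


def _subadditive_runlength(
    a: str,
    b: str,
    w: Callable[[int], float],
    s: Callable[[int, int], float],
    max_run: int | None = None,
) -> float:
    """Run-length end-state formulation.

    The end column type is generalized to ``<p, l>``: pattern p with a run
    of l equal columns at the alignment's end.  Extending a run by one
    column adds the increment ``w(l) - w(l-1)`` (the match score for
    ``p = match``), which telescopes to ``w(l)`` over the whole run, so
    every maximal run is charged exactly once; the auxiliary state
    ``<p, 0>`` (the best over all states with a different pattern) handles
    run switches.  Exact for arbitrary run costs; cubic time and space.
    """
    n1, n2 = len(a), len(b)
    cap = max(n1, n2) if max_run is None else min(max_run, max(n1, n2))

    def d(p: Pattern, l: int, i: int, j: int) -> float:
        if p == MATCH:
            return s(i - 1, j - 1)
        return w(l) - w(l - 1)

    # table[(i, j)][p] = list over run length l (index l-1)
    table: dict[tuple[int, int], dict[Pattern, list[float]]] = {}
    aux: dict[tuple[int, int], dict[Pattern, float]] = {}
    aux[(0, 0)] = {p: 0.0 for p in _PAIR_COLUMNS}
    table[(0, 0)] = {p: [] for p in _PAIR_COLUMNS}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if (i, j) == (0, 0):
                continue
            here: dict[Pattern, list[float]] = {}
            for p in _PAIR_COLUMNS:
                pi, pj = i - p[0], j - p[1]
                runs: list[float] = []
                if pi >= 0 and pj >= 0:
                    prev_runs = table[(pi, pj)][p]
                    prev_aux = aux[(pi, pj)][p]
                    limit = cap if p != MATCH else max(n1, n2)
                    for l in range(1, limit + 1):
                        base = prev_aux if l == 1 else (
                            prev_runs[l - 2] if l - 2 < len(prev_runs) else NEG_INF
                        )
                        if base == NEG_INF:
                            runs.append(NEG_INF)
                        else:
                            runs.append(base + d(p, l, i, j))
                here[p] = runs
            table[(i, j)] = here
            # best over states with pattern p', per excluded pattern p
            best_per_p = {
                p: max(here[p], default=NEG_INF) for p in _PAIR_COLUMNS
            }
            aux[(i, j)] = {
                p: max(
                    (best_per_p[q] for q in _PAIR_COLUMNS if q != p),
                    default=NEG_INF,
                )
                for p in _PAIR_COLUMNS
            }
    if (n1, n2) == (0, 0):
        return 0.0
    finals = table[(n1, n2)]
    return max(max(runs, default=NEG_INF) for runs in finals.values())


def subadditive_align(
    a: str,
    b: str,
    params: SubadditiveGapParams,
    cfg: ScoringConfig,
    method: str = "run_length",
    score_fn: Callable[[int, int], float] | None = None,
) -> float:
    """Optimal global alignment score with run cost ``w(l) = a + b*l + c*ln(l)``.

    ``method`` selects between the two independent formulations
    (``"direct"`` and ``"run_length"``); they return identical scores for
    sub-additive ``w`` and serve as mutual cross-checks.  With ``c_log = 0``
    the result equals :func:`gotoh_align` with ``gap_open = a`` and
    ``gap_extend = b``.
    """
    s = score_fn if score_fn is not None else _match_fn(a, b, cfg)
    if method == "direct":
        return _subadditive_direct(a, b, params.cost, s)
    if method == "run_length":
        return _subadditive_runlength(a, b, params.cost, s)
    raise InputError(f"unknown method {method!r}; expected 'direct' or 'run_length'")
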