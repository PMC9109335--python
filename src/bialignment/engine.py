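"""Bi-alignment dynamic programs: linear, affine-gap, affine-shift and
combined affine cost models, with shift banding and deterministic traceback.

All four modes run through one banded multi-tape DP (see
:mod:`bialignment._kernel`); they differ only in which end column types
the state has to track:

* ``linear`` -- no opening costs, a single state;
* ``affine_gap`` -- affine gaps in U and V, linear shifts: the 9 variant-A
  states ``(p, q)`` (end column types of U and V), 15 recursion cases per
  cell;
* ``affine_shift`` -- affine shifts, linear gaps: symmetric, tracking the
  self-alignment pairs (1,3) and (2,4) instead;
* ``affine_both`` -- both affine: the general 4-tuple states
  ``(p12, p13, p24, p34)``, restricted to the reachable subset of the 81
  candidates (51 states, computed constructively, not hard-coded).

The band limits how far either sequence may be displaced against its own
structure: only cells with ``|x1-y1| <= lambda`` and ``|x2-y2| <= lambda``
exist, giving O(n^2 lambda^2) time and space; ``lambda_max=None`` runs the
exact O(n^4) recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import _kernel
from .core import (
    ALL_GAP,
    BiAlignment,
    COLUMN_TYPES,
    Column4,
    DELETION,
    END_PATTERNS,
    EndState,
    INITIAL_STATE,
    INSERTION,
    InputError,
    LengthMismatchError,
    MATCH,
    Pattern,
    ScoringConfig,
    UnknownSymbolError,
)

__all__ = [
    "EngineResult",
    "DPTables",
    "band_filter",
    "reachable_states",
    "bialign",
    "fill_tables",
    "traceback",
]

_BIALIGN_MODES = ("linear", "affine_gap", "affine_shift", "affine_both")

#: Which pairwise projections each mode tracks in its DP state.
_TRACKED = {
    "linear": (),
    "affine_gap": ("p12", "p34"),
    "affine_shift": ("p13", "p24"),
    "affine_both": ("p12", "p13", "p24", "p34"),
}


def band_filter(x1: int, x2: int, y1: int, y2: int, lam: int) -> bool:
    """True iff the cell lies within the shift band of half-width ``lam``."""
    if lam < 0:
        raise InputError("lambda must be >= 0")
    return abs(x1 - y1) <= lam and abs(x2 - y2) <= lam


@lru_cache(maxsize=1)
def reachable_states() -> frozenset[EndState]:
    """All end-state tuples ``(p12, p13, p24, p34)`` that occur in valid
    bi-alignments.

    Computed as the closure of the pattern-update rule over the 15 column
    types, starting from the all-match state of the empty alignment; of
    the 3^4 = 81 candidate tuples only this subset is consistent.
    """
    seen = {INITIAL_STATE}
    frontier = [INITIAL_STATE]
    while frontier:
        nxt = []
        for state in frontier:
            for col in COLUMN_TYPES:
                new = state.update(col)
                if new not in seen:
                    seen.add(new)
                    nxt.append(new)
        frontier = nxt
    return frozenset(seen)


def _mask_state(state: EndState, tracked: tuple[str, ...]) -> EndState:
    return EndState(
        *(getattr(state, f) if f in tracked else MATCH for f in EndState._fields)
    )


def _state_space(mode: str) -> tuple[EndState, ...]:
    tracked = _TRACKED[mode]
    if mode == "affine_both":
        states = reachable_states()
    else:
        states = {_mask_state(s, tracked) for s in reachable_states()}
    return tuple(sorted(states))


@lru_cache(maxsize=32)
def _mode_tables(
    mode: str,
    gap_open: float,
    gap_extend: float,
    shift_open: float,
    shift_extend: float,
):
    """State list plus the kernel's transition/fixed-cost/flag tables."""
    states = _state_space(mode)
    index = {s: i for i, s in enumerate(states)}
    tracked = _TRACKED[mode]
    n_cols = len(COLUMN_TYPES)
    trans = np.zeros((len(states), n_cols), np.int64)
    fixed = np.zeros((len(states), n_cols), np.float64)
    for si, state in enumerate(states):
        for ti, col in enumerate(COLUMN_TYPES):
            trans[si, ti] = index[_mask_state(state.update(col), tracked)]
            cost = 0.0
            for part, prev in ((col.c, state.p12), (col.d, state.p34)):
                if part in (DELETION, INSERTION):
                    cost += gap_extend + (gap_open if prev != part else 0.0)
            for part, prev in ((col.p13, state.p13), (col.p24, state.p24)):
                if part in (DELETION, INSERTION):
                    cost += shift_extend + (shift_open if prev != part else 0.0)
            fixed[si, ti] = cost
    seq_flag = np.array([col.c == MATCH for col in COLUMN_TYPES], np.bool_)
    struct_flag = np.array([col.d == MATCH for col in COLUMN_TYPES], np.bool_)
    dshift = np.array([col.shift for col in COLUMN_TYPES], np.int32)
    dx = np.array([col.deltas for col in COLUMN_TYPES], np.int64)
    s0 = index[INITIAL_STATE]
    return states, trans, fixed, seq_flag, struct_flag, dshift, dx, s0


@dataclass
class DPTables:
    """Filled DP tables of one bi-alignment run.

    ``score``/``shifts``/``back`` are indexed by
    ``(x1, y1-x1+lam, x2, y2-x2+lam, state)``; offsets outside the band
    are never allocated, cells never reached stay at -inf.
    """

    score: np.ndarray
    shifts: np.ndarray
    back: np.ndarray
    states: tuple[EndState, ...]
    lam: int
    cfg: ScoringConfig
    seq_a: str
    seq_b: str
    str_a: str
    str_b: str

    def lookup(self, x1: int, x2: int, y1: int, y2: int, state: EndState) -> float:
        """Best score of the banded cell, or -inf if outside the band."""
        if not band_filter(x1, x2, y1, y2, self.lam):
            return float("-inf")
        v = self.score[
            x1, y1 - x1 + self.lam, x2, y2 - x2 + self.lam, self.states.index(state)
        ]
        return float(v) if v > _kernel.NEG_INF / 2 else float("-inf")

    @property
    def n_cells(self) -> int:
        """Number of banded (x, y) cells allocated (all states share them)."""
        n1 = self.score.shape[0] - 1
        n2 = self.score.shape[2] - 1
        c1 = sum(
            1
            for x in range(n1 + 1)
            for o in range(-self.lam, self.lam + 1)
            if 0 <= x + o <= n1
        )
        c2 = sum(
            1
            for x in range(n2 + 1)
            for o in range(-self.lam, self.lam + 1)
            if 0 <= x + o <= n2
        )
        return c1 * c2

    @property
    def cells_filled(self) -> int:
        """Number of (cell, state) entries actually reached by the DP."""
        return int((self.score > _kernel.NEG_INF / 2).sum())


@dataclass
class EngineResult:
    """Optimal bi-alignment plus bookkeeping about the run."""

    alignment: BiAlignment
    score: float
    mode: str
    n_states: int
    n_column_types: int
    cells_filled: int
    lam: int

    @property
    def shift_count(self) -> int:
        return self.alignment.shift_count


def _resolve_substitution(cfg: ScoringConfig) -> ScoringConfig:
    if cfg.substitution is not None:
        return cfg
    from .io import read_matrix

    return replace(cfg, substitution=read_matrix())


def _validate_inputs(
    seq_a: str, seq_b: str, str_a: str, str_b: str, cfg: ScoringConfig
) -> None:
    if len(seq_a) != len(str_a) or len(seq_b) != len(str_b):
        raise LengthMismatchError(
            "each structure string must have the same length as its sequence"
        )
    alphabet = set(cfg.substitution.alphabet)  # type: ignore[union-attr]
    unknown = sorted((set(seq_a) | set(seq_b)) - alphabet)
    if unknown:
        raise UnknownSymbolError(
            f"residue symbol(s) {unknown!r} not covered by the substitution matrix"
        )


def fill_tables(
    seq_a: str, seq_b: str, str_a: str, str_b: str, cfg: ScoringConfig
) -> DPTables:
    """Run the banded DP for ``cfg.mode`` and return the filled tables."""
    if cfg.mode not in _BIALIGN_MODES:
        raise InputError(
            f"mode {cfg.mode!r} is not a bi-alignment mode; expected one of "
            f"{_BIALIGN_MODES}"
        )
    cfg = _resolve_substitution(cfg)
    _validate_inputs(seq_a, seq_b, str_a, str_b, cfg)
    n1, n2 = len(seq_a), len(seq_b)
    lam = cfg.lambda_max if cfg.lambda_max is not None else max(n1, n2)
    lam = min(lam, max(n1, n2))
    states, trans, fixed, seq_flag, struct_flag, dshift, dx, s0 = _mode_tables(
        cfg.mode,
        float(cfg.gap_open_effective),
        float(cfg.gap_extend),
        float(cfg.shift_open_effective),
        float(cfg.shift_extend),
    )
    sub = cfg.substitution
    subm = np.array(
        [[sub.score(ca, cb) for cb in seq_b] for ca in seq_a], np.float64
    ).reshape(n1, n2)
    structm = np.empty((n1, n2), np.float64)
    for i, ca in enumerate(str_a):
        for j, cb in enumerate(str_b):
            structm[i, j] = (
                cfg.structure_match if ca == cb else cfg.structure_mismatch
            )
    score, shifts, back = _kernel.fill_tables(
        n1, n2, lam, subm, structm, trans, fixed, seq_flag, struct_flag, dshift, dx, s0
    )
    return DPTables(score, shifts, back, states, lam, cfg, seq_a, seq_b, str_a, str_b)


def traceback(tables: DPTables) -> BiAlignment:
    """Reconstruct one optimal bi-alignment from filled tables.

    Among score-co-optimal alignments the DP already minimizes the total
    shift count; remaining ties resolve to the first candidate in the
    canonical column order, so the result is deterministic.
    """
    n1, n2 = len(tables.seq_a), len(tables.seq_b)
    lam = tables.lam
    finals = tables.score[n1, lam, n2, lam, :]
    final_shifts = tables.shifts[n1, lam, n2, lam, :]
    order = sorted(
        range(len(tables.states)),
        key=lambda s: (-finals[s], final_shifts[s], s),
    )
    s = order[0]
    best = finals[s]
    if best <= _kernel.NEG_INF / 2:
        raise InputError("DP tables contain no finite final score (corrupt tables)")
    cols: list[Column4] = []
    x1, x2, y1, y2 = n1, n2, n1, n2
    while (x1, x2, y1, y2) != (0, 0, 0, 0) or s != tables.states.index(INITIAL_STATE):
        bp = int(tables.back[x1, y1 - x1 + lam, x2, y2 - x2 + lam, s])
        if bp < 0:
            raise InputError("broken traceback chain (corrupt tables)")
        t, sp = divmod(bp, 128)
        col = COLUMN_TYPES[t]
        cols.append(col)
        dx1, dx2, dy1, dy2 = col.deltas
        x1 -= dx1
        x2 -= dx2
        y1 -= dy1
        y2 -= dy2
        s = sp
    cols.reverse()
    return BiAlignment(
        cols,
        tables.seq_a,
        tables.seq_b,
        tables.str_a,
        tables.str_b,
        score=float(best),
    )


def bialign(
    seq_a: str, seq_b: str, str_a: str, str_b: str, cfg: ScoringConfig
) -> EngineResult:
    """Globally optimal bi-alignment of two sequence/structure pairs.

    ``cfg.mode`` selects the cost model; ``cfg.lambda_max`` the shift band.
    Raises :class:`LengthMismatchError` if a structure string does not
    match its sequence and :class:`UnknownSymbolError` for residues the
    matrix does not cover.
    """
    tables = fill_tables(seq_a, seq_b, str_a, str_b, cfg)
    alignment = traceback(tables)
    return EngineResult(
        alignment=alignment,
        score=alignment.score,
        mode=cfg.mode,
        n_states=len(tables.states),
        n_column_types=len(COLUMN_TYPES),
        cells_filled=tables.cells_filled,
        lam=tables.lam,
    )
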