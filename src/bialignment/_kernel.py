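"""Banded multi-tape DP kernel, compiled with numba.

One kernel serves every cost model: the mode differences (which pairwise
projections carry affine opening costs, and hence which end column types
must be tracked) are folded into precomputed state-transition and
fixed-cost tables by :mod:`bialignment.engine`.  Cells are indexed by
``(x1, y1-x1+lam, x2, y2-x2+lam, state)``; only offsets within the shift
band ``|x1-y1| <= lam``, ``|x2-y2| <= lam`` are allocated, giving
O(n^2 lam^2) space.  The DP optimizes the pair (score, -shift_count)
lexicographically; remaining ties fall to the first candidate in the
canonical column-type order, so tracebacks are fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e18


@njit(cache=True)
def fill_tables(n1, n2, lam, subm, structm, trans, fixed, seq_flag, struct_flag, dshift, dx, s0):
    n_states = trans.shape[0]
    n_cols = dx.shape[0]
    w = 2 * lam + 1
    score = np.full((n1 + 1, w, n2 + 1, w, n_states), NEG_INF, np.float64)
    shifts = np.zeros((n1 + 1, w, n2 + 1, w, n_states), np.int32)
    back = np.full((n1 + 1, w, n2 + 1, w, n_states), -1, np.int16)
    score[0, lam, 0, lam, s0] = 0.0
    for x1 in range(n1 + 1):
        for i1 in range(w):
            y1 = x1 + i1 - lam
            if y1 < 0 or y1 > n1:
                continue
            for x2 in range(n2 + 1):
                for i2 in range(w):
                    y2 = x2 + i2 - lam
                    if y2 < 0 or y2 > n2:
                        continue
                    for t in range(n_cols):
                        px1 = x1 - dx[t, 0]
                        px2 = x2 - dx[t, 1]
                        py1 = y1 - dx[t, 2]
                        py2 = y2 - dx[t, 3]
                        if px1 < 0 or px2 < 0 or py1 < 0 or py2 < 0:
                            continue
                        pi1 = py1 - px1 + lam
                        if pi1 < 0 or pi1 >= w:
                            continue
                        pi2 = py2 - px2 + lam
                        if pi2 < 0 or pi2 >= w:
                            continue
                        add = 0.0
                        if seq_flag[t]:
                            add += subm[px1, px2]
                        if struct_flag[t]:
                            add += structm[py1, py2]
                        for sp in range(n_states):
                            v = score[px1, pi1, px2, pi2, sp]
                            if v <= NEG_INF / 2.0:
                                continue
                            cand = v + fixed[sp, t] + add
                            cnt = shifts[px1, pi1, px2, pi2, sp] + dshift[t]
                            s2 = trans[sp, t]
                            cur = score[x1, i1, x2, i2, s2]
                            if cand > cur or (
                                cand == cur and cnt < shifts[x1, i1, x2, i2, s2]
                            ):
                                score[x1, i1, x2, i2, s2] = cand
                                shifts[x1, i1, x2, i2, s2] = cnt
                                back[x1, i1, x2, i2, s2] = t * 128 + sp
    return score, shifts, back
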