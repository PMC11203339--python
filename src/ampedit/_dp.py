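"""Numba kernel for global alignment with affine gap scoring.

Three-state Gotoh dynamic programme (M = aligned pair, DEL = gap in the
query consuming reference, INS = gap in the reference consuming query).
With the pipeline's scheme (match 1, mismatch 0, gapOpen -2, gapExt 0) a
gap of any length costs a flat 2, which is why tie-breaking matters: the
traceback prefers staying inside an open gap over opening a new one (so
one long gap beats two short ones at equal score) and resolves remaining
ties in a fixed state order, giving a deterministic operation list.

Op codes emitted: 0 = match, 1 = mismatch, 2 = insertion (query base),
3 = deletion (reference base).
"""

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))
N_CODE = 4  # 'N' never matches anything, including another N


@njit(cache=False)
def align_kernel(q, r, match, mismatch, gap_open, gap_ext):
    n = q.shape[0]
    m = r.shape[0]
    M = np.full((n + 1, m + 1), NEG, np.int64)
    D = np.full((n + 1, m + 1), NEG, np.int64)  # deletion: consumes reference (j)
    I = np.full((n + 1, m + 1), NEG, np.int64)  # insertion: consumes query (i)
    # predecessor state codes: 0=M, 1=D, 2=I
    PM = np.zeros((n + 1, m + 1), np.int8)
    PD = np.zeros((n + 1, m + 1), np.int8)
    PI = np.zeros((n + 1, m + 1), np.int8)

    M[0, 0] = 0
    for j in range(1, m + 1):
        D[0, j] = gap_open + gap_ext * (j - 1)
        PD[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        I[i, 0] = gap_open + gap_ext * (i - 1)
        PI[i, 0] = 2 if i > 1 else 0

    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != N_CODE) else mismatch
            # M: diagonal step; tie order M > D > I
            bm, pm = M[i - 1, j - 1], 0
            if D[i - 1, j - 1] > bm:
                bm, pm = D[i - 1, j - 1], 1
            if I[i - 1, j - 1] > bm:
                bm, pm = I[i - 1, j - 1], 2
            M[i, j] = bm + s
            PM[i, j] = pm
            # D: consume reference; prefer extending the gap on ties
            bd, pd = D[i, j - 1] + gap_ext, 1
            if M[i, j - 1] + gap_open > bd:
                bd, pd = M[i, j - 1] + gap_open, 0
            if I[i, j - 1] + gap_open > bd:
                bd, pd = I[i, j - 1] + gap_open, 2
            D[i, j] = bd
            PD[i, j] = pd
            # I: consume query; prefer extending the gap on ties
            bi, pi = I[i - 1, j] + gap_ext, 2
            if M[i - 1, j] + gap_open > bi:
                bi, pi = M[i - 1, j] + gap_open, 0
            if D[i - 1, j] + gap_open > bi:
                bi, pi = D[i - 1, j] + gap_open, 1
            I[i, j] = bi
            PI[i, j] = pi

    # final state: tie order M > D > I
    state = 0
    score = M[n, m]
    if D[n, m] > score:
        score, state = D[n, m], 1
    if I[n, m] > score:
        score, state = I[n, m], 2

    ops = np.empty(n + m, np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0 if (q[i - 1] == r[j - 1] and q[i - 1] != N_CODE) else 1
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 3
            state = PD[i, j]
            j -= 1
        else:
            ops[k] = 2
            state = PI[i, j]
            i -= 1
    return score, ops[k:]
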