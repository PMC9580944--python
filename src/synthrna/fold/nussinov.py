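"""Fallback folding oracle: canonical base-pair maximization.

Plain Nussinov dynamic program with minimum hairpin size 3 and canonical
(Watson-Crick + wobble) pairs only.  Clearly labeled non-thermodynamic;
used when speed matters or as an independent test oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PAIR_TYPE, encode_sequence

_TURN = 3


@njit(cache=True)
def _nuss_fill(S, ptype, M):
    n = len(S)
    for d in range(_TURN + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = M[i, j - 1]
            for k in range(i, j - _TURN):
                if ptype[S[k], S[j]] > 0:
                    left = M[i, k - 1] if k > i else 0
                    v = left + M[k + 1, j - 1] + 1
                    if v > best:
                        best = v
            M[i, j] = best


@njit(cache=True)
def _nuss_trace(S, ptype, M, partner):
    n = len(S)
    stk_i = np.empty(2 * n + 4, dtype=np.int64)
    stk_j = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    stk_i[top], stk_j[top] = 0, n - 1
    top += 1
    while top > 0:
        top -= 1
        i, j = stk_i[top], stk_j[top]
        if j - i <= _TURN:
            continue
        if M[i, j] == M[i, j - 1]:
            stk_i[top], stk_j[top] = i, j - 1
            top += 1
            continue
        for k in range(i, j - _TURN):
            if ptype[S[k], S[j]] > 0:
                left = M[i, k - 1] if k > i else 0
                if left + M[k + 1, j - 1] + 1 == M[i, j]:
                    partner[k] = j
                    partner[j] = k
                    if k > i:
                        stk_i[top], stk_j[top] = i, k - 1
                        top += 1
                    stk_i[top], stk_j[top] = k + 1, j - 1
                    top += 1
                    break


def nussinov_fold(seq: str) -> str:
    """Maximum-pairing nested structure as a dot-bracket string."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return ""
    S = encode_sequence(seq)
    M = np.zeros((n, n), dtype=np.int64)
    _nuss_fill(S, PAIR_TYPE, M)
    partner = np.full(n, -1, dtype=np.int64)
    _nuss_trace(S, PAIR_TYPE, M, partner)
    return "".join(
        "(" if partner[k] > k else ")" if 0 <= partner[k] < k else "."
        for k in range(n)
    )
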