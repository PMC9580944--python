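"""Minimum-free-energy secondary-structure prediction.

A self-contained implementation of the Zuker dynamic program over the
nearest-neighbor (Turner 2004) energy model, with the double-dangle ("d2")
treatment of exterior- and multiloop stems that the standard thermodynamic
folder applies by default.  Operates on 1-based padded integer sequences;
energies are integer dekacal/mol throughout the DP.

The recursion arrays are

* ``c[i,j]``   – best energy of the segment [i,j] given that (i,j) pairs
* ``fML[i,j]`` – best energy of [i,j] as part of a multiloop (>= 1 stem)
* ``fM1[i,j]`` – as fML but with exactly one stem, starting at i
* ``f5[j]``    – best energy of the 5' prefix 1..j
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import INF, MAXLOOP, PAIR_TYPE, TurnerParams, encode_sequence

TURN = 3  # minimum unpaired span inside a hairpin


@njit(cache=True)
def _e_hairpin(i, j, t, S1, spe, hairpin, mmh, lxc, term_au):
    size = j - i - 1
    if size == 3 and spe[i, 0] < INF:
        return spe[i, 0]
    if size == 4 and spe[i, 1] < INF:
        return spe[i, 1]
    if size == 6 and spe[i, 2] < INF:
        return spe[i, 2]
    if size <= 30:
        e = hairpin[size]
    else:
        e = hairpin[30] + int(lxc * math.log(size / 30.0))
    if size == 3:
        if t > 2:
            e += term_au
        return e
    return e + mmh[t, S1[i + 1], S1[j - 1]]


@njit(cache=True)
def _e_intloop(
    n1, n2, t, t2, si1, sj1, sp1, sq1,
    stack, bulge, internal, mi, mi1n, mi23,
    int11, int21, int22, ninio, max_ninio, lxc, term_au,
):
    if n1 > n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:
        return stack[t, t2]
    if ns == 0:  # bulge
        if nl <= MAXLOOP:
            e = bulge[nl]
        else:
            e = bulge[30] + int(lxc * math.log(nl / 30.0))
        if nl == 1:
            e += stack[t, t2]
        else:
            if t > 2:
                e += term_au
            if t2 > 2:
                e += term_au
        return e
    if ns == 1:
        if nl == 1:
            return int11[t, t2, si1, sj1]
        if nl == 2:
            if n1 == 1:
                return int21[t, t2, si1, sq1, sj1]
            return int21[t2, t, sq1, si1, sp1]
        # 1 x n loop
        if nl + 1 <= MAXLOOP:
            e = internal[nl + 1]
        else:
            e = internal[30] + int(lxc * math.log((nl + 1) / 30.0))
        e += min(max_ninio, (nl - ns) * ninio)
        e += mi1n[t, si1, sj1] + mi1n[t2, sq1, sp1]
        return e
    if ns == 2:
        if nl == 2:
            return int22[t, t2, si1, sp1, sq1, sj1]
        if nl == 3:  # 2x3 loop
            e = internal[5] + ninio
            e += mi23[t, si1, sj1] + mi23[t2, sq1, sp1]
            return e
    u = nl + ns
    if u <= MAXLOOP:
        e = internal[u]
    else:
        e = internal[30] + int(lxc * math.log(u / 30.0))
    e += min(max_ninio, (nl - ns) * ninio)
    e += mi[t, si1, sj1] + mi[t2, sq1, sp1]
    return e


@njit(cache=True)
def _e_ml_stem(t, s5, s3, mmm, d5, d3, ml_intern, term_au):
    if s5 >= 0 and s3 >= 0:
        e = mmm[t, s5, s3]
    elif s5 >= 0:
        e = d5[t, s5]
    elif s3 >= 0:
        e = d3[t, s3]
    else:
        e = 0
    if t > 2:
        e += term_au
    return e + ml_intern


@njit(cache=True)
def _e_ext_stem(t, s5, s3, mme, d5, d3, term_au):
    if s5 >= 0 and s3 >= 0:
        e = mme[t, s5, s3]
    elif s5 >= 0:
        e = d5[t, s5]
    elif s3 >= 0:
        e = d3[t, s3]
    else:
        e = 0
    if t > 2:
        e += term_au
    return e


@njit(cache=True)
def _fill(
    S1, ptype, spe,
    stack, hairpin, bulge, internal,
    mmh, mi, mi1n, mi23, mmm, mme, d5, d3,
    int11, int21, int22,
    ml_base, ml_closing, ml_intern, ninio, max_ninio, term_au, lxc,
    c, fML, fM1, f5,
):
    n = len(S1) - 2
    for d in range(TURN + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            t = ptype[S1[i], S1[j]]
            cij = INF
            if t > 0:
                cij = _e_hairpin(i, j, t, S1, spe, hairpin, mmh, lxc, term_au)
                # interior loops (includes stacks and bulges)
                pmax = min(i + MAXLOOP + 1, j - TURN - 2)
                for p in range(i + 1, pmax + 1):
                    u1 = p - i - 1
                    qmin = max(p + TURN + 1, j - 1 - (MAXLOOP - u1))
                    for q in range(qmin, j):
                        if c[p, q] >= INF:
                            continue
                        t2 = ptype[S1[q], S1[p]]
                        e = _e_intloop(
                            u1, j - q - 1, t, t2,
                            S1[i + 1], S1[j - 1], S1[p - 1], S1[q + 1],
                            stack, bulge, internal, mi, mi1n, mi23,
                            int11, int21, int22,
                            ninio, max_ninio, lxc, term_au,
                        )
                        if e + c[p, q] < cij:
                            cij = e + c[p, q]
                # multiloop closing
                best = INF
                for u in range(i + TURN + 2, j - TURN - 2):
                    v = fML[i + 1, u] + fM1[u + 1, j - 1]
                    if v < best:
                        best = v
                if best < INF:
                    rt = ptype[S1[j], S1[i]]
                    e = (
                        best
                        + ml_closing
                        + _e_ml_stem(rt, S1[j - 1], S1[i + 1],
                                     mmm, d5, d3, ml_intern, term_au)
                    )
                    if e < cij:
                        cij = e
            c[i, j] = cij
            # fM1: single stem starting at i
            v = fM1[i, j - 1] + ml_base if j - 1 >= i + TURN + 1 else INF
            if t > 0 and cij < INF:
                stem = cij + _e_ml_stem(t, S1[i - 1], S1[j + 1],
                                        mmm, d5, d3, ml_intern, term_au)
                if stem < v:
                    v = stem
            fM1[i, j] = v
            # fML
            v = fM1[i, j]
            if fML[i + 1, j] + ml_base < v:
                v = fML[i + 1, j] + ml_base
            if fML[i, j - 1] + ml_base < v:
                v = fML[i, j - 1] + ml_base
            for u in range(i + TURN + 1, j - TURN - 1):
                w = fML[i, u] + fM1[u + 1, j]
                if w < v:
                    v = w
            fML[i, j] = v
    # exterior loop
    f5[0] = 0
    for j in range(1, n + 1):
        f5[j] = f5[j - 1]
        for i in range(1, j - TURN):
            if c[i, j] >= INF:
                continue
            t = ptype[S1[i], S1[j]]
            s5 = S1[i - 1] if i > 1 else -1
            s3 = S1[j + 1] if j < n else -1
            e = f5[i - 1] + c[i, j] + _e_ext_stem(t, s5, s3, mme, d5, d3, term_au)
            if e < f5[j]:
                f5[j] = e


# traceback stack modes
_F5, _C, _M, _M1 = 0, 1, 2, 3


@njit(cache=True)
def _traceback(
    S1, ptype, spe,
    stack, hairpin, bulge, internal,
    mmh, mi, mi1n, mi23, mmm, mme, d5, d3,
    int11, int21, int22,
    ml_base, ml_closing, ml_intern, ninio, max_ninio, term_au, lxc,
    c, fML, fM1, f5, partner,
):
    n = len(S1) - 2
    stk_i = np.empty(4 * n + 8, dtype=np.int64)
    stk_j = np.empty(4 * n + 8, dtype=np.int64)
    stk_m = np.empty(4 * n + 8, dtype=np.int64)
    top = 0
    stk_i[top], stk_j[top], stk_m[top] = 1, n, _F5
    top += 1
    while top > 0:
        top -= 1
        i, j, mode = stk_i[top], stk_j[top], stk_m[top]
        if mode == _F5:
            while j > 0 and f5[j] == f5[j - 1]:
                j -= 1
            if j == 0:
                continue
            found = False
            for i2 in range(1, j - TURN):
                if c[i2, j] >= INF:
                    continue
                t = ptype[S1[i2], S1[j]]
                s5 = S1[i2 - 1] if i2 > 1 else -1
                s3 = S1[j + 1] if j < n else -1
                e = f5[i2 - 1] + c[i2, j] + _e_ext_stem(
                    t, s5, s3, mme, d5, d3, term_au)
                if e == f5[j]:
                    stk_i[top], stk_j[top], stk_m[top] = i2, j, _C
                    top += 1
                    stk_i[top], stk_j[top], stk_m[top] = 1, i2 - 1, _F5
                    top += 1
                    found = True
                    break
            if not found:  # numerical safety; should not happen
                continue
        elif mode == _C:
            partner[i] = j
            partner[j] = i
            t = ptype[S1[i], S1[j]]
            cij = c[i, j]
            if cij == _e_hairpin(i, j, t, S1, spe, hairpin, mmh, lxc, term_au):
                continue
            done = False
            pmax = min(i + MAXLOOP + 1, j - TURN - 2)
            for p in range(i + 1, pmax + 1):
                u1 = p - i - 1
                qmin = max(p + TURN + 1, j - 1 - (MAXLOOP - u1))
                for q in range(qmin, j):
                    if c[p, q] >= INF:
                        continue
                    t2 = ptype[S1[q], S1[p]]
                    e = _e_intloop(
                        u1, j - q - 1, t, t2,
                        S1[i + 1], S1[j - 1], S1[p - 1], S1[q + 1],
                        stack, bulge, internal, mi, mi1n, mi23,
                        int11, int21, int22,
                        ninio, max_ninio, lxc, term_au,
                    )
                    if e + c[p, q] == cij:
                        stk_i[top], stk_j[top], stk_m[top] = p, q, _C
                        top += 1
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            rt = ptype[S1[j], S1[i]]
            emlc = (
                ml_closing
                + _e_ml_stem(rt, S1[j - 1], S1[i + 1],
                             mmm, d5, d3, ml_intern, term_au)
            )
            for u in range(i + TURN + 2, j - TURN - 2):
                if fML[i + 1, u] + fM1[u + 1, j - 1] + emlc == cij:
                    stk_i[top], stk_j[top], stk_m[top] = i + 1, u, _M
                    top += 1
                    stk_i[top], stk_j[top], stk_m[top] = u + 1, j - 1, _M1
                    top += 1
                    break
        elif mode == _M1:
            while j - 1 >= i + TURN + 1 and fM1[i, j] == fM1[i, j - 1] + ml_base:
                j -= 1
            stk_i[top], stk_j[top], stk_m[top] = i, j, _C
            top += 1
        else:  # _M
            while i + 1 <= j and fML[i, j] == fML[i + 1, j] + ml_base:
                i += 1
            while j - 1 >= i and fML[i, j] == fML[i, j - 1] + ml_base:
                j -= 1
            if fML[i, j] == fM1[i, j]:
                stk_i[top], stk_j[top], stk_m[top] = i, j, _M1
                top += 1
                continue
            t = ptype[S1[i], S1[j]]
            if t > 0 and c[i, j] < INF and fML[i, j] == c[i, j] + _e_ml_stem(
                t, S1[i - 1], S1[j + 1], mmm, d5, d3, ml_intern, term_au
            ):
                stk_i[top], stk_j[top], stk_m[top] = i, j, _C
                top += 1
                continue
            for u in range(i + TURN + 1, j - TURN - 1):
                if fML[i, j] == fML[i, u] + fM1[u + 1, j]:
                    stk_i[top], stk_j[top], stk_m[top] = i, u, _M
                    top += 1
                    stk_i[top], stk_j[top], stk_m[top] = u + 1, j, _M1
                    top += 1
                    break


class MfeFolder:
    """Turner-model MFE folder (d2 dangles, canonical pairs, min hairpin 3)."""

    def __init__(self, params: TurnerParams):
        self.params = params
        self._special = params.special_hairpins

    def _special_vec(self, seq: str, n: int) -> np.ndarray:
        spe = np.full((n + 2, 3), INF, dtype=np.int64)
        sp = self._special
        for i in range(n):
            # columns: loop size 3 / 4 / 6 (key length includes closing pair)
            for col, size in enumerate((5, 6, 8)):
                if i + size <= n:
                    e = sp.get(seq[i : i + size])
                    if e is not None:
                        spe[i + 1, col] = e
        return spe

    def fold(self, seq: str) -> tuple[str, float]:
        """Return (dot-bracket structure, free energy in kcal/mol)."""
        seq = seq.upper().replace("T", "U")
        n = len(seq)
        if n == 0:
            return "", 0.0
        S = encode_sequence(seq)
        if (S == 0).any():
            raise ValueError("cannot fold sequence containing N")
        S1 = np.zeros(n + 2, dtype=np.int64)
        S1[1 : n + 1] = S
        spe = self._special_vec(seq, n)
        p = self.params
        c = np.full((n + 2, n + 2), INF, dtype=np.int64)
        fML = np.full((n + 2, n + 2), INF, dtype=np.int64)
        fM1 = np.full((n + 2, n + 2), INF, dtype=np.int64)
        f5 = np.zeros(n + 1, dtype=np.int64)
        args = (
            S1, PAIR_TYPE, spe,
            p.stack, p.hairpin, p.bulge, p.internal,
            p.mismatch_hairpin, p.mismatch_interior, p.mismatch_interior_1n,
            p.mismatch_interior_23, p.mismatch_multi, p.mismatch_exterior,
            p.dangle5, p.dangle3,
            p.int11, p.int21, p.int22,
            p.ml_base, p.ml_closing, p.ml_intern,
            p.ninio, p.max_ninio, p.terminal_au, p.lxc,
            c, fML, fM1, f5,
        )
        _fill(*args)
        partner = np.full(n + 2, -1, dtype=np.int64)
        _traceback(*args, partner)
        db = "".join(
            "(" if 0 < partner[k] and partner[k] > k
            else ")" if 0 < partner[k] < k
            else "."
            for k in range(1, n + 1)
        )
        return db, f5[n] / 100.0
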