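"""Structure algebra: pseudoknot removal, matrix postprocessing, censuses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .pairtable import UNPAIRED, PairTable, RawPairAssignment


@njit(cache=True)
def _nested_dp(w):
    """Max-weight non-crossing pair subset; w[i,j] > 0 marks candidate pairs."""
    n = w.shape[0]
    best = np.zeros((n + 1, n + 1))
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            b = best[i + 1, j]
            for k in range(i + 1, j + 1):
                if w[i, k] > 0.0:
                    v = w[i, k] + best[i + 1, k - 1] + best[k + 1, j]
                    if v > b:
                        b = v
            best[i, j] = b
    return best


@njit(cache=True)
def _nested_trace(w, best, partner):
    n = w.shape[0]
    stk_i = np.empty(2 * n + 4, dtype=np.int64)
    stk_j = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    stk_i[top], stk_j[top] = 0, n - 1
    top += 1
    while top > 0:
        top -= 1
        i, j = stk_i[top], stk_j[top]
        while i < j and best[i, j] == best[i + 1, j]:
            used = False
            # prefer retaining a pair starting at i (lexicographic tie-break)
            for k in range(i + 1, j + 1):
                if w[i, k] > 0.0 and (
                    w[i, k] + best[i + 1, k - 1] + best[k + 1, j] == best[i, j]
                ):
                    used = True
                    break
            if used:
                break
            i += 1
        if i >= j:
            continue
        for k in range(i + 1, j + 1):
            if w[i, k] > 0.0 and (
                w[i, k] + best[i + 1, k - 1] + best[k + 1, j] == best[i, j]
            ):
                partner[i] = k
                partner[k] = i
                stk_i[top], stk_j[top] = i + 1, k - 1
                top += 1
                stk_i[top], stk_j[top] = k + 1, j
                top += 1
                break
    return partner


def remove_pseudoknots(
    raw: RawPairAssignment | PairTable, weights: dict | None = None
) -> PairTable:
    """Maximum-cardinality (or maximum-weight) non-crossing pair subset.

    Shared endpoints are also resolved: the result has at most one partner
    per position.  Ties break toward lexicographically smallest pairs.
    """
    if isinstance(raw, PairTable):
        raw = RawPairAssignment(raw.n, raw.pairs())
    n = raw.n
    if n == 0 or not raw.pairs:
        return PairTable.from_pairs(n, [])
    w = np.zeros((n, n))
    for i, j in raw.pairs:
        if weights is not None:
            w[i, j] = float(weights[(i, j)])
        elif raw.weights:
            w[i, j] = float(raw.weights[(i, j)])
        else:
            w[i, j] = 1.0
        if w[i, j] <= 0.0:
            raise ValueError(f"non-positive weight for pair ({i},{j})")
    best = _nested_dp(w)
    partner = np.full(n, UNPAIRED, dtype=np.int64)
    _nested_trace(w, best, partner)
    return PairTable(partner)


@dataclass
class CrossingCensus:
    """Counts of non-nested and multi-partnered pairings in raw output."""

    structures_with_crossings: int = 0
    crossing_pairs: int = 0
    structures_with_multipairs: int = 0
    multi_pairings: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.structures_with_crossings,
            self.crossing_pairs,
            self.structures_with_multipairs,
            self.multi_pairings,
        )


def crossing_and_multipair_census(raws) -> CrossingCensus:
    """Census crossing-involved pairs and multi-partnered positions.

    A pair is crossing-involved if it crosses any other pair of the same
    structure.  Each pair incident to a position with >= 2 partners counts
    one multi-pairing per (position, pair) incidence.
    """
    census = CrossingCensus()
    for raw in raws:
        if isinstance(raw, PairTable):
            raw = RawPairAssignment(raw.n, raw.pairs())
        pairs = raw.pairs
        crossing = set()
        for a in range(len(pairs)):
            i, j = pairs[a]
            for b in range(a + 1, len(pairs)):
                k, l = pairs[b]
                if i < k < j < l:
                    crossing.add(pairs[a])
                    crossing.add(pairs[b])
        if crossing:
            census.structures_with_crossings += 1
            census.crossing_pairs += len(crossing)
        degree: dict[int, int] = {}
        for i, j in pairs:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        multi = sum(
            1
            for i, j in pairs
            for pos in (i, j)
            if degree[pos] >= 2
        )
        if multi:
            census.structures_with_multipairs += 1
            census.multi_pairings += multi
    return census


def pairtable_to_matrix(pt: PairTable) -> np.ndarray:
    """Binary symmetric ground-truth base-pair matrix (zero diagonal)."""
    m = np.zeros((pt.n, pt.n))
    for i, j in pt.pairs():
        m[i, j] = m[j, i] = 1.0
    return m


def matrix_to_structure(
    m: np.ndarray,
    threshold: float = 0.5,
    symmetrize: str = "either",
) -> PairTable:
    """Reduce an n x n score matrix to a valid nested structure.

    Keeps only the highest entry per row (ties toward smaller column),
    drops entries below ``threshold``, symmetrizes (``either``: row max in
    row i or row j with mean score >= threshold; ``both``: row max in both),
    then removes remaining conflicts and pseudoknots by max-weight nested
    subset selection.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if symmetrize not in ("either", "both"):
        raise ValueError("symmetrize must be 'either' or 'both'")
    n = m.shape[0]
    if n == 0:
        return PairTable.from_pairs(0, [])
    row_argmax = np.argmax(m, axis=1)  # ties -> smallest index
    row_ok = m[np.arange(n), row_argmax] >= threshold
    survived = set()
    for i in range(n):
        if row_ok[i] and row_argmax[i] != i:
            survived.add((i, int(row_argmax[i])))
    candidates = {}
    for i, j in survived:
        a, b = min(i, j), max(i, j)
        ok = (
            ((a, b) in survived or (b, a) in survived)
            if symmetrize == "either"
            else ((a, b) in survived and (b, a) in survived)
        )
        mean = 0.5 * (m[a, b] + m[b, a])
        if ok and mean >= threshold:
            candidates[(a, b)] = mean
    raw = RawPairAssignment(n, sorted(candidates), dict(candidates))
    return remove_pseudoknots(raw)
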