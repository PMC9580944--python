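"""Inverse folding: design a sequence whose MFE structure matches a target.

Adaptive-walk search against the folding oracle: start from a random
structure-compatible sequence, mutate (paired positions change as canonical
pairs), accept when the base-pair distance to the target does not increase.
The best sequence over ``tries`` independent walks is returned, mirroring
the best-of-k protocol of classical inverse-folding tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..fold import FoldingOracle, get_oracle
from ..structures import PairTable, parse_dotbracket

# canonical pairs with stability-biased sampling weights
_PAIRS = ["GC", "CG", "AU", "UA", "GU", "UG"]
_PAIR_W = np.array([0.3, 0.3, 0.15, 0.15, 0.05, 0.05])
_BASES = list("ACGU")


def basepair_distance(a: PairTable, b: PairTable) -> int:
    """Size of the symmetric difference of the two pair sets."""
    return len(set(a.pairs()) ^ set(b.pairs()))


def _seed_sequence(target: PairTable, rng: np.random.Generator) -> list[str]:
    seq = [""] * target.n
    for i in range(target.n):
        if target.partner[i] == -1:
            seq[i] = "A"
    for i, j in target.pairs():
        p = _PAIRS[rng.choice(len(_PAIRS), p=_PAIR_W)]
        seq[i], seq[j] = p[0], p[1]
    return seq


@dataclass
class InverseFoldResult:
    sequence: str
    distance: int
    structure: PairTable  # achieved MFE structure


def inverse_fold(
    target: PairTable,
    oracle: FoldingOracle | None = None,
    tries: int = 6,
    seed: int | np.random.Generator = 0,
    max_steps: int = 300,
) -> InverseFoldResult:
    """Search for a sequence folding into ``target``; best of ``tries`` runs."""
    if target.has_crossings:
        raise ValueError("inverse folding target must be nested")
    oracle = oracle or get_oracle()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    best: InverseFoldResult | None = None
    for _ in range(max(1, tries)):
        res = _adaptive_walk(target, oracle, rng, max_steps)
        if best is None or res.distance < best.distance:
            best = res
        if best.distance == 0:
            break
    return best


def _mutate(seq, target, rng) -> list[str]:
    out = list(seq)
    i = int(rng.integers(target.n))
    j = target.partner[i]
    if j == -1:
        out[i] = _BASES[int(rng.integers(4))]
    else:
        p = _PAIRS[rng.choice(len(_PAIRS), p=_PAIR_W)]
        a, b = (i, j) if i < j else (j, i)
        out[a], out[b] = p[0], p[1]
    return out


def _adaptive_walk(target, oracle, rng, max_steps) -> InverseFoldResult:
    seq = _seed_sequence(target, rng)
    folded = parse_dotbracket(oracle.fold("".join(seq)))
    dist = basepair_distance(folded, target)
    for _ in range(max_steps):
        if dist == 0:
            break
        cand = _mutate(seq, target, rng)
        cf = parse_dotbracket(oracle.fold("".join(cand)))
        cd = basepair_distance(cf, target)
        if cd <= dist:
            seq, folded, dist = cand, cf, cd
    return InverseFoldResult("".join(seq), dist, folded)
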