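"""Structure-biased dataset construction.

``bias_emulator`` produces a repetitive, structure-biased collection built
from a handful of structure shape families (hairpin / two-hairpin /
cloverleaf-like templates with jittered helix and loop sizes), standing in
for large curated collections whose diversity is dominated by few families.
``replicate_bias_dataset`` turns any structure collection into a
sequence-diverse but structure-biased dataset by inverse folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..fold import FoldingOracle, get_oracle
from ..structures import (
    PairTable,
    RawPairAssignment,
    parse_dotbracket,
    remove_pseudoknots,
)
from .bundle import DatasetBundle
from .inverse import inverse_fold


def _hairpin(rng, stem=(4, 9), loop=(3, 8)) -> str:
    s = int(rng.integers(*stem))
    l = int(rng.integers(*loop))
    return "(" * s + "." * l + ")" * s


def _shape_single(rng) -> str:
    tail5 = "." * int(rng.integers(0, 4))
    tail3 = "." * int(rng.integers(0, 4))
    return tail5 + _hairpin(rng, (6, 12), (3, 9)) + tail3


def _shape_two_hairpin(rng) -> str:
    mid = "." * int(rng.integers(1, 5))
    return (
        "." * int(rng.integers(0, 3))
        + _hairpin(rng)
        + mid
        + _hairpin(rng)
        + "." * int(rng.integers(0, 3))
    )


def _shape_cloverleaf(rng) -> str:
    stem = int(rng.integers(3, 6))
    arms = "".join(
        _hairpin(rng, (3, 5), (4, 8)) + "." * int(rng.integers(0, 3))
        for _ in range(3)
    )
    return "(" * stem + "." * 2 + arms + ")" * stem + "." * int(rng.integers(0, 3))


def _shape_bulged(rng) -> str:
    s1 = int(rng.integers(3, 6))
    s2 = int(rng.integers(3, 6))
    bulge = "." * int(rng.integers(1, 4))
    loop = "." * int(rng.integers(3, 7))
    return "(" * s1 + bulge + "(" * s2 + loop + ")" * s2 + ")" * s1

_SHAPES = [_shape_cloverleaf, _shape_single, _shape_two_hairpin, _shape_bulged]


def bias_emulator(
    n_shapes: int,
    n_per_shape: int,
    seed: int = 0,
    lmin: int = 25,
    lmax: int = 120,
) -> list[PairTable]:
    """Emit a structure-biased, sequence-free collection of nested shapes."""
    if n_shapes < 1:
        raise ValueError("n_shapes must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_shapes):
        make = _SHAPES[k % len(_SHAPES)]
        for _ in range(n_per_shape):
            for _attempt in range(100):
                db = make(rng)
                if lmin <= len(db) <= lmax:
                    out.append(parse_dotbracket(db))
                    break
            else:  # pragma: no cover - templates stay in range
                raise RuntimeError("shape template out of length range")
    return out


@dataclass
class BiasDatasetReport:
    n_input: int
    n_length_filtered: int
    n_pseudoknot_dropped: int
    n_kept: int
    exact_designs: int


def replicate_bias_dataset(
    structures,
    oracle: FoldingOracle | None = None,
    seed: int = 0,
    tries: int = 6,
    max_crossing_pairs: int = 6,
    lmin: int = 25,
    lmax: int = 120,
    val_fraction: float = 0.2,
    max_steps: int = 300,
) -> tuple[DatasetBundle, DatasetBundle, BiasDatasetReport]:
    """Inverse-fold a structure collection into a biased training dataset.

    Structures are length-filtered, pseudoknots removed (structures with
    more than ``max_crossing_pairs`` crossing-involved pairs dropped), each
    survivor inverse-folded, and the oracle refold of the designed sequence
    used as ground truth.  Returns (train, validation, report) with a
    seeded 80/20 split.
    """
    oracle = oracle or get_oracle()
    rng = np.random.default_rng(seed)
    n_input = len(structures)
    kept_targets = []
    n_lenfail = n_pkdrop = 0
    for pt in structures:
        if not (lmin <= pt.n <= lmax):
            n_lenfail += 1
            continue
        pairs = pt.pairs()
        crossing = set()
        for a in range(len(pairs)):
            i, j = pairs[a]
            for b in range(a + 1, len(pairs)):
                k, l = pairs[b]
                if i < k < j < l:
                    crossing.add(pairs[a])
                    crossing.add(pairs[b])
        if len(crossing) > max_crossing_pairs:
            n_pkdrop += 1
            continue
        if crossing:
            pt = remove_pseudoknots(RawPairAssignment(pt.n, pairs))
        kept_targets.append(pt)
    seqs, pts = [], []
    exact = 0
    seen = set()
    for pt in kept_targets:
        res = inverse_fold(pt, oracle, tries=tries, seed=rng,
                           max_steps=max_steps)
        if res.sequence in seen:
            continue
        seen.add(res.sequence)
        if res.distance == 0:
            exact += 1
        seqs.append(res.sequence)
        pts.append(res.structure)  # ground truth = refolded structure
    idx = rng.permutation(len(seqs))
    n_val = int(round(val_fraction * len(seqs)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    prov = {"seed": seed, "oracle": oracle.ident, "tries": tries}
    train = DatasetBundle(
        [seqs[i] for i in train_idx], [pts[i] for i in train_idx],
        dict(prov), "train",
    )
    val = DatasetBundle(
        [seqs[i] for i in val_idx], [pts[i] for i in val_idx],
        dict(prov), "validation",
    )
    report = BiasDatasetReport(
        n_input=n_input,
        n_length_filtered=n_lenfail,
        n_pseudoknot_dropped=n_pkdrop,
        n_kept=len(seqs),
        exact_designs=exact,
    )
    return train, val, report
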