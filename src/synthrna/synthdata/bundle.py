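"""Dataset bundles: aligned sequences + ground-truth structures + provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..fold import FoldingOracle, get_oracle
from ..structures import PairTable, parse_dotbracket, read_dbn, write_dbn
from .sampling import (
    PRESETS,
    UNIFORM_COMPOSITION,
    LengthDistributionSpec,
    fixed_length,
    sample_sequences,
)


@dataclass
class DatasetBundle:
    """Aligned sequences and ground-truth structures with provenance."""

    sequences: list
    structures: list
    provenance: dict = field(default_factory=dict)
    split: str = "train"

    def __post_init__(self):
        if len(self.sequences) != len(self.structures):
            raise ValueError("sequences and structures must be aligned")
        for s, pt in zip(self.sequences, self.structures):
            if len(s) != pt.n:
                raise ValueError("sequence/structure length mismatch")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate sequences in bundle")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(zip(self.sequences, self.structures))

    def subset(self, idx) -> "DatasetBundle":
        return DatasetBundle(
            [self.sequences[i] for i in idx],
            [self.structures[i] for i in idx],
            dict(self.provenance),
            self.split,
        )

    def to_dbn(self, path) -> None:
        from ..structures import write_dotbracket

        write_dbn(
            path,
            (
                (f"{self.split}_{k}", s, write_dotbracket(pt))
                for k, (s, pt) in enumerate(self)
            ),
        )
        manifest = str(path) + ".json"
        with open(manifest, "w") as fh:
            json.dump(
                {"split": self.split, "count": len(self), **self.provenance},
                fh,
                indent=2,
            )

    @classmethod
    def from_dbn(cls, path, split: str = "train") -> "DatasetBundle":
        records = read_dbn(path)
        seqs = [r[1] for r in records]
        pts = [parse_dotbracket(r[2]) for r in records]
        prov = {"source": str(path)}
        try:
            with open(str(path) + ".json") as fh:
                prov.update(json.load(fh))
        except FileNotFoundError:
            pass
        return cls(seqs, pts, prov, split)


def fold_dataset(
    seqs, oracle: FoldingOracle | None = None, provenance: dict | None = None,
    split: str = "train",
) -> DatasetBundle:
    """Fold every sequence with the oracle to obtain ground truth."""
    oracle = oracle or get_oracle()
    pts = [parse_dotbracket(oracle.fold(s)) for s in seqs]
    prov = dict(provenance or {})
    prov["oracle"] = oracle.ident
    return DatasetBundle(list(seqs), pts, prov, split)


def make_dataset(
    count: int,
    dist: LengthDistributionSpec,
    seed: int,
    composition=UNIFORM_COMPOSITION,
    oracle: FoldingOracle | None = None,
    split: str = "train",
) -> DatasetBundle:
    """Sample + fold in one step, with full provenance recorded."""
    seqs = sample_sequences(count, dist, composition, seed)
    return fold_dataset(
        seqs,
        oracle,
        {
            "sampler": {
                "kind": dist.kind,
                "lmin": dist.lmin,
                "lmax": dist.lmax,
                "params": list(dist.params),
                "name": dist.name,
            },
            "composition": list(composition),
            "seed": seed,
            "count": count,
        },
        split,
    )


def preset_distribution_sets(
    preset: str,
    seed: int,
    train_size: int = 30000,
    val_size: int = 5000,
    oracle: FoldingOracle | None = None,
) -> tuple[DatasetBundle, DatasetBundle]:
    """Train/validation bundles for one of the D1-D4 length presets."""
    dist = PRESETS[preset]
    rng = np.random.default_rng(seed)
    seqs = sample_sequences(train_size + val_size, dist, seed=rng)
    prov = {"preset": preset, "seed": seed}
    train = fold_dataset(seqs[:train_size], oracle, prov, "train")
    val = fold_dataset(seqs[train_size:], oracle, prov, "validation")
    return train, val


def length_series_sets(
    lengths=range(30, 251, 20),
    per_bin: int = 2000,
    seed: int = 0,
    oracle: FoldingOracle | None = None,
) -> dict[int, DatasetBundle]:
    """One oracle-folded bundle of ``per_bin`` sequences per length."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("lengths must be non-empty")
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for n in lengths:
        seqs = sample_sequences(per_bin, fixed_length(n), seed=rng)
        out[n] = fold_dataset(
            seqs, oracle, {"length": n, "seed": seed}, "test"
        )
    return out
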