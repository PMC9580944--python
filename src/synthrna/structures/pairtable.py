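"""Core secondary-structure representations and dot-bracket/bpseq I/O.

All coordinates are 0-based internally; bpseq records are 1-based on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = set("ACGU")
UNPAIRED = -1

# bracket tiers; tiers beyond "()" encode crossing (pseudoknotted) pairs
_OPEN = "([{<"
_CLOSE = ")]}>"

_CANONICAL = {
    ("G", "C"): "GC", ("C", "G"): "CG",
    ("A", "U"): "AU", ("U", "A"): "UA",
    ("G", "U"): "GU", ("U", "G"): "UG",
}

PAIR_TYPES = ("GC", "CG", "AU", "UA", "GU", "UG", "NC")


@dataclass(frozen=True)
class RnaSequence:
    """Validated RNA sequence over {A,C,G,U}."""

    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"non-ACGU residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


class PairTable:
    """Per-nucleotide partner index (at most one partner per position).

    Crossing pairs are representable (``has_crossings`` flags them); multiple
    partners per position are not — use :class:`RawPairAssignment` for raw
    network output.
    """

    __slots__ = ("n", "partner")

    def __init__(self, partner: np.ndarray | list):
        partner = np.asarray(partner, dtype=np.int64)
        n = len(partner)
        for i, j in enumerate(partner):
            if j == UNPAIRED:
                continue
            if not 0 <= j < n:
                raise ValueError(f"partner index {j} out of range at {i}")
            if j == i:
                raise ValueError(f"self-pair at position {i}")
            if partner[j] != i:
                raise ValueError(f"asymmetric pairing at ({i},{j})")
        self.n = n
        self.partner = partner

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "PairTable":
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for i, j in pairs:
            if partner[i] != UNPAIRED or partner[j] != UNPAIRED:
                raise ValueError(f"position in pair ({i},{j}) already paired")
            partner[i], partner[j] = j, i
        return cls(partner)

    def pairs(self) -> list[tuple[int, int]]:
        """Canonical (i, j) with i < j, sorted."""
        return [
            (i, int(j)) for i, j in enumerate(self.partner) if j > i
        ]

    @property
    def has_crossings(self) -> bool:
        ps = self.pairs()
        for a, (i, j) in enumerate(ps):
            for k, l in ps[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    return True
        return False

    def __eq__(self, other) -> bool:
        return isinstance(other, PairTable) and np.array_equal(
            self.partner, other.partner
        )

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairTable({write_dotbracket(self)!r})"


@dataclass
class RawPairAssignment:
    """Pair list that may contain crossings and multi-partnered positions."""

    n: int
    pairs: list = field(default_factory=list)
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        canon = []
        for i, j in self.pairs:
            if not (0 <= i < self.n and 0 <= j < self.n and i != j):
                raise ValueError(f"bad pair ({i},{j}) for n={self.n}")
            canon.append((min(i, j), max(i, j)))
        self.pairs = sorted(set(canon))


def parse_dotbracket(text: str) -> PairTable:
    """Parse a dot-bracket string (multi-tier brackets allowed)."""
    partner = np.full(len(text), UNPAIRED, dtype=np.int64)
    stacks: list[list[int]] = [[] for _ in _OPEN]
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            tier = _CLOSE.index(ch)
            if not stacks[tier]:
                raise ValueError(f"unbalanced '{ch}' at position {pos}")
            i = stacks[tier].pop()
            partner[i], partner[pos] = pos, i
        else:
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    for tier, stk in enumerate(stacks):
        if stk:
            raise ValueError(
                f"unbalanced '{_OPEN[tier]}' at position {stk[-1]}"
            )
    return PairTable(partner)


def write_dotbracket(pt: PairTable) -> str:
    """Dot-bracket string; crossing pairs go to higher bracket tiers."""
    from .algebra import remove_pseudoknots  # cycle-free at call time

    out = ["."] * pt.n
    remaining = RawPairAssignment(pt.n, pt.pairs())
    tier = 0
    while remaining.pairs:
        if tier >= len(_OPEN):
            raise ValueError("structure needs more than 4 bracket tiers")
        nested = remove_pseudoknots(remaining)
        for i, j in nested.pairs():
            out[i], out[j] = _OPEN[tier], _CLOSE[tier]
        left = set(remaining.pairs) - set(nested.pairs())
        remaining = RawPairAssignment(pt.n, sorted(left))
        tier += 1
    return "".join(out)


def pair_type(a: str, b: str) -> str:
    """Classify an ordered residue pair into GC/CG/AU/UA/GU/UG/NC."""
    return _CANONICAL.get((a, b), "NC")


# ---------------------------------------------------------------------------
# file formats


def read_dbn(path) -> list[tuple[str, str, str]]:
    """Read 3-line (>id / sequence / structure) records; returns tuples."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for k in range(0, len(lines), 3):
        header = lines[k]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header at line {k + 1}")
        records.append((header[1:].strip(), lines[k + 1], lines[k + 2]))
    return records


def write_dbn(path, records) -> None:
    """Write (id, sequence, structure) triples as a .dbn file."""
    with open(path, "w") as fh:
        for name, seq, db in records:
            fh.write(f">{name}\n{seq}\n{db}\n")


def read_bpseq(path) -> tuple[str, PairTable]:
    """Read a bpseq file (1-based 'index residue partner', 0 = unpaired)."""
    seq, partners = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, res, par = line.split()
            if int(idx) != len(seq) + 1:
                raise ValueError(f"non-sequential bpseq index {idx}")
            seq.append(res.upper())
            partners.append(int(par) - 1)  # 0 -> -1 (unpaired)
    return "".join(seq), PairTable(np.array(partners, dtype=np.int64))


def write_bpseq(path, seq: str, pt: PairTable) -> None:
    with open(path, "w") as fh:
        for i, res in enumerate(seq):
            j = pt.partner[i]
            fh.write(f"{i + 1} {res} {0 if j == UNPAIRED else int(j) + 1}\n")
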