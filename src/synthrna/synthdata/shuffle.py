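"""Exact dinucleotide-preserving sequence shuffling (Euler-walk method).

Builds the dinucleotide multigraph of the input, samples a random Eulerian
walk from the first residue to the last, and reads the shuffled sequence off
the walk.  The set of last-out-edges is rejection-sampled until it forms an
arborescence into the final vertex, which makes the walk a valid Euler path
(Altschul-Erickson construction); first residue, last residue, mono- and
dinucleotide counts are all conserved exactly.
"""

from __future__ import annotations

import numpy as np


def _dinucleotide_counts(seq: str) -> dict:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


def dinucleotide_shuffle(
    seq: str, seed: int | np.random.Generator = 0
) -> str:
    """Random permutation of ``seq`` preserving exact dinucleotide counts."""
    s = str(seq)
    if len(s) < 2:
        raise ValueError("need a sequence of length >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = [v for v in edges if v != last]

    def _reaches_last(last_edge: dict) -> bool:
        for v in vertices:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in last_edge:
                    return False
                seen.add(u)
                u = last_edge[u]
        return True

    while True:
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))]
                     for v in vertices}
        if _reaches_last(last_edge):
            break
    walk_lists = {}
    for v, succ in edges.items():
        succ = list(succ)
        if v in last_edge:
            succ.remove(last_edge[v])
        rng.shuffle(succ)
        if v in last_edge:
            succ.append(last_edge[v])
        walk_lists[v] = succ
    out = [first]
    pos = {v: 0 for v in edges}
    u = first
    for _ in range(len(s) - 1):
        nxt = walk_lists[u][pos[u]]
        pos[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)
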