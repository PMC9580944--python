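"""Loop decomposition and aggregate structural statistics.

Unpaired bases are classified by the loop that encloses them:

* ``EL`` exterior loop (not enclosed by any pair)
* ``HL`` hairpin loop (closing pair, no branch helices)
* ``BL`` bulge loop (one branch, unpaired bases on exactly one side)
* ``IL`` interior loop (one branch, unpaired bases on both sides)
* ``ML`` multiloop (two or more branches)

Paired bases are labeled ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairtable import PAIR_TYPES, PairTable, pair_type

CONTEXTS = ("P", "EL", "BL", "HL", "IL", "ML")
ELEMENTS = ("helix", "EL", "BL", "HL", "IL", "ML")


@dataclass
class LoopAnnotation:
    """Per-position structural context labels."""

    labels: list

    def counts(self) -> dict:
        out = {c: 0 for c in CONTEXTS}
        for lab in self.labels:
            out[lab] += 1
        return out


@dataclass
class _Loop:
    opener: int
    children: list = field(default_factory=list)  # (start, end) branch spans
    unpaired: list = field(default_factory=list)


def _decompose(pt: PairTable):
    """Yield (kind, loop) for every loop; kind in EL/HL/BL/IL/ML.

    Stacked pairs (one branch, no unpaired bases on either side) are helix
    continuations, not loops, and are skipped.
    """
    exterior = _Loop(opener=-1)
    stack = [exterior]
    i = 0
    n = pt.n
    partner = pt.partner
    while i < n:
        j = partner[i]
        if j == -1:
            stack[-1].unpaired.append(i)
            i += 1
        elif j > i:
            loop = _Loop(opener=i)
            stack.append(loop)
            i += 1
        else:  # closing bracket
            loop = stack.pop()
            if loop.opener != j:
                raise ValueError(
                    "loop decomposition requires a nested structure; "
                    "call remove_pseudoknots first"
                )
            stack[-1].children.append((j, i))
            kind = _classify(loop, closing=(j, i))
            if kind is not None:
                yield kind, loop
            i += 1
    yield "EL", exterior


def _classify(loop: _Loop, closing) -> str | None:
    nb = len(loop.children)
    if nb == 0:
        return "HL"
    if nb >= 2:
        return "ML"
    (cs, ce) = loop.children[0]
    u5 = cs - closing[0] - 1
    u3 = closing[1] - ce - 1
    if u5 > 0 and u3 > 0:
        return "IL"
    if u5 == 0 and u3 == 0:
        return None  # stacked pair
    return "BL"


def loop_decomposition(pt: PairTable) -> LoopAnnotation:
    """Label every position with its structural context."""
    if pt.has_crossings:
        raise ValueError(
            "loop_decomposition requires a nested structure; "
            "call remove_pseudoknots first"
        )
    labels = ["P"] * pt.n
    for kind, loop in _decompose(pt):
        for u in loop.unpaired:
            labels[u] = kind
    return LoopAnnotation(labels)


def count_elements(pt: PairTable) -> dict:
    """Per-structure element counts (helices and loop instances).

    A helix is a maximal run of stacked pairs.  The exterior loop counts as
    one element for any structure (mean EL is ~1 by convention).
    """
    if pt.has_crossings:
        raise ValueError("count_elements requires a nested structure")
    counts = {e: 0 for e in ELEMENTS}
    partner = pt.partner
    for i, j in pt.pairs():
        # helix start: (i-1, j+1) is not a pair
        if i == 0 or j == pt.n - 1 or partner[i - 1] != j + 1:
            counts["helix"] += 1
    for kind, _loop in _decompose(pt):
        if kind != "EL":
            counts[kind] += 1
    counts["EL"] = 1 if pt.n >= 1 else 0
    return counts


def multiloop_lengths(pt: PairTable) -> list[int]:
    """Number of unpaired nucleotides inside each multiloop."""
    if pt.has_crossings:
        raise ValueError("multiloop_lengths requires a nested structure")
    return [
        len(loop.unpaired) for kind, loop in _decompose(pt) if kind == "ML"
    ]


def pairtype_frequencies(seq, pt: PairTable) -> dict:
    """Counts of ordered pair types GC/CG/AU/UA/GU/UG/NC."""
    s = str(seq)
    if len(s) != pt.n:
        raise ValueError(f"sequence length {len(s)} != structure length {pt.n}")
    out = {t: 0 for t in PAIR_TYPES}
    for i, j in pt.pairs():
        out[pair_type(s[i], s[j])] += 1
    return out


@dataclass
class StructureStatsReport:
    """Aggregate structural statistics over a structure collection."""

    context_freq: dict  # base fractions per context
    element_counts: dict  # mean per-structure counts
    pairtype_freq: dict  # pair fractions per type
    multiloop_length_median: float | None
    n_structures: int
    context_freq_se: dict = field(default_factory=dict)
    element_counts_se: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "context_freq": self.context_freq,
            "element_counts": self.element_counts,
            "pairtype_freq": self.pairtype_freq,
            "multiloop_length_median": self.multiloop_length_median,
            "n_structures": self.n_structures,
        }


def aggregate_stats(seqs, pts) -> StructureStatsReport:
    """Pooled context/pair-type fractions, mean element counts, ML median.

    Monte-Carlo standard errors (over structures) are attached for the
    context fractions and element counts.
    """
    seqs, pts = list(seqs), list(pts)
    if not seqs or len(seqs) != len(pts):
        raise ValueError("need non-empty, aligned sequence/structure inputs")
    ctx_frac = {c: [] for c in CONTEXTS}
    ctx_tot = {c: 0 for c in CONTEXTS}
    elem = {e: [] for e in ELEMENTS}
    ptype_tot = {t: 0 for t in PAIR_TYPES}
    ml_lengths: list[int] = []
    for seq, pt in zip(seqs, pts):
        counts = loop_decomposition(pt).counts()
        for c in CONTEXTS:
            ctx_frac[c].append(counts[c] / pt.n)
            ctx_tot[c] += counts[c]
        ec = count_elements(pt)
        for e in ELEMENTS:
            elem[e].append(ec[e])
        for t, v in pairtype_frequencies(seq, pt).items():
            ptype_tot[t] += v
        ml_lengths.extend(multiloop_lengths(pt))
    total_bases = sum(pt.n for pt in pts)
    ctx_pooled = {c: ctx_tot[c] / total_bases for c in CONTEXTS}
    npairs = sum(ptype_tot.values())
    k = len(seqs)
    return StructureStatsReport(
        context_freq=ctx_pooled,
        element_counts={e: float(np.mean(v)) for e, v in elem.items()},
        pairtype_freq={
            t: (v / npairs if npairs else 0.0) for t, v in ptype_tot.items()
        },
        multiloop_length_median=(
            float(np.median(ml_lengths)) if ml_lengths else None
        ),
        n_structures=k,
        context_freq_se={
            c: float(np.std(v, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
            for c, v in ctx_frac.items()
        },
        element_counts_se={
            e: float(np.std(v, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
            for e, v in elem.items()
        },
    )
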