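"""Random sequence sampling under configurable length distributions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.array(list("ACGU"))
UNIFORM_COMPOSITION = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class LengthDistributionSpec:
    """Sequence-length law on an integer support [lmin, lmax].

    kinds: ``fixed`` (lmin == lmax), ``uniform``, ``beta`` (discretized
    beta(a, b) stretched over the support), ``empirical`` (explicit pmf).
    """

    kind: str
    lmin: int
    lmax: int
    params: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.lmin < 1 or self.lmax < self.lmin:
            raise ValueError(f"bad support [{self.lmin}, {self.lmax}]")
        if self.kind not in ("fixed", "uniform", "beta", "empirical"):
            raise ValueError(f"unknown length distribution kind {self.kind!r}")

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(count, self.lmin, dtype=np.int64)
        if self.kind == "uniform":
            return rng.integers(self.lmin, self.lmax + 1, size=count)
        if self.kind == "beta":
            a, b = self.params
            x = rng.beta(a, b, size=count)
            span = self.lmax - self.lmin + 1
            return np.minimum(
                self.lmin + np.floor(x * span).astype(np.int64), self.lmax
            )
        pmf = np.asarray(self.params, dtype=float)
        pmf = pmf / pmf.sum()
        return rng.choice(
            np.arange(self.lmin, self.lmax + 1), size=count, p=pmf
        )


def fixed_length(n: int) -> LengthDistributionSpec:
    return LengthDistributionSpec("fixed", n, n, name=f"fixed{n}")


# Fig-2-style presets on 25-100 nt.  The exact shapes of the originals are
# not published; these are representative choices (uniform / skewed-long /
# symmetric-unimodal / strongly-skewed-short) exposed for configuration.
PRESETS = {
    "D1": LengthDistributionSpec("uniform", 25, 100, name="D1"),
    "D2": LengthDistributionSpec("beta", 25, 100, (5.0, 1.8), name="D2"),
    "D3": LengthDistributionSpec("beta", 25, 100, (5.0, 5.0), name="D3"),
    "D4": LengthDistributionSpec("beta", 25, 100, (1.0, 6.0), name="D4"),
}


def sample_sequences(
    count: int,
    dist: LengthDistributionSpec,
    composition=UNIFORM_COMPOSITION,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``count`` distinct random sequences (duplicates are re-drawn)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a 4-vector summing to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # uniqueness is only enforceable when the reachable sequence space is
    # large enough (degenerate compositions may admit a single sequence)
    n_letters = int((comp > 0).sum())
    space = float(n_letters) ** dist.lmin
    enforce_unique = space >= 4 * count
    seen: set[str] = set()
    out: list[str] = []
    guard = 0
    while len(out) < count:
        need = count - len(out)
        lengths = dist.sample(need, rng)
        for n in lengths:
            s = "".join(rng.choice(BASES, size=int(n), p=comp))
            if not enforce_unique or s not in seen:
                seen.add(s)
                out.append(s)
        guard += 1
        if guard > 1000:  # pragma: no cover - defensive
            raise RuntimeError("could not draw enough distinct sequences")
    return out
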