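"""Folding oracles: sequence -> pseudoknot-free MFE dot-bracket."""

from __future__ import annotations

from functools import lru_cache

from .nussinov import nussinov_fold
from .params import load_params


class FoldingOracle:
    """Deterministic folding engine with a stable identifier.

    ``turner`` is the bundled Turner-2004 nearest-neighbor MFE folder;
    ``fallback`` is a base-pair-maximization dynamic program (non-Turner,
    for environments where speed matters more than realism).
    """

    def __init__(self, engine: str = "turner"):
        if engine not in ("turner", "fallback"):
            raise ValueError(f"unknown folding engine {engine!r}")
        self.engine = engine
        if engine == "turner":
            from .engine import MfeFolder

            self._folder = MfeFolder(load_params())
            self.ident = "turner2004-d2"
        else:
            self._folder = None
            self.ident = "nussinov-maxpair"

    def fold(self, seq: str) -> str:
        """MFE dot-bracket structure for ``seq``."""
        if self.engine == "turner":
            return self._folder.fold(seq)[0]
        return nussinov_fold(seq)

    def fold_energy(self, seq: str) -> tuple[str, float]:
        """(structure, energy kcal/mol); energy is -pairs for the fallback."""
        if self.engine == "turner":
            return self._folder.fold(seq)
        db = nussinov_fold(seq)
        return db, -float(db.count("("))


@lru_cache(maxsize=4)
def get_oracle(engine: str = "turner") -> FoldingOracle:
    return FoldingOracle(engine)
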