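"""Nearest-neighbor energy parameter tables.

Reads the standard RNAfold parameter file format (v2.0) into dense numpy
arrays suitable for the dynamic-programming engine.  Energies are stored in
dekacal/mol (i.e. 10*kcal/mol) as in the file; the engine converts to
kcal/mol only when reporting.

Index conventions (identical to the common C implementations):

* bases:  0 = N/none, 1 = A, 2 = C, 3 = G, 4 = U
* pair types: 0 = non-pairing, 1 = CG, 2 = GC, 3 = GU, 4 = UG,
  5 = AU, 6 = UA, 7 = NN (unused here; only canonical pairs are formed)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

INF = 1_000_000  # large sentinel, safe to add a few times in int64
MAXLOOP = 30

BASES = "NACGU"
BASE_INDEX = {c: i for i, c in enumerate(BASES)}

# pair-type lookup: PAIR_TYPE[si][sj]
PAIR_TYPE = np.zeros((5, 5), dtype=np.int64)
for _t, (_a, _b) in enumerate(
    [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")], start=1
):
    PAIR_TYPE[BASE_INDEX[_a], BASE_INDEX[_b]] = _t

_NUM_RE = re.compile(r"-?\d+|INF|DEF|NST")


def _tokens(body: str) -> list[int]:
    body = re.sub(r"/\*.*?\*/", "", body, flags=re.S)
    out = []
    for tok in _NUM_RE.findall(body):
        if tok == "INF":
            out.append(INF)
        elif tok == "DEF":
            out.append(-50)
        elif tok == "NST":
            out.append(0)
        else:
            out.append(int(tok))
    return out


@dataclass
class TurnerParams:
    """Parsed free-energy tables (37 °C values only)."""

    stack: np.ndarray  # [8,8]
    hairpin: np.ndarray  # [31]
    bulge: np.ndarray  # [31]
    internal: np.ndarray  # [31]
    mismatch_hairpin: np.ndarray  # [8,5,5]
    mismatch_interior: np.ndarray  # [8,5,5]
    mismatch_interior_1n: np.ndarray  # [8,5,5]
    mismatch_interior_23: np.ndarray  # [8,5,5]
    mismatch_multi: np.ndarray  # [8,5,5]
    mismatch_exterior: np.ndarray  # [8,5,5]
    dangle5: np.ndarray  # [8,5]
    dangle3: np.ndarray  # [8,5]
    int11: np.ndarray  # [8,8,5,5]
    int21: np.ndarray  # [8,8,5,5,5]
    int22: np.ndarray  # [8,8,5,5,5,5]
    ml_base: int  # per unpaired nt in multiloop
    ml_closing: int  # multiloop closing penalty
    ml_intern: int  # per branch
    ninio: int
    max_ninio: int
    terminal_au: int
    lxc: float
    special_hairpins: dict = field(default_factory=dict)  # seq -> energy
    ident: str = "turner2004"


def _sections(text: str) -> dict[str, str]:
    parts = re.split(r"^#\s*(\S[^\n]*)$", text, flags=re.M)
    out = {}
    for name, body in zip(parts[1::2], parts[2::2]):
        out[name.strip()] = body
    return out


def load_params(path: str | None = None) -> TurnerParams:
    """Load a v2.0 parameter file; default is the bundled Turner-2004 set."""
    if path is None:
        text = (
            resources.files("synthrna.fold") / "data" / "rna_turner2004.par"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    sec = _sections(text)

    def arr(name, shape, pair_dims=0, base_offset=0):
        """Reshape section tokens; pair dims are stored for types 1..k."""
        data = np.array(_tokens(sec[name]), dtype=np.int64).reshape(shape)
        # embed into full-size array indexed from 0
        full_shape = tuple(
            (s + 1) if d < pair_dims else (s + base_offset)
            for d, s in enumerate(shape)
        )
        full = np.full(full_shape, INF, dtype=np.int64)
        idx = tuple(
            slice(1, None) if d < pair_dims else slice(base_offset, None)
            for d in range(len(shape))
        )
        full[idx] = data
        return full

    stack = arr("stack", (7, 7), pair_dims=2)
    mh = arr("mismatch_hairpin", (7, 5, 5), pair_dims=1)
    mi = arr("mismatch_internal", (7, 5, 5), pair_dims=1)
    mi1n = arr("mismatch_internal_1n", (7, 5, 5), pair_dims=1)
    mi23 = arr("mismatch_internal_23", (7, 5, 5), pair_dims=1)
    mm = arr("mismatch_multi", (7, 5, 5), pair_dims=1)
    me = arr("mismatch_exterior", (7, 5, 5), pair_dims=1)
    d5 = arr("dangle5", (7, 5), pair_dims=1)
    d3 = arr("dangle3", (7, 5), pair_dims=1)
    int11 = arr("int11", (7, 7, 5, 5), pair_dims=2)
    int21 = arr("int21", (7, 7, 5, 5, 5), pair_dims=2)
    # int22 covers pairs 1..6 and real bases 1..4 only
    int22_raw = np.array(_tokens(sec["int22"]), dtype=np.int64).reshape(
        6, 6, 4, 4, 4, 4
    )
    int22 = np.full((8, 8, 5, 5, 5, 5), INF, dtype=np.int64)
    int22[1:7, 1:7, 1:, 1:, 1:, 1:] = int22_raw

    hairpin = np.array(_tokens(sec["hairpin"]), dtype=np.int64)
    bulge = np.array(_tokens(sec["bulge"]), dtype=np.int64)
    internal = np.array(_tokens(sec["internal"]), dtype=np.int64)

    ml = _tokens(sec["ML_params"])  # cu cu_dH cc cc_dH ci ci_dH
    ninio = _tokens(sec["NINIO"])  # m m_dH max
    misc_body = re.sub(r"/\*.*?\*/", "", sec["Misc"], flags=re.S)
    misc = [float(t) for t in misc_body.split()]
    # DuplexInit DuplexInit_dH TerminalAU TerminalAU_dH LXC LXC_dH

    special = {}
    for name in ("Triloops", "Tetraloops", "Hexaloops"):
        for line in sec.get(name, "").splitlines():
            fields = line.split()
            if len(fields) >= 2 and set(fields[0]) <= set("ACGU"):
                special[fields[0]] = int(fields[1])

    return TurnerParams(
        stack=stack,
        hairpin=hairpin,
        bulge=bulge,
        internal=internal,
        mismatch_hairpin=mh,
        mismatch_interior=mi,
        mismatch_interior_1n=mi1n,
        mismatch_interior_23=mi23,
        mismatch_multi=mm,
        mismatch_exterior=me,
        dangle5=d5,
        dangle3=d3,
        int11=int11,
        int21=int21,
        int22=int22,
        ml_base=ml[0],
        ml_closing=ml[2],
        ml_intern=ml[4],
        ninio=ninio[0],
        max_ninio=ninio[2],
        terminal_au=int(misc[2]),
        lxc=misc[4],
        special_hairpins=special,
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGU string to the 1..4 integer encoding (0 for N)."""
    try:
        return np.array([BASE_INDEX[c] for c in seq.upper().replace("T", "U")],
                        dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGU residue {exc} in sequence") from None
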