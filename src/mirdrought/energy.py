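"""Nearest-neighbour energy model and structure evaluation.

The model is a deliberately simplified stack/loop parameterisation: stacking
energies for the six canonical pairs (AU, UA, GC, CG, GU, UG), length-dependent
hairpin/bulge/internal loop penalties with logarithmic extrapolation, a linear
multiloop cost, and a 0.5 kcal/mol penalty per AU/GU helix end. It provides a
consistent free-energy scale for hairpin assessment; it does not reproduce
Turner/mfold energies and is not meant to.

Energies are carried internally as integers in deci-kcal/mol (value * 10), so
that folding results are exactly reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from importlib import resources
from pathlib import Path

import numpy as np

#: base encoding used throughout the folding code
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: canonical pair types, indexed as PAIR_NAMES
PAIR_NAMES = ("AU", "UA", "GC", "CG", "GU", "UG")

# PAIR_TYPE[a, b] = index into PAIR_NAMES for bases a (5') and b (3'), else -1
PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _idx, _name in enumerate(PAIR_NAMES):
    PAIR_TYPE[BASE_CODE[_name[0]], BASE_CODE[_name[1]]] = _idx

MAX_SEQ_LEN = 1000
MIN_HAIRPIN_LOOP = 3

#: log-extrapolation coefficient for long loops, deci-kcal (1.1 kcal/mol)
_LOOP_EXTRAP = 11.0


def encode(seq: str) -> np.ndarray:
    """Encode an ACGU/ACGT string as an int8 array; raises on other letters."""
    try:
        return np.array([BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


@dataclasses.dataclass(frozen=True)
class EnergyModel:
    """All parameters in integer deci-kcal/mol."""

    stack: np.ndarray      # (6, 6) stack[outer_pair, inner_pair]
    hairpin: np.ndarray    # (MAX_SEQ_LEN + 1,) penalty by loop size
    bulge: np.ndarray
    internal: np.ndarray
    ml_a: int              # multiloop closing penalty
    ml_b: int              # per-branch penalty (closing pair included)
    ml_c: int              # per-unpaired-base penalty
    terminal: np.ndarray   # (6,) helix-end penalty by pair type

    @property
    def max_len(self) -> int:
        return MAX_SEQ_LEN


def _extrapolate(table: dict[int, int], min_size: int) -> np.ndarray:
    """Fill a loop-penalty array of length MAX_SEQ_LEN+1 (deci-kcal ints)."""
    out = np.full(MAX_SEQ_LEN + 1, 2**30, dtype=np.int64)
    last = max(table)
    for n in range(min_size, MAX_SEQ_LEN + 1):
        if n in table:
            out[n] = table[n]
        else:
            out[n] = table[last] + round(_LOOP_EXTRAP * math.log(n / last))
    return out


def load_model(path: str | Path | None = None) -> EnergyModel:
    """Load the energy model from a parameter TSV (default: packaged table)."""
    if path is None:
        path = resources.files("mirdrought.data") / "stack_energies.tsv"
    stack = np.zeros((6, 6), dtype=np.int64)
    hairpin: dict[int, int] = {}
    bulge: dict[int, int] = {}
    internal: dict[int, int] = {}
    ml = {}
    terminal = np.zeros(6, dtype=np.int64)
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, key, value = line.split("\t")
            deci = round(float(value) * 10)
            if kind == "stack":
                outer, inner = key.split(":")
                stack[PAIR_NAMES.index(outer), PAIR_NAMES.index(inner)] = deci
            elif kind == "hairpin":
                hairpin[int(key)] = deci
            elif kind == "bulge":
                bulge[int(key)] = deci
            elif kind == "internal":
                internal[int(key)] = deci
            elif kind == "multiloop":
                ml[key] = deci
            elif kind == "terminal":
                terminal[PAIR_NAMES.index(key)] = deci
            else:
                raise ValueError(f"unknown parameter kind {kind!r}")
    return EnergyModel(
        stack=stack,
        hairpin=_extrapolate(hairpin, MIN_HAIRPIN_LOOP),
        bulge=_extrapolate(bulge, 1),
        internal=_extrapolate(internal, 2),
        ml_a=ml["a"],
        ml_b=ml["b"],
        ml_c=ml["c"],
        terminal=terminal,
    )


@functools.lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    return load_model()


def validate_pairs(n: int, pairs: tuple[tuple[int, int], ...]) -> None:
    """Check 0-based pairs are in range, disjoint, nested, min-loop >= 3."""
    seen: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i},{j}) out of range")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"pair ({i},{j}) violates minimum loop size")
        if i in seen or j in seen:
            raise ValueError(f"base in more than one pair: ({i},{j})")
        seen.update((i, j))
    ordered = sorted(pairs)
    stack: list[tuple[int, int]] = []
    for i, j in ordered:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (stack[-1][0] < i and j < stack[-1][1]):
            raise ValueError(f"pseudoknot: ({i},{j}) crosses {stack[-1]}")
        stack.append((i, j))


def structure_energy_deci(
    codes: np.ndarray, pairs: tuple[tuple[int, int], ...], model: EnergyModel | None = None
) -> int:
    """Free energy of a nested structure, in deci-kcal/mol.

    Loop-decomposition evaluation: the energy is the sum over stacks, loop
    penalties (hairpin/bulge/internal/multiloop) and helix-end penalties. This
    evaluator defines the model; both the DP and the brute-force enumerator
    are checked against it.
    """
    model = model or default_model()
    n = len(codes)
    validate_pairs(n, pairs)
    if not pairs:
        return 0
    ordered = sorted(pairs)

    def pt(i: int, j: int) -> int:
        t = PAIR_TYPE[codes[i], codes[j]]
        if t < 0:
            raise ValueError(f"non-pairable bases at ({i},{j})")
        return int(t)

    # children[p] = pairs directly enclosed by p; roots = exterior branches
    roots: list[tuple[int, int]] = []
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in ordered}
    enclosing: list[tuple[int, int]] = []
    for p in ordered:
        while enclosing and enclosing[-1][1] < p[0]:
            enclosing.pop()
        (children[enclosing[-1]] if enclosing else roots).append(p)
        enclosing.append(p)

    e = 0
    for i, j in roots:  # exterior-loop helix ends
        e += int(model.terminal[pt(i, j)])
    for (i, j), kids in children.items():
        t_ij = pt(i, j)
        if not kids:
            e += int(model.hairpin[j - i - 1]) + int(model.terminal[t_ij])
        elif len(kids) == 1:
            k, l = kids[0]
            d1, d2 = k - i - 1, j - l - 1
            if d1 == 0 and d2 == 0:
                e += int(model.stack[t_ij, pt(k, l)])
            else:
                table = model.bulge if min(d1, d2) == 0 else model.internal
                e += int(table[d1 + d2])
                e += int(model.terminal[t_ij]) + int(model.terminal[pt(k, l)])
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            e += model.ml_a + model.ml_b * (len(kids) + 1) + model.ml_c * unpaired
            e += int(model.terminal[t_ij])
            for k, l in kids:
                e += int(model.terminal[pt(k, l)])
    return e


def structure_energy(seq: str, pairs: tuple[tuple[int, int], ...], model: EnergyModel | None = None) -> float:
    """Free energy in kcal/mol of a nested structure given as 0-based pairs."""
    return structure_energy_deci(encode(seq), pairs, model) / 10.0
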