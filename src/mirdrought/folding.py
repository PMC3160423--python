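"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over the simplified nearest-neighbour model in
:mod:`mirdrought.energy` (no pseudoknots, hairpin loops >= 3 nt, multiloops
via the standard linear model). Ties in free energy are broken in favour of
structures with fewer pairs, then by a fixed traceback order, so results are
fully deterministic.

An exhaustive enumerator (`brute_force_fold`, sequences <= 18 nt) serves as an
independent search oracle: it scores every nested structure with the same
loop-decomposition evaluator and returns the global optimum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from mirdrought.energy import (
    MIN_HAIRPIN_LOOP,
    PAIR_TYPE,
    EnergyModel,
    default_model,
    encode,
    structure_energy_deci,
)

INF = np.int64(2**60)

#: default cap on bulge/internal loop size (sum of both sides)
MAX_INTERIOR = 30

# DP scores pack (deci-kcal energy, number of pairs) into one integer:
# score = energy * PACK + npairs, PACK > any possible pair count, so the
# minimum-score structure is the minimum-energy one with fewest pairs.
PACK = np.int64(1024)


@dataclasses.dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its free energy.

    ``pairs`` are 1-based (i, j) with i < j; ``mfe`` is in kcal/mol.
    """

    seq: str
    pairs: tuple[tuple[int, int], ...]
    dotbracket: str
    mfe: float

    @property
    def partner(self) -> dict[int, int]:
        """1-based partner map (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def _dotbracket(n: int, pairs0: tuple[tuple[int, int], ...]) -> str:
    chars = ["."] * n
    for i, j in pairs0:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


@njit(cache=True)
def _fill(codes, pair_type, stack, hairpin, bulge, internal, ml_a, ml_b, ml_c, terminal, maxloop):
    """Fill V (pair-closed), WM (multiloop segment) and W (external) tables.

    All energy parameters arrive pre-scaled by PACK; +1 is added per pair.
    """
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    W = np.zeros(n + 1, dtype=np.int64)

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            t_ij = pair_type[codes[i], codes[j]]
            if t_ij >= 0:
                # hairpin closure
                best = hairpin[span - 1] + terminal[t_ij] + 1
                # stack / bulge / internal closure
                for k in range(i + 1, min(i + maxloop + 2, j - MIN_HAIRPIN_LOOP - 1)):
                    d1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (maxloop - d1))
                    for l in range(j - 1, lmin - 1, -1):
                        if l <= k:
                            break
                        if V[k, l] >= INF:
                            continue
                        d2 = j - l - 1
                        t_kl = pair_type[codes[k], codes[l]]
                        if d1 == 0 and d2 == 0:
                            cand = V[k, l] + stack[t_ij, t_kl] + 1
                        else:
                            size = d1 + d2
                            pen = bulge[size] if (d1 == 0 or d2 == 0) else internal[size]
                            cand = V[k, l] + pen + terminal[t_ij] + terminal[t_kl] + 1
                        if cand < best:
                            best = cand
                # multiloop closure: >= 2 branches inside
                base = ml_a + ml_b + terminal[t_ij] + 1
                for m in range(i + 2, j - 2):
                    if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                        cand = base + WM[i + 1, m] + WM[m + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best

            # WM: segment holding >= 1 multiloop branch
            best = INF
            if t_ij >= 0 and V[i, j] < INF:
                best = V[i, j] + ml_b + terminal[t_ij]
            if WM[i + 1, j] < INF:
                cand = WM[i + 1, j] + ml_c
                if cand < best:
                    best = cand
            if WM[i, j - 1] < INF:
                cand = WM[i, j - 1] + ml_c
                if cand < best:
                    best = cand
            for m in range(i + 1, j):
                if WM[i, m - 1] < INF:
                    t_mj = pair_type[codes[m], codes[j]]
                    if t_mj >= 0 and V[m, j] < INF:
                        cand = WM[i, m - 1] + V[m, j] + ml_b + terminal[t_mj]
                        if cand < best:
                            best = cand
            WM[i, j] = best

    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - 1):
            t = pair_type[codes[i], codes[j - 1]]
            if t >= 0 and V[i, j - 1] < INF:
                cand = W[i] + V[i, j - 1] + terminal[t]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, W


def _scaled(model: EnergyModel):
    return (
        model.stack * PACK,
        model.hairpin * PACK,
        model.bulge * PACK,
        model.internal * PACK,
        np.int64(model.ml_a) * PACK,
        np.int64(model.ml_b) * PACK,
        np.int64(model.ml_c) * PACK,
        model.terminal * PACK,
    )


def _traceback(codes, V, WM, W, scaled, maxloop) -> list[tuple[int, int]]:
    stack_s, hairpin_s, bulge_s, internal_s, ml_a, ml_b, ml_c, term_s = scaled
    pairs: list[tuple[int, int]] = []
    tasks: list[tuple[str, int, int]] = [("W", 0, len(codes))]

    def pt(i, j):
        return PAIR_TYPE[codes[i], codes[j]]

    while tasks:
        kind, a, b = tasks.pop()
        if kind == "W":
            j = b
            while j > 0:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                for i in range(0, j - 1):
                    t = pt(i, j - 1)
                    if t >= 0 and V[i, j - 1] < INF and W[j] == W[i] + V[i, j - 1] + term_s[t]:
                        tasks.append(("V", i, j - 1))
                        j = i
                        break
                else:  # pragma: no cover - fill/traceback mismatch
                    raise AssertionError("external traceback failed")
        elif kind == "V":
            i, j = a, b
            pairs.append((i, j))
            t_ij = pt(i, j)
            target = V[i, j]
            if target == hairpin_s[j - i - 1] + term_s[t_ij] + 1:
                continue
            found = False
            for k in range(i + 1, min(i + maxloop + 2, j - MIN_HAIRPIN_LOOP - 1)):
                d1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (maxloop - d1))
                for l in range(j - 1, lmin - 1, -1):
                    if l <= k:
                        break
                    if V[k, l] >= INF:
                        continue
                    d2 = j - l - 1
                    t_kl = pt(k, l)
                    if d1 == 0 and d2 == 0:
                        cand = V[k, l] + stack_s[t_ij, t_kl] + 1
                    else:
                        size = d1 + d2
                        pen = bulge_s[size] if (d1 == 0 or d2 == 0) else internal_s[size]
                        cand = V[k, l] + pen + term_s[t_ij] + term_s[t_kl] + 1
                    if cand == target:
                        tasks.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            base = ml_a + ml_b + term_s[t_ij] + 1
            for m in range(i + 2, j - 2):
                if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                    if base + WM[i + 1, m] + WM[m + 1, j - 1] == target:
                        tasks.append(("M", i + 1, m))
                        tasks.append(("M", m + 1, j - 1))
                        found = True
                        break
            if not found:  # pragma: no cover
                raise AssertionError("pair traceback failed")
        else:  # WM segment
            i, j = a, b
            while True:
                target = WM[i, j]
                t_ij = pt(i, j)
                if t_ij >= 0 and V[i, j] < INF and target == V[i, j] + ml_b + term_s[t_ij]:
                    tasks.append(("V", i, j))
                    break
                if WM[i + 1, j] < INF and target == WM[i + 1, j] + ml_c:
                    i += 1
                    continue
                if WM[i, j - 1] < INF and target == WM[i, j - 1] + ml_c:
                    j -= 1
                    continue
                found = False
                for m in range(i + 1, j):
                    t_mj = pt(m, j)
                    if WM[i, m - 1] < INF and t_mj >= 0 and V[m, j] < INF:
                        if target == WM[i, m - 1] + V[m, j] + ml_b + term_s[t_mj]:
                            tasks.append(("M", i, m - 1))
                            tasks.append(("V", m, j))
                            found = True
                            break
                if not found:  # pragma: no cover
                    raise AssertionError("multiloop traceback failed")
                break
    return sorted(pairs)


def fold_mfe(seq: str, model: EnergyModel | None = None, maxloop: int = MAX_INTERIOR) -> SecondaryStructure:
    """Fold a sequence to its minimum-free-energy nested structure.

    Returns the empty structure (mfe = 0) when no negative-energy structure
    exists. Sequences must be 10-1000 nt over ACGU/ACGT.
    """
    model = model or default_model()
    if not 10 <= len(seq) <= model.max_len:
        raise ValueError(f"sequence length {len(seq)} outside 10..{model.max_len}")
    codes = encode(seq)
    scaled = _scaled(model)
    V, WM, W = _fill(
        codes, PAIR_TYPE, scaled[0], scaled[1], scaled[2], scaled[3],
        scaled[4], scaled[5], scaled[6], scaled[7], maxloop,
    )
    if W[len(codes)] >= 0:
        return SecondaryStructure(seq=seq, pairs=(), dotbracket="." * len(seq), mfe=0.0)
    pairs0 = tuple(_traceback(codes, V, WM, W, scaled, maxloop))
    mfe_deci = structure_energy_deci(codes, pairs0, model)
    pairs1 = tuple((i + 1, j + 1) for i, j in pairs0)
    return SecondaryStructure(seq=seq, pairs=pairs1, dotbracket=_dotbracket(len(codes), pairs0), mfe=mfe_deci / 10.0)


def enumerate_structures(codes: np.ndarray) -> list[tuple[tuple[int, int], ...]]:
    """All nested structures over canonical pairs with min-loop >= 3 (0-based)."""
    n = len(codes)
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i + 1 < MIN_HAIRPIN_LOOP + 2:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if PAIR_TYPE[codes[i], codes[k]] < 0:
                continue
            inner = rec(i + 1, k - 1)
            outer = rec(k + 1, j)
            for left in inner:
                for right in outer:
                    out.append(((i, k),) + left + right)
        memo[key] = out
        return out

    return rec(0, n - 1)


def brute_force_fold(seq: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Exhaustive-search fold for sequences <= 18 nt (test oracle).

    Scores every admissible nested structure with the loop-decomposition
    evaluator; ties broken by fewest pairs, then lexicographically smallest
    sorted pair list.
    """
    if len(seq) > 18:
        raise ValueError("brute-force folding is limited to sequences <= 18 nt")
    model = model or default_model()
    codes = encode(seq)
    best: tuple[int, int, tuple[tuple[int, int], ...]] | None = None
    for pairs in enumerate_structures(codes):
        key = (structure_energy_deci(codes, pairs, model), len(pairs), tuple(sorted(pairs)))
        if best is None or key < best:
            best = key
    assert best is not None
    energy, _, pairs0 = best
    if energy >= 0:
        energy, pairs0 = 0, ()
    pairs1 = tuple((i + 1, j + 1) for i, j in pairs0)
    return SecondaryStructure(seq=seq, pairs=pairs1, dotbracket=_dotbracket(len(codes), pairs0), mfe=energy / 10.0)


@dataclasses.dataclass(frozen=True)
class HairpinMetrics:
    is_single_hairpin: bool
    arm: str | None                  # "5p", "3p", or None when undefined
    mature_paired_fraction: float
    mature_unpaired_count: int
    loop_span: tuple[int, int] | None  # 1-based unpaired terminal loop interval


def hairpin_metrics(structure: SecondaryStructure, mature: tuple[int, int]) -> HairpinMetrics:
    """Assess a structure as a miRNA hairpin for a mature interval.

    ``mature`` is a 1-based inclusive interval on ``structure.seq``. The
    structure is a single hairpin iff its pairs form one stem-loop: every pair
    nests inside the previous one, leaving a single terminal loop. The arm is
    5p when the mature lies entirely 5' of the terminal loop and 3p when
    entirely 3' of it; a mature overlapping the loop has no arm.
    """
    s, e = mature
    if not (1 <= s <= e <= len(structure.seq)):
        raise ValueError("mature interval outside sequence")
    pairs = sorted(structure.pairs)
    single = len(pairs) > 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            single = False
            break
    loop = None
    if single:
        i_in, j_in = pairs[-1]  # innermost pair
        loop = (i_in + 1, j_in - 1)
    partner = structure.partner
    unpaired = sum(1 for p in range(s, e + 1) if p not in partner)
    frac = 1.0 - unpaired / (e - s + 1)
    arm = None
    if single:
        i_in, j_in = pairs[-1]
        if e <= i_in:
            arm = "5p"
        elif s >= j_in:
            arm = "3p"
    return HairpinMetrics(
        is_single_hairpin=single,
        arm=arm,
        mature_paired_fraction=frac,
        mature_unpaired_count=unpaired,
        loop_span=loop,
    )


def vienna_text(structure: SecondaryStructure) -> str:
    """Vienna-style text rendering: sequence, dot-bracket and energy."""
    from mirdrought.sequtil import to_rna

    return f"{to_rna(structure.seq).upper()}\n{structure.dotbracket} ({structure.mfe:.1f})"
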