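"""Differential expression between two sequencing libraries.

Counts are normalized to reads per million of clean reads (CPM), entries
with CPM below 1 in both libraries are removed, the effect size is
log2(DS/CK) of the normalized values, and significance comes from the
Audic-Claverie conditional Poisson test generalized to unequal library
depths. Given a count x in library 1 (depth N1), the count Y in library 2
(depth N2) follows

    P(Y = y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative binomial with x+1 successes and success probability N1/(N1+N2).
The two-sided p-value doubles the smaller of the two inclusive tails,
min(1, 2*min(P(Y <= y | x), P(Y >= y | x))), which keeps the test
conservative for discrete counts. The statistic treats the two libraries as
an unordered pair: the tails are evaluated in a canonical argument order, so
exchanging the libraries returns the bit-identical p-value.

Regulation calls follow a fold-change ratio threshold (default 1.5) combined
with p <= 0.05, with significance tiers "*" (0.01 < p <= 0.05) and "**"
(p <= 0.01). No multiple-testing correction is applied by default, matching
the per-miRNA reporting convention of single-library-pair DGE studies;
Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

#: pseudo-CPM applied to a zero side when displaying fold changes
ZERO_CPM_EPSILON = 0.01


def normalize_cpm(count: float, total_clean: int) -> float:
    """Counts per million clean reads: count / total * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / total_clean * 1_000_000


def filter_low(norm_ck: float, norm_ds: float, min_cpm: float = 1.0) -> bool:
    """True (keep) unless the normalized expression is below ``min_cpm`` in
    both libraries (strict '<'; a condition-specific miRNA with one high
    library is retained)."""
    return not (norm_ck < min_cpm and norm_ds < min_cpm)


def log2_fold(norm_ds: float, norm_ck: float) -> tuple[float, bool]:
    """log2(DS/CK); zero sides are regularized with a pseudo-CPM.

    Returns (log2fc, regularized) where ``regularized`` flags an
    infinite-fold entry whose zero side was replaced by ``ZERO_CPM_EPSILON``
    for display purposes.
    """
    if norm_ck < 0 or norm_ds < 0:
        raise ValueError("normalized expression must be >= 0")
    regularized = norm_ck == 0 or norm_ds == 0
    ck = norm_ck if norm_ck > 0 else ZERO_CPM_EPSILON
    ds = norm_ds if norm_ds > 0 else ZERO_CPM_EPSILON
    return math.log2(ds / ck), regularized


def _ac_two_sided(x: int, y: int, n1: int, n2: int) -> float:
    p0 = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p0)                       # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, p0) if y > 0 else 1.0  # P(Y >= y | x)
    return min(1.0, 2.0 * min(float(lower), float(upper)))


def poisson_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts (x, y) at depths (N1, N2).

    Exactly exchange-symmetric: poisson_p(x, y, N1, N2) ==
    poisson_p(y, x, N2, N1), to the bit, via canonical argument ordering.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    if x == y and n1 == n2:
        return 1.0  # both tails are exactly 1/2 by symmetry
    if (x, n1) <= (y, n2):
        return _ac_two_sided(int(x), int(y), int(n1), int(n2))
    return _ac_two_sided(int(y), int(x), int(n2), int(n1))


def poisson_p_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Exact-rational summation of the conditional mass function (test oracle).

    Sums P(Y = y' | x) with ``fractions.Fraction`` over the relevant tail, so
    the value is exact up to the final float conversion.
    """
    from fractions import Fraction

    def lower_tail(x: int, y: int, n1: int, n2: int) -> Fraction:
        r = Fraction(n2, n1)
        acc = Fraction(0)
        term = Fraction(1) / (1 + r) ** (x + 1)  # y' = 0
        acc += term
        for yp in range(1, y + 1):
            term = term * r * (x + yp) / (yp * (1 + r))
            acc += term
        return acc

    if x == y and n1 == n2:
        return 1.0
    if (x, n1) > (y, n2):
        x, y, n1, n2 = y, x, n2, n1
    low = lower_tail(x, y, n1, n2)
    up = 1 - lower_tail(x, y - 1, n1, n2) if y > 0 else Fraction(1)
    return float(min(Fraction(1), 2 * min(low, up)))


def classify_de(
    table: pd.DataFrame,
    n1: int,
    n2: int,
    min_cpm: float = 1.0,
    fold_ratio_threshold: float = 1.5,
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full differential-expression analysis of a count table.

    ``table`` needs columns id, count_ck, count_ds; ``n1``/``n2`` are the
    total clean reads of the CK and DS libraries. Returns a DataFrame with
    normalized expression, log2 fold change, p-value, regulation class
    (up/down/ns) and significance tier ('', '*', '**'), restricted to
    entries passing the low-expression filter.
    """
    df = table.copy()
    df["norm_ck"] = [normalize_cpm(c, n1) for c in df["count_ck"]]
    df["norm_ds"] = [normalize_cpm(c, n2) for c in df["count_ds"]]
    keep = [filter_low(a, b, min_cpm) for a, b in zip(df["norm_ck"], df["norm_ds"])]
    df = df.loc[keep].reset_index(drop=True)
    fc = [log2_fold(ds, ck) for ck, ds in zip(df["norm_ck"], df["norm_ds"])]
    df["log2fc"] = [v for v, _ in fc]
    df["regularized"] = [r for _, r in fc]
    df["p"] = [
        poisson_p(int(x), int(y), n1, n2) for x, y in zip(df["count_ck"], df["count_ds"])
    ]
    pcol = df["p"]
    if bh_correct and len(df):
        pcol = pd.Series(stats.false_discovery_control(df["p"].to_numpy()), index=df.index)
    df["p_adj"] = pcol
    up = (df["norm_ds"] > df["norm_ck"] * fold_ratio_threshold) & (pcol <= alpha)
    down = (df["norm_ck"] > df["norm_ds"] * fold_ratio_threshold) & (pcol <= alpha)
    df["regulation"] = np.where(up, "up", np.where(down, "down", "ns"))
    tier = np.where(pcol <= alpha_strong, "**", np.where(pcol <= alpha, "*", ""))
    df["tier"] = np.where(df["regulation"] == "ns", "", tier)
    return df


def write_de(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def de_scatter(df: pd.DataFrame, path) -> None:
    """Log-log scatter of normalized CK vs DS expression, colored by call."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"up": "tab:red", "down": "tab:blue", "ns": "0.6"}
    for cls, sub in df.groupby("regulation"):
        ax.scatter(
            sub["norm_ck"].clip(lower=ZERO_CPM_EPSILON),
            sub["norm_ds"].clip(lower=ZERO_CPM_EPSILON),
            s=12, label=f"{cls} (n={len(sub)})", color=colors.get(cls, "k"), alpha=0.7,
        )
    lim = max(df["norm_ck"].max(), df["norm_ds"].max(), 1.0) * 2
    ax.plot([ZERO_CPM_EPSILON, lim], [ZERO_CPM_EPSILON, lim], "k-", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("normalized expression, CK (CPM)")
    ax.set_ylabel("normalized expression, DS (CPM)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
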