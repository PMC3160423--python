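import math

import numpy as np
import pandas as pd
import pytest

from mirdrought.diffexpr import (
    classify_de,
    filter_low,
    log2_fold,
    normalize_cpm,
    poisson_p,
    poisson_p_oracle,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (0, 1_000_000, 0.0),
            (100, 2_000_000, 50.0),
            (6_420_234, 6_420_234, 1_000_000.0),  # whole-library identity
        ],
    )
    def test_examples(self, count, total, expected):
        assert normalize_cpm(count, total) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_cpm(10, 0)

    def test_conservation_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5_000, size=500)
        total = int(counts.sum())
        assert sum(normalize_cpm(int(c), total) for c in counts) == pytest.approx(
            1_000_000.0, rel=1e-9
        )


class TestFilterLow:
    def test_both_below_dropped(self):
        assert not filter_low(0.5, 0.5)

    def test_one_side_high_kept(self):
        assert filter_low(0.5, 10.0)

    def test_boundary_is_strict(self):
        assert filter_low(1.0, 1.0)


class TestLog2Fold:
    @pytest.mark.parametrize("ds,ck,expected", [(100, 25, 2.0), (50, 50, 0.0)])
    def test_examples(self, ds, ck, expected):
        fc, reg = log2_fold(ds, ck)
        assert fc == pytest.approx(expected) and not reg

    def test_zero_side_regularized(self):
        fc, reg = log2_fold(0.0, 10.0)
        assert reg and fc == pytest.approx(math.log2(0.01 / 10.0))

    def test_threshold_ratio_mapping(self):
        fc, _ = log2_fold(15.0, 10.0)
        assert abs(fc) > math.log2(1.5) - 1e-12
        assert fc == pytest.approx(0.5849625007, abs=1e-9)


class TestPoissonP:
    def test_equal_counts_equal_depths_is_one(self):
        for x in (0, 1, 5, 50, 1000):
            assert poisson_p(x, x, 10**6, 10**6) == 1.0

    def test_exchange_symmetry_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x, y = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            n1, n2 = int(rng.integers(10**3, 10**7)), int(rng.integers(10**3, 10**7))
            assert poisson_p(x, y, n1, n2) == poisson_p(y, x, n2, n1)  # bit-exact

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x, y = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            n1, n2 = int(rng.integers(10**4, 10**7)), int(rng.integers(10**4, 10**7))
            p = poisson_p(x, y, n1, n2)
            p_exact = poisson_p_oracle(x, y, n1, n2)
            assert p == pytest.approx(p_exact, rel=1e-10, abs=1e-300)

    def test_documented_example_against_oracle(self):
        p = poisson_p(5, 50, 10**6, 10**6)
        assert p == pytest.approx(poisson_p_oracle(5, 50, 10**6, 10**6), rel=1e-10)
        assert p < 1e-8  # a 10-fold change at these counts is overwhelming

    def test_upper_tail_monotone_in_y(self):
        from scipy.stats import nbinom

        x, n1, n2 = 20, 10**6, 2 * 10**6
        p0 = n1 / (n1 + n2)
        tails = [nbinom.sf(y - 1, x + 1, p0) for y in range(0, 200)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_p(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            poisson_p(0, 0, 0, 10)

    def test_null_calibration_quick(self):
        """Fraction of p <= 0.05 under a Poisson null is near-nominal but not
        anticonservative (full-size calibration lives in the acceptance
        suite)."""
        rng = np.random.default_rng(3)
        lam = rng.uniform(50, 500, size=300)
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        n = 10**6
        frac = np.mean([poisson_p(int(a), int(b), n, n) <= 0.05 for a, b in zip(x, y)])
        assert 0.01 <= frac <= 0.08


class TestClassify:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["id", "count_ck", "count_ds"])

    def test_rule_application(self):
        # 10 vs 40 at depth 1e6: ratio 4 > 1.5 and p well below 0.01
        df = classify_de(self._table([("a", 100, 400)]), 10**6, 10**6)
        row = df.iloc[0]
        assert row["regulation"] == "up" and row["tier"] == "**"

    def test_small_ratio_is_ns(self):
        df = classify_de(self._table([("a", 10_000, 12_000)]), 10**6, 10**6)
        assert df.iloc[0]["regulation"] == "ns"  # ratio 1.2 below threshold

    def test_star_tier_window(self):
        # engineer a p in (0.01, 0.05]: ratio must still exceed 1.5
        n = 10**6
        x, y = 18, 34
        p = poisson_p(x, y, n, n)
        assert 0.01 < p <= 0.05
        df = classify_de(self._table([("a", x, y)]), n, n, min_cpm=10 / n * 1e6)
        assert df.iloc[0]["tier"] == "*"
        assert df.iloc[0]["regulation"] == "up"

    def test_low_expression_removed(self):
        df = classify_de(self._table([("lo", 0, 0), ("hi", 50, 60)]), 10**6, 10**6)
        assert list(df["id"]) == ["hi"]

    def test_label_swap_antisymmetry(self):
        rows = [("a", 100, 400), ("b", 900, 100), ("c", 300, 290), ("d", 0, 80)]
        n1, n2 = 2 * 10**6, 10**6
        fwd = classify_de(self._table(rows), n1, n2).set_index("id")
        swapped = classify_de(
            self._table([(i, ds, ck) for i, ck, ds in rows]), n2, n1
        ).set_index("id")
        flip = {"up": "down", "down": "up", "ns": "ns"}
        for i in fwd.index:
            assert swapped.loc[i, "regulation"] == flip[fwd.loc[i, "regulation"]]
            assert swapped.loc[i, "log2fc"] == pytest.approx(-fwd.loc[i, "log2fc"])
            assert swapped.loc[i, "p"] == fwd.loc[i, "p"]  # exchange symmetry

    def test_bh_option(self):
        rows = [(f"g{i}", 100, 100 + 10 * i) for i in range(10)]
        plain = classify_de(self._table(rows), 10**6, 10**6)
        bh = classify_de(self._table(rows), 10**6, 10**6, bh_correct=True)
        assert (bh["p_adj"] >= plain["p"] - 1e-15).all()
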