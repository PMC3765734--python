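"""Normalization, the exact tag-count test, DE calls, and S/D patterns."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgetag.expression import (
    ac_test,
    call_de,
    classify_pattern,
    classify_patterns,
    normalize,
)


def exact_two_sided(x: int, n1: int, y: int, n2: int) -> float:
    """Oracle: exact-rational tail sums of Binomial(x+y, N2/(N1+N2))."""
    n = x + y
    if n == 0:
        return 1.0
    q = Fraction(n2, n1 + n2)
    pmf = [comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(n + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    return float(min(1, 2 * min(lower, upper)))


class TestNormalize:
    def test_single_gene_takes_the_million(self):
        counts = pd.DataFrame({"lib": [50]}, index=["g"])
        tpm, _ = normalize(counts)
        assert tpm.loc["g", "lib"] == pytest.approx(1e6)

    def test_direct_formulas(self):
        counts = pd.DataFrame({"lib": [10]}, index=["g"])
        tpm, rpkm = normalize(counts, {"lib": 1e6}, {"g": 2000})
        assert tpm.loc["g", "lib"] == pytest.approx(10)
        assert rpkm.loc["g", "lib"] == pytest.approx(5)

    def test_tpm_sums_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 3)),
                              columns=["a", "b", "c"])
        tpm, _ = normalize(counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_missing_length_names_genes(self):
        counts = pd.DataFrame({"lib": [1, 2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            normalize(counts, {"lib": 100}, {"g1": 500})


class TestAcTest:
    def test_equal_counts_equal_depths_is_one(self):
        assert ac_test(5, 1e6, 5, 1e6) == 1.0

    def test_extreme_split_tiny_p(self):
        p = ac_test(0, 1e6, 100, 1e6)
        assert p == pytest.approx(2 * 0.5**100, rel=1e-9)
        assert p < 1e-20

    def test_modest_split_not_significant(self):
        assert ac_test(2, 1e6, 4, 1e6) > 0.05

    def test_zero_zero(self):
        assert ac_test(0, 1e6, 0, 2e6) == 1.0

    @given(
        st.integers(0, 80), st.integers(0, 80),
        st.integers(1, 10**6), st.integers(1, 10**6),
    )
    def test_symmetry(self, x, y, n1, n2):
        assert ac_test(x, n1, y, n2) == pytest.approx(
            ac_test(y, n2, x, n1), rel=1e-12)

    @given(
        st.integers(0, 120), st.integers(0, 80),
        st.integers(10, 10**6), st.integers(10, 10**6),
    )
    def test_agrees_with_exact_rational_oracle(self, x, y, n1, n2):
        assert x + y <= 200
        assert ac_test(x, n1, y, n2) == pytest.approx(
            exact_two_sided(x, n1, y, n2), rel=1e-9)

    def test_null_rejection_conservative(self, rng):
        lam = 30
        x = rng.poisson(lam, size=10_000)
        y = rng.poisson(lam, size=10_000)
        p = ac_test(x, 1e5, y, 1e5)
        rate = float((p <= 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert rate <= 0.05 + 2 * se

    def test_vectorized_matches_scalar(self):
        xs, ys = [0, 3, 10], [7, 3, 2]
        vec = ac_test(xs, 1e4, ys, 2e4)
        for x, y, v in zip(xs, ys, vec):
            assert v == ac_test(x, 1e4, y, 2e4)


class TestCallDe:
    def test_identical_libraries_unchanged(self):
        counts = pd.DataFrame({"a": [10, 0, 55], "b": [10, 0, 55]},
                              index=["g1", "g2", "g3"])
        de = call_de(counts, ("a", "b"), {"a": 1e4, "b": 1e4})
        assert (de["direction"] == "unchanged").all()
        assert (de["p_value"] == 1.0).all()

    def test_single_gene_extreme_called_up(self):
        counts = pd.DataFrame({"a": [0], "b": [100]}, index=["g"])
        de = call_de(counts, ("a", "b"), {"a": 1e6, "b": 1e6})
        assert de.loc["g", "direction"] == "up"

    def test_fdr_monotone_in_p_rank(self, rng):
        counts = pd.DataFrame(
            {"a": rng.poisson(20, 100), "b": rng.poisson(25, 100)})
        de = call_de(counts, ("a", "b"), {"a": 1e4, "b": 1e4})
        ranked = de.sort_values("p_value")
        assert (ranked["fdr"].diff().dropna() >= -1e-12).all()

    def test_direction_requires_both_thresholds(self):
        # significant p but modest fold change stays unchanged
        counts = pd.DataFrame({"a": [1000], "b": [1300]}, index=["g"])
        de = call_de(counts, ("a", "b"), {"a": 1e5, "b": 1e5})
        assert de.loc["g", "p_value"] < 0.05
        assert abs(de.loc["g", "log2_fold_change"]) < 1
        assert de.loc["g", "direction"] == "unchanged"


class TestPatterns:
    DEPTHS = {"embryo": (6e6, 6e6), "larva": (6e6, 6e6),
              "pupa": (6e6, 6e6), "adult": (6e6, 6e6)}

    def test_all_zero_gene_is_similar(self):
        call = classify_pattern(
            "g", {s: (0, 0) for s in self.DEPTHS}, self.DEPTHS)
        assert call.pattern == "S"
        assert set(call.stage_directions.values()) == {"unchanged"}

    def test_single_stage_difference_is_different(self):
        counts = {s: (50, 48) for s in self.DEPTHS}
        counts["larva"] = (200, 0)
        call = classify_pattern("g", counts, self.DEPTHS)
        assert call.pattern == "D"
        assert call.stage_directions["larva"] == "down"

    def test_matrix_and_single_gene_agree(self, rng):
        stages = tuple(self.DEPTHS)
        genes = [f"g{i}" for i in range(20)]
        cols = {(sp, s): rng.poisson(30, len(genes))
                for sp in ("A", "B") for s in stages}
        depths = {k: 1e5 for k in cols}
        matrix = pd.DataFrame(cols, index=genes)
        table = classify_patterns(matrix, depths, ("A", "B"), stages)
        # BH across genes can only raise a gene's q-value above its raw p,
        # so a matrix-level D call implies the single-gene call is D too
        for g in genes:
            single = classify_pattern(
                g,
                {s: (matrix.loc[g, ("A", s)], matrix.loc[g, ("B", s)]) for s in stages},
                {s: (1e5, 1e5) for s in stages},
            )
            if table.loc[g, "pattern"] == "D":
                assert single.pattern == "D"
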