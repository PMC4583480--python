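"""TPM, the exact two-library test (vs. a direct-summation oracle),
BH correction, DE calling and hypergeometric enrichment."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from trichomir.diffexpr import (
    DEConfig,
    audic_claverie_test,
    bh_adjust,
    call_de,
    enrich_terms,
    fisher_test,
    log2_ratio,
    tpm,
    two_library_test,
)


def ac_oracle(x: int, n1: int, y: int, n2: int) -> float:
    """Direct log-gamma summation of the symmetrized two-sided AC p-value.

    Independent numerics: explicit pmf sums, no scipy distribution objects.
    """

    def pmf_vec(r: int, p: float, kmax: int) -> np.ndarray:
        k = np.arange(kmax + 1)
        logp = (
            gammaln(r + k)
            - gammaln(k + 1)
            - gammaln(r)
            + r * math.log(p)
            + k * math.log1p(-p)
        )
        return np.exp(logp)

    p1 = n1 / (n1 + n2)
    p2 = n2 / (n1 + n2)
    kmax = 20 * (x + y + 10)
    f1 = pmf_vec(x + 1, p1, kmax)  # distribution of Y given x
    f2 = pmf_vec(y + 1, p2, kmax)  # distribution of X given y
    up = 0.5 * (f1[y:].sum() + f2[: x + 1].sum())
    down = 0.5 * (f1[: y + 1].sum() + f2[x:].sum())
    return min(1.0, 2.0 * min(up, down))


class TestTPM:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(12, 12_000_000, 1.0), (0, 1_000_000, 0.0), (50, 10_000_000, 5.0)],
    )
    def test_values(self, count, total, expected):
        assert tpm(count, total) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(5, 0)


class TestAudicClaverie:
    def test_equal_counts_not_significant(self):
        assert audic_claverie_test(10, 10**6, 10, 10**6) > 0.9

    def test_strong_difference_highly_significant(self):
        assert audic_claverie_test(0, 10**6, 50, 10**6) < 1e-10

    def test_matches_direct_summation_oracle(self):
        """Implementation equals the independent pmf-summation oracle to 1e-10
        relative tolerance across count pairs up to 200."""
        rng = np.random.default_rng(7)
        pairs = [(0, 0), (0, 1), (1, 0), (200, 200), (0, 200), (113, 87)]
        pairs += [(int(a), int(b)) for a, b in rng.integers(0, 201, (40, 2))]
        for x, y in pairs:
            for n1, n2 in ((10**6, 10**6), (12_152_212, 8_988_274), (50_000, 120_000)):
                expected = ac_oracle(x, n1, y, n2)
                got = audic_claverie_test(x, n1, y, n2)
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        n1=st.integers(10**4, 10**7),
        n2=st.integers(10**4, 10**7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exchange_symmetry(self, x, y, n1, n2):
        assert audic_claverie_test(x, n1, y, n2) == audic_claverie_test(y, n2, x, n1)

    def test_lowering_high_count_never_raises_significance(self):
        """Shrinking the elevated count toward parity makes p monotonically larger."""
        prev = 0.0
        for y in (400, 200, 100, 50, 25):
            p = audic_claverie_test(25, 10**6, y, 10**6)
            assert p >= prev
            prev = p

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            audic_claverie_test(-1, 10, 0, 10)
        with pytest.raises(ValueError):
            audic_claverie_test(1, 0, 0, 10)

    def test_fisher_alternative_available(self):
        p = two_library_test(5, 1000, 50, 1000, method="fisher")
        assert p == pytest.approx(fisher_test(5, 1000, 50, 1000))
        with pytest.raises(ValueError):
            two_library_test(1, 10, 1, 10, method="bogus")


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_four_value_vector(self):
        # min over the tail of p * m / rank: all collapse to 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_at_least_p_and_rank_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallDE:
    def test_equal_tpm_is_ns(self):
        df = call_de({"a": (10, 10)}, (10**6, 10**6))
        assert df.loc[0, "log2_ratio"] == 0.0 and df.loc[0, "call"] == "ns"

    def test_zero_tpm_floor_fold(self):
        assert log2_ratio(8.0, 0.0, floor=0.01) == pytest.approx(math.log2(8 / 0.01))
        assert log2_ratio(8.0, 0.0, floor=0.01) == pytest.approx(9.6439, abs=1e-3)

    def test_calls_respect_all_three_thresholds(self):
        counts = {
            "up": (10, 500),
            "down": (500, 10),
            "big_fold_low_counts": (0, 2),  # fold passes, significance cannot
            "significant_small_fold": (10_000, 11_500),
        }
        df = call_de(counts, (10**6, 10**6)).set_index("id")
        assert df.loc["up", "call"] == "up"
        assert df.loc["down", "call"] == "down"
        assert df.loc["big_fold_low_counts", "call"] == "ns"
        assert df.loc["significant_small_fold", "call"] == "ns"
        up = df[df["call"] == "up"]
        assert ((up["p_value"] < 0.05) & (up["q_value"] < 0.05) & (up["log2_ratio"] > 1)).all()

    def test_relabeling_invariance(self):
        counts = {"a": (5, 300), "b": (300, 5), "c": (50, 60)}
        df1 = call_de(counts, (10**5, 10**5)).set_index("id")
        df2 = call_de({f"x_{k}": v for k, v in counts.items()}, (10**5, 10**5)).set_index("id")
        for k in counts:
            assert df1.loc[k, "call"] == df2.loc[f"x_{k}", "call"]
            assert df1.loc[k, "p_value"] == df2.loc[f"x_{k}", "p_value"]


class TestEnrichment:
    def test_matches_pmf_summation(self):
        universe = [f"g{i}" for i in range(100)]
        annotation = {g: {"T"} if i < 10 else {"other"} for i, g in enumerate(universe)}
        selected = universe[:5] + universe[50:55]  # 5 of 10 term members
        df = enrich_terms(selected, annotation, universe).set_index("term")
        expected = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10) for k in range(5, 11)
        )
        assert df.loc["T", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_term_covering_universe_is_null(self):
        universe = ["a", "b", "c"]
        df = enrich_terms(["a"], {g: {"T"} for g in universe}, universe).set_index("term")
        assert df.loc["T", "p_value"] == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms([], {"a": {"T"}}, ["a"])

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms(["zz"], {"a": {"T"}}, ["a"])

    def test_enriched_flag_follows_corrected_p(self):
        universe = [f"g{i}" for i in range(50)]
        annotation = {g: ({"hot"} if i < 8 else {"cold"}) for i, g in enumerate(universe)}
        df = enrich_terms(universe[:8], annotation, universe).set_index("term")
        assert bool(df.loc["hot", "enriched"]) is True
        assert df.loc["hot", "q_value"] <= 0.05
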