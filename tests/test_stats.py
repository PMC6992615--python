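"""Exact rank tests against brute-force enumeration and printed summaries."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from oculogas.stats import (
    mann_whitney_u,
    prone_supine_comparison,
    round_half_up,
    summarize,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(diffs):
    """Independent oracle: enumerate every sign assignment from scratch."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def brute_force_mwu_p(a, b):
    """Independent oracle: enumerate labelings, computing U by pair counts."""
    a, b = list(a), list(b)
    pooled = a + b
    na, n = len(a), len(a) + len(b)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxon:
    def test_all_improving_distinct_n8(self):
        pre = np.arange(1.0, 9.0)
        post = pre - np.linspace(0.1, 0.9, 8)  # all improve by distinct amounts
        res = wilcoxon_signed_rank(post, pre)  # differences all negative
        assert res.statistic == 0.0
        assert res.p_exact == pytest.approx(2.0 / 256.0)

    def test_antisymmetric_differences_centered(self):
        res = wilcoxon_signed_rank([0.5, -0.5, 1.2, -1.2])
        assert res.p_exact == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 11)
            d = np.round(rng.normal(0.2, 1.0, n), 1)  # rounding creates ties
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_exact == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, 12)
        ours = wilcoxon_signed_rank(d)
        theirs = scipy.stats.wilcoxon(d, mode="exact")
        assert ours.p_exact == pytest.approx(theirs.pvalue, abs=1e-9)

    def test_pratt_zero_rule_changes_ranks(self):
        d = [0.0, 0.5, -1.0, 2.0]
        drop = wilcoxon_signed_rank(d, zero_rule="wilcoxon")
        pratt = wilcoxon_signed_rank(d, zero_rule="pratt")
        assert drop.n == pratt.n == 3
        assert pratt.statistic > drop.statistic  # zeros push nonzero ranks up


class TestMannWhitney:
    def test_disjoint_groups_8v8(self):
        a = np.arange(8.0)
        b = np.arange(10.0, 18.0)
        res = mann_whitney_u(a, b)
        assert res.statistic == 0.0
        assert res.p_exact == pytest.approx(2.0 / 12870.0)

    def test_identical_groups(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_exact == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1.0], [1.0, 2.0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            na, nb = rng.integers(2, 6, size=2)
            a = np.round(rng.normal(0, 1, na), 1)
            b = np.round(rng.normal(0.5, 1, nb), 1)
            res = mann_whitney_u(a, b)
            assert res.p_exact == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 7)
        b = rng.normal(1, 1, 6)
        ours = mann_whitney_u(a, b)
        theirs = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_exact == pytest.approx(theirs.pvalue, abs=1e-9)

    @given(
        st.lists(st.integers(-20, 20), min_size=3, max_size=6),
        st.lists(st.integers(-20, 20), min_size=3, max_size=6),
        st.integers(1, 30),
    )
    @settings(max_examples=60, deadline=None)
    def test_shift_monotonicity(self, a, b, shift):
        """Shifting one group upward never makes it look more similar on the
        side it moves away from: the one-sided tail toward b-larger grows."""
        base = mann_whitney_u(a, b)
        shifted = mann_whitney_u(a, [x + shift for x in b])
        # U(a over b) can only fall (or stay) when b grows
        assert shifted.statistic <= base.statistic + 1e-9


class TestPrintedSummaries:
    def test_gas_volume_and_angle_summary(self, printed_tables):
        t3 = printed_tables["gas_angle"]
        s = summarize(
            t3,
            {
                "gas_volume_pct_prone": 1,
                "gas_volume_pct_supine": 1,
                "angle_deg_prone": 1,
                "angle_deg_supine": 1,
            },
        )
        assert s.loc["gas_volume_pct_prone", ["mean", "se"]].tolist() == [60.1, 4.0]
        assert s.loc["gas_volume_pct_supine", ["mean", "se"]].tolist() == [60.0, 4.0]
        assert s.loc["angle_deg_prone", ["mean", "se"]].tolist() == [16.1, 2.8]
        assert s.loc["angle_deg_supine", ["mean", "se"]].tolist() == [1.8, 3.5]

    def test_patient_characteristics_summary(self, printed_tables):
        s = summarize(
            printed_tables["patients"],
            {"age_years": 1, "axial_length_mm": 1, "quadrants": 1, "n_breaks": 1},
        )
        assert s.loc["age_years", ["mean", "se"]].tolist() == [59.8, 1.8]
        assert s.loc["axial_length_mm", ["mean", "se"]].tolist() == [25.4, 0.4]
        assert s.loc["quadrants", ["mean", "se"]].tolist() == [1.9, 0.4]
        assert s.loc["n_breaks", ["mean", "se"]].tolist() == [2.8, 0.8]

    def test_bcva_summary(self, printed_tables):
        s = summarize(
            printed_tables["outcomes"], {"bcva_preop_logmar": 2, "bcva_postop_logmar": 2}
        )
        assert s.loc["bcva_preop_logmar", ["mean", "se"]].tolist() == [0.82, 0.27]
        assert s.loc["bcva_postop_logmar", ["mean", "se"]].tolist() == [0.11, 0.07]

    def test_constant_column_zero_se(self):
        import pandas as pd

        s = summarize(pd.DataFrame({"x": [4.0, 4.0, 4.0]}), {"x": 1})
        assert s.loc["x", "se"] == 0.0

    def test_non_numeric_cell_named(self):
        import pandas as pd

        with pytest.raises(ValueError, match="x"):
            summarize(pd.DataFrame({"x": [1.0, "oops", 3.0]}), {"x": 1})

    def test_half_up_rounding(self):
        assert round_half_up(1.75, 1) == 1.8
        assert round_half_up(0.25, 1) == 0.3


class TestStudyComparisons:
    def test_gas_volume_prone_vs_supine_p_one(self, printed_tables):
        t3 = printed_tables["gas_angle"]
        comp = prone_supine_comparison(
            t3["gas_volume_pct_prone"], t3["gas_volume_pct_supine"]
        )
        assert comp["mann_whitney"].exact
        assert comp["mann_whitney"].p_value == pytest.approx(1.0)

    def test_bcva_exact_p_from_enumeration(self, printed_tables):
        t2 = printed_tables["outcomes"]
        res = wilcoxon_signed_rank(
            t2["bcva_preop_logmar"].to_numpy(), t2["bcva_postop_logmar"].to_numpy()
        )
        d = (t2["bcva_preop_logmar"] - t2["bcva_postop_logmar"]).to_numpy()
        assert res.p_exact == pytest.approx(brute_force_wilcoxon_p(d))
        assert res.p_exact == pytest.approx(6.0 / 256.0)
        # Both variants are significant at the study's 0.05 level.
        assert res.p_exact < 0.05 and res.p_approx < 0.05
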