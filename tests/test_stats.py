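"""Statistics battery vs independent oracles (scipy, pingouin,
test-side enumeration)."""

from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from condylometry.stats import (
    compare_software_volumes,
    icc,
    kruskal_wallis,
    mann_whitney_u,
    normality_gate,
    wilcoxon_signed_rank,
)


class TestNormalityGate:
    def test_normal_data_parametric(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 200) for _ in range(3)]
            decision, _ = normality_gate(groups)
            hits += decision == "parametric"
        assert hits >= 0.85 * 60  # >= alpha-level false-trigger allowance

    def test_exponential_data_nonparametric(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = [rng.exponential(1.0, 200) for _ in range(3)]
            decision, _ = normality_gate(groups)
            assert decision == "nonparametric"

    def test_unequal_variance_triggers_levene(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            groups = [rng.normal(0, 1, 100), rng.normal(0, 3, 100)]
            decision, results = normality_gate(groups)
            hits += decision == "nonparametric"
        assert hits >= 19

    def test_constant_sample_noted(self):
        decision, results = normality_gate(
            [np.ones(10), np.random.default_rng(0).normal(size=10)]
        )
        assert decision == "nonparametric"
        assert any("constant" in r.note for r in results)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([np.array([1.0, 2.0])])


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis(
            [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        )
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.n == (3, 3, 3)

    def test_identical_groups_zero(self):
        res = kruskal_wallis([np.ones(4), np.ones(4), np.ones(4)])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            k = rng.integers(2, 5)
            groups = [
                rng.normal(0, 1, rng.integers(3, 12)) for _ in range(k)
            ]
            if rng.random() < 0.5:  # inject ties
                groups = [np.round(g, 1) for g in groups]
            mine = kruskal_wallis(groups)
            ref_h, ref_p = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref_h, abs=1e-10)
            assert mine.p_value == pytest.approx(ref_p, abs=1e-10)


def enumerate_mwu_p(a, b):
    """Test-side enumeration over all rank splits of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    offset = n1 * (n1 + 1) / 2
    u_obs1 = ranks[:n1].sum() - offset
    u_obs2 = n1 * len(b) - u_obs1
    lo, hi = min(u_obs1, u_obs2), max(u_obs1, u_obs2)
    count = total = 0
    for pick in combinations(range(len(pooled)), n1):
        u = ranks[list(pick)].sum() - offset
        count += u <= lo + 1e-12 or u >= hi - 1e-12
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_equal_multisets_central_u(self):
        a = np.array([1.0, 2, 3, 4])
        res = mann_whitney_u(a, a.copy())
        assert res.statistic == len(a) ** 2 / 2

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n1, n2 = rng.integers(2, 5, size=2)
            a = rng.integers(0, 6, n1).astype(float)  # heavy ties
            b = rng.integers(0, 6, n2).astype(float)
            mine = mann_whitney_u(a, b)
            assert mine.p_value == pytest.approx(
                enumerate_mwu_p(a, b), abs=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        mine = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_sample_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        mine = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def enumerate_wilcoxon_p(first, second):
    d = np.asarray(second, float) - np.asarray(first, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    n = len(d)
    count = 0
    for mask in range(1 << n):
        wp = sum(ranks[i] for i in range(n) if mask >> i & 1)
        count += wp <= lo + 1e-12 or wp >= hi - 1e-12
    return count / (1 << n)


class TestWilcoxon:
    def test_constant_positive_shift(self):
        first = np.arange(8.0)
        res = wilcoxon_signed_rank(first, first + 3.0)
        assert res.direction == 1
        assert res.statistic == 0.0

    def test_identical_pairs_degenerate(self):
        x = np.arange(6.0)
        res = wilcoxon_signed_rank(x, x.copy())
        assert res.p_value == 1.0
        assert "zero" in res.note

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = rng.integers(4, 10)
            first = rng.integers(0, 8, n).astype(float)
            second = rng.integers(0, 8, n).astype(float)
            if np.all(first == second):
                continue
            mine = wilcoxon_signed_rank(first, second)
            assert mine.p_value == pytest.approx(
                enumerate_wilcoxon_p(first, second), abs=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(200 + seed)
        first = rng.normal(size=9)
        second = first + rng.normal(size=9)
        mine = wilcoxon_signed_rank(first, second)
        ref = sps.wilcoxon(second, first, mode="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def make_table(data: np.ndarray) -> pd.DataFrame:
    n, k = data.shape
    rows = []
    for i in range(n):
        for r in range(k):
            rows.append(
                {"condyle": i, "rater": r + 1, "occasion": 1,
                 "value": data[i, r]}
            )
    return pd.DataFrame(rows)


def make_intra_table(data: np.ndarray) -> pd.DataFrame:
    n, k = data.shape
    rows = []
    for i in range(n):
        for o in range(k):
            rows.append(
                {"condyle": i, "rater": 1, "occasion": o + 1,
                 "value": data[i, o]}
            )
    return pd.DataFrame(rows)


class TestICC:
    def test_identical_readings_unity(self):
        data = np.tile(np.array([[100.0], [200.0], [300.0], [400.0]]), (1, 2))
        assert icc(make_table(data), "inter").value == pytest.approx(1.0)
        assert icc(make_intra_table(data), "intra").value == pytest.approx(1.0)

    def test_fixed_bias_separates_forms(self):
        base = np.array([1500.0, 1600, 1700, 1550, 1650, 1750])
        data = np.column_stack([base, base + 50.0])
        assert icc(make_intra_table(data), "intra").value == pytest.approx(1.0)
        assert icc(make_table(data), "inter").value < 1.0

    def test_consistency_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        data = rng.normal(1600, 100, size=(8, 2))
        a = icc(make_intra_table(data), "intra").value
        b = icc(make_intra_table(data + 500.0), "intra").value
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("design,pg_type", [("intra", "ICC(C,1)"),
                                                ("inter", "ICC(A,1)")])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, design, pg_type, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(1600, 100, size=(10, 2)) + rng.normal(
            0, 10, size=(10, 2)
        )
        table = make_intra_table(data) if design == "intra" else make_table(data)
        mine = icc(table, design)
        long = table.rename(
            columns={"condyle": "targets",
                     "occasion" if design == "intra" else "rater": "raters"}
        )
        ref = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="value"
        )
        ref_val = float(ref.loc[ref["Type"] == pg_type, "ICC"].iloc[0])
        assert mine.value == pytest.approx(ref_val, abs=1e-10)

    def test_zero_between_condyle_variance_rejected(self):
        data = np.full((5, 2), 1000.0)
        with pytest.raises(ValueError, match="variance"):
            icc(make_table(data), "inter")

    def test_variance_component_recovery(self):
        # sigma_c^2=10000, sigma_r^2=0, sigma_e^2=100 -> ICC(2,1) ~ 0.990
        from condylometry.synth import make_rating_table

        values = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            truth = rng.normal(1631, 100, size=20)
            t = make_rating_table(
                20, truth, within_rater_sd=10.0, between_rater_sd=0.0,
                seed=seed + 1000,
            )
            values.append(icc(t, "inter").value)
        assert np.mean(values) == pytest.approx(10000 / 10100, abs=0.01)


class TestCompareSoftwareVolumes:
    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_software_volumes({"only": np.arange(10.0)})

    def test_shifted_group_detected_with_posthoc(self):
        rng = np.random.default_rng(0)
        groups = {
            f"m{i}": rng.normal(1600, 30, 20) for i in range(4)
        }
        groups["shifted"] = rng.normal(1900, 30, 20)
        out = compare_software_volumes(groups)
        assert out["kruskal_wallis"].p_value < 0.05
        assert out["differs_from"]["shifted"]  # flagged against others
        assert all(
            p["p_bonferroni"] >= p["p_raw"] for p in out["posthoc"]
        )

    def test_null_groups_usually_not_significant(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = {f"m{i}": rng.normal(1600, 150, 20) for i in range(5)}
            out = compare_software_volumes(groups)
            hits += out["kruskal_wallis"].p_value < 0.05
        assert hits <= 6  # ~5% nominal rate, generous bound at n=40

    def test_summary_fields(self):
        out = compare_software_volumes(
            {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])}
        )
        assert out["summary"]["a"]["median"] == 2.0
        assert out["summary"]["a"]["min"] == 1.0
        assert out["summary"]["b"]["max"] == 6.0
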