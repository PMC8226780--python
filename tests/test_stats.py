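"""Statistical kernels against brute-force and library oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from headperturb.stats import (
    anova_main_effects,
    bonferroni,
    fisher_z,
    network_entry_mask,
    posthoc_marginal_means,
    spearman_matrix_similarity,
    wilcoxon_signed_rank,
)
from headperturb.types import ConnectivityMatrix


def _conn(m, names=None):
    m = np.asarray(m, dtype=float)
    names = names or [f"s{i}" for i in range(m.shape[0])]
    return ConnectivityMatrix({"alpha": m}, {"alpha": (8.0, 13.0)}, names)


def _sym(vals, n):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vals
    return m + m.T


class TestSpearman:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        m = _sym(rng.standard_normal(15), 6)
        assert np.isclose(spearman_matrix_similarity(_conn(m), _conn(m.copy()),
                                                     "alpha"), 1.0)

    def test_rank_reversal_gives_minus_one(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(15)
        a = _sym(vals, 6)
        b = _sym(-vals, 6)
        assert np.isclose(spearman_matrix_similarity(_conn(a), _conn(b), "alpha"),
                          -1.0)

    def test_toy_vectors_match_rank_formula(self):
        # upper triangle of a 4-seed matrix has 6 entries
        a = _sym([3, 1, 2, 5, 4, 6], 4)
        b = _sym([1, 2, 3, 4, 5, 6], 4)
        # rho = 1 - 6*Σd²/(n(n²-1)); d = (2,-1,-1,1,-1,0), Σd² = 8, n = 6
        expected = 1 - 6 * 8 / (6 * 35)
        got = spearman_matrix_similarity(_conn(a), _conn(b), "alpha")
        assert np.isclose(got, expected)

    @given(st.integers(0, 1000))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        vals_a = rng.integers(0, 5, size=15).astype(float)
        vals_b = rng.standard_normal(15)
        if np.ptp(vals_a) == 0:
            return
        a = _sym(vals_a, 6)
        b = _sym(vals_b, 6)
        got = spearman_matrix_similarity(_conn(a), _conn(b), "alpha")
        want = ss.spearmanr(vals_a, vals_b).statistic
        assert np.isclose(got, want, atol=1e-12)

    def test_constant_vector_rejected(self):
        a = _sym(np.ones(15), 6)
        b = _sym(np.arange(15.0), 6)
        with pytest.raises(ValueError):
            spearman_matrix_similarity(_conn(a), _conn(b), "alpha")

    def test_network_selector_counts(self, network21):
        mask = network_entry_mask(network21, "VAN")
        k = len(network21.seeds_of("VAN"))
        n = 21
        expected = k * (k - 1) // 2 + k * (n - k)
        assert mask.sum() == expected


class TestFisher:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert np.isclose(fisher_z(0.5), 0.5493061443)

    def test_antisymmetry(self):
        for r in (0.1, 0.35, 0.99):
            assert np.isclose(fisher_z(-r), -fisher_z(r))

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z) and z > 8.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


def _factorial_table(level_counts, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(len(level_counts))]
    rows = []
    for combo in product(*[range(k) for k in level_counts]):
        rows.append(dict(zip(names, [f"L{v}" for v in combo])))
    df = pd.DataFrame(rows)
    df["z"] = constant if constant is not None else rng.standard_normal(len(df))
    return df, names


class TestAnova:
    def test_four_way_design_dfs(self):
        df, names = _factorial_table([6, 5, 4, 2])
        aov = anova_main_effects(df, names)
        by = aov.set_index("factor")
        assert by.loc["Residuals", "df"] == 226
        assert by.loc["Total", "df"] == 239

    def test_three_way_design_dfs(self):
        df, names = _factorial_table([6, 5, 3])
        aov = anova_main_effects(df, names)
        by = aov.set_index("factor")
        assert by.loc["Residuals", "df"] == 78
        assert by.loc["Total", "df"] == 89

    def test_constant_response_reports_nan_f(self):
        df, names = _factorial_table([3, 2], constant=1.0)
        aov = anova_main_effects(df, names)
        assert (aov[aov.factor.isin(names)]["sum_sq"] == 0).all()
        assert aov[aov.factor.isin(names)]["F"].isna().all()

    def test_incomplete_design_rejected(self):
        df, names = _factorial_table([3, 2])
        with pytest.raises(ValueError):
            anova_main_effects(df.iloc[:-1], names)

    @given(st.lists(st.integers(2, 5), min_size=2, max_size=4),
           st.integers(0, 10**6))
    @settings(max_examples=15)
    def test_df_identity_for_any_complete_design(self, levels, seed):
        df, names = _factorial_table(levels, seed=seed)
        aov = anova_main_effects(df, names)
        by = aov.set_index("factor")
        total = int(np.prod(levels)) - 1
        factor_dfs = sum(k - 1 for k in levels)
        assert by.loc["Total", "df"] == total
        assert by.loc["Residuals", "df"] == total - factor_dfs
        assert int(by.loc[names, "df"].sum()) == factor_dfs
        # SS are non-negative and factor+residual SS add to total
        assert (by.loc[names + ["Residuals"], "sum_sq"] >= -1e-9).all()
        assert np.isclose(by.loc[names, "sum_sq"].sum()
                          + by.loc["Residuals", "sum_sq"],
                          by.loc["Total", "sum_sq"])

    def test_matches_r_style_balanced_decomposition(self):
        # balanced main-effects ANOVA: SS_factor = Σ n_level (mean_level - grand)²
        df, names = _factorial_table([4, 3], seed=5)
        aov = anova_main_effects(df, names).set_index("factor")
        grand = df.z.mean()
        for f in names:
            ss_f = sum(len(g) * (g.z.mean() - grand) ** 2
                       for _, g in df.groupby(f))
            assert np.isclose(aov.loc[f, "sum_sq"], ss_f)


class TestPosthoc:
    def test_comparison_count(self):
        df, names = _factorial_table([5, 2], seed=2)
        out = posthoc_marginal_means(df, names, "f0")
        assert len(out) == 5 * 4 // 2

    def test_outlier_level_detected(self):
        df, names = _factorial_table([3, 2], seed=3)
        df["z"] = 0.001 * np.random.default_rng(0).standard_normal(len(df))
        df.loc[df.f0 == "L2", "z"] += 10.0
        out = posthoc_marginal_means(df, names, "f0")
        involving = out[(out.level_a == "L2") | (out.level_b == "L2")]
        others = out[(out.level_a != "L2") & (out.level_b != "L2")]
        assert (involving.p_adj < 1e-6).all()
        assert (others.p_adj > 0.05).all()

    def test_single_level_rejected(self):
        df, names = _factorial_table([3, 2])
        df["f1"] = "only"
        with pytest.raises(ValueError):
            posthoc_marginal_means(df, names, "f1")


def _brute_force_wilcoxon(d, alternative):
    """Enumerate all 2^n sign patterns of |d| (exact null)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**n):
        signs = [(bits >> k) & 1 for k in range(n)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return w_obs, p_ge
    if alternative == "less":
        return w_obs, p_le
    return w_obs, min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_n6_all_positive_two_tailed(self):
        a = np.arange(1.0, 7.0) + 1.0
        b = np.arange(1.0, 7.0)
        w, p, z = wilcoxon_signed_rank(a, b)
        assert w == 21.0
        assert np.isclose(p, 2 / 64)
        assert z > 0

    def test_all_zero_differences_rejected(self):
        a = np.ones(8)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a)

    def test_swap_flips_one_tailed_p(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(12)
        b = a + rng.standard_normal(12) * 0.5
        # distinct |d| (no ties, no zeros) so the exact null is symmetric
        _, p_g, _ = wilcoxon_signed_rank(a, b, "greater")
        _, p_l, _ = wilcoxon_signed_rank(b, a, "less")
        assert np.isclose(p_g, p_l)

    @given(st.integers(0, 10**6), st.integers(5, 10),
           st.sampled_from(["two-sided", "greater", "less"]))
    @settings(max_examples=30)
    def test_exact_null_matches_brute_force(self, seed, n, alternative):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=n).astype(float)
        if np.all(d == 0) or np.count_nonzero(d) < 5:
            return
        a = d
        b = np.zeros_like(d)
        w, p, _ = wilcoxon_signed_rank(a, b, alternative)
        w_bf, p_bf = _brute_force_wilcoxon(d, alternative)
        assert w == w_bf
        assert np.isclose(p, p_bf, atol=1e-12)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        w, p, _ = wilcoxon_signed_rank(a, b)
        res = ss.wilcoxon(a, b, alternative="two-sided", mode="exact")
        # scipy reports min(W+, W-); ours reports W+
        n = 15
        assert w in (res.statistic, n * (n + 1) / 2 - res.statistic)
        assert np.isclose(p, res.pvalue, atol=1e-12)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni(np.array([0.01]), 5)[0] == 0.05
        assert bonferroni(np.array([0.5]), 10)[0] == 1.0
        assert bonferroni(np.array([0.2]), 1)[0] == 0.2

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.5]), 2)

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([0.1, 0.2, 0.3]), 2)
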