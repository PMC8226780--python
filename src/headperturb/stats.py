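"""Statistical machinery for model comparisons: Spearman matrix similarity,
Fisher transform, main-effects factorial ANOVA with Tukey-style post-hoc
marginal means, exact/approximate Wilcoxon signed-rank, and Bonferroni
correction."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as ss
from scipy.stats import rankdata

from .types import ConnectivityMatrix, NetworkDefinition

__all__ = [
    "spearman_matrix_similarity",
    "network_entry_mask",
    "fisher_z",
    "anova_main_effects",
    "posthoc_marginal_means",
    "wilcoxon_signed_rank",
    "bonferroni",
]


def network_entry_mask(network_def: NetworkDefinition, network: str) -> np.ndarray:
    """Upper-triangle mask of seed pairs involving the given network's
    seeds (its within-network pairs plus all its between-network pairs)."""
    n = len(network_def.seed_names)
    members = set(network_def.seeds_of(network))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if i in members or j in members:
                mask[i, j] = True
    return mask


def spearman_matrix_similarity(
    conn_a: ConnectivityMatrix,
    conn_b: ConnectivityMatrix,
    band: str,
    entry_selector: np.ndarray | None = None,
) -> float:
    """Spearman rank correlation between two connectivity matrices.

    Entries are vectorized over ``entry_selector`` (an upper-triangle
    boolean mask; default: all off-diagonal seed pairs). Ties receive
    average ranks.
    """
    if conn_a.seed_names != conn_b.seed_names:
        raise ValueError("connectivity matrices have different seeds")
    a = conn_a.z[band]
    b = conn_b.z[band]
    n = a.shape[0]
    if entry_selector is None:
        entry_selector = np.triu(np.ones((n, n), dtype=bool), k=1)
    va = a[entry_selector]
    vb = b[entry_selector]
    if va.size < 5:
        raise ValueError("selector yields fewer than 5 entries")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant vector: Spearman undefined")
    ra = rankdata(va)
    rb = rankdata(vb)
    return float(np.corrcoef(ra, rb)[0, 1])


def fisher_z(rho: float) -> float:
    """Variance-stabilizing Fisher transform z = atanh(rho); |rho| = 1 is
    clipped at 1 − 1e-7 with a warning."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if abs(rho) == 1.0:
        warnings.warn("|rho| = 1 clipped before Fisher transform", stacklevel=2)
        rho = np.sign(rho) * (1.0 - 1e-7)
    return float(np.arctanh(rho))


def anova_main_effects(table: pd.DataFrame, factor_columns: list[str],
                       response: str = "z") -> pd.DataFrame:
    """Main-effects-only fixed-effects ANOVA on a complete factorial table.

    Expects one observation per design cell. Returns a table with one row
    per factor plus Residuals and Total; degrees of freedom are
    Σ(levels−1) per factor with residual df = total − Σ factor dfs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.copy()
    levels = {}
    for f in factor_columns:
        levels[f] = sorted(data[f].unique())
    sizes = [len(v) for v in levels.values()]
    expected = int(np.prod(sizes))
    cells = data.groupby(factor_columns, observed=True).size()
    if len(cells) != expected or (cells != 1).any():
        raise ValueError("design is not a complete factorial with one "
                         "observation per cell")

    if data[response].nunique() == 1:
        rows = []
        for f, lv in levels.items():
            rows.append((f, len(lv) - 1, 0.0, 0.0, np.nan, np.nan))
        resid_df = expected - 1 - sum(len(lv) - 1 for lv in levels.values())
        rows.append(("Residuals", resid_df, 0.0, 0.0, np.nan, np.nan))
        rows.append(("Total", expected - 1, 0.0, np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["factor", "df", "sum_sq", "mean_sq", "F", "p"])

    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factor_columns)
    model = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)

    rows = []
    for f in factor_columns:
        r = aov.loc[f"C({f})"]
        rows.append((f, int(r["df"]), float(r["sum_sq"]),
                     float(r["sum_sq"] / r["df"]), float(r["F"]), float(r["PR(>F)"])))
    res = aov.loc["Residual"]
    rows.append(("Residuals", int(res["df"]), float(res["sum_sq"]),
                 float(res["sum_sq"] / res["df"]), np.nan, np.nan))
    total_ss = float(((data[response] - data[response].mean()) ** 2).sum())
    rows.append(("Total", expected - 1, total_ss, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["factor", "df", "sum_sq", "mean_sq", "F", "p"])


def posthoc_marginal_means(table: pd.DataFrame, factor_columns: list[str],
                           factor: str, response: str = "z") -> pd.DataFrame:
    """Tukey-HSD pairwise comparisons of estimated marginal means.

    Marginal means are per-level response means; the standard error uses
    the residual mean square of the main-effects ANOVA and p-values come
    from the studentized-range distribution with the residual df.
    """
    if factor not in factor_columns:
        raise ValueError(f"{factor!r} not among the design factors")
    lv = sorted(table[factor].unique())
    if len(lv) < 2:
        raise ValueError("factor has a single level")
    aov = anova_main_effects(table, factor_columns, response)
    mse = float(aov.loc[aov["factor"] == "Residuals", "mean_sq"].iloc[0])
    df_resid = int(aov.loc[aov["factor"] == "Residuals", "df"].iloc[0])
    k = len(lv)
    means = table.groupby(factor, observed=True)[response].mean()
    ns = table.groupby(factor, observed=True)[response].size()
    rows = []
    for a, b in combinations(lv, 2):
        diff = float(means[a] - means[b])
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        if mse == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(ss.studentized_range.sf(q, k, df_resid))
        rows.append((a, b, diff, float(se), float(q), min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "diff", "se", "q", "p_adj"])


def _exact_signed_rank_cdf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ over all sign assignments.

    Ranks may be half-integers (average ties); the support is enumerated on
    doubled ranks by dynamic programming over the 2^n sign patterns.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[:total + 1 - r]
        probs = 0.5 * (probs + shifted)
    support = np.arange(total + 1) / 2.0
    return support, probs


def wilcoxon_signed_rank(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); the null is exact
    (all sign assignments) for n ≤ 25 and a continuity-corrected normal
    approximation above. Returns (W+, p, z) where z is the signed normal
    score of W+ (positive when a tends to exceed b).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided/greater/less")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("fewer than 5 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    mu = n * (n + 1) / 4.0
    # tie-corrected variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    cc = 0.5 if w_plus != mu else 0.0
    z = (w_plus - mu - np.sign(w_plus - mu) * cc) / sigma

    if n <= 25:
        support, probs = _exact_signed_rank_cdf(ranks)
        p_ge = probs[support >= w_plus - 1e-9].sum()
        p_le = probs[support <= w_plus + 1e-9].sum()
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        if alternative == "greater":
            p = float(ss.norm.sf((w_plus - mu - 0.5) / sigma))
        elif alternative == "less":
            p = float(ss.norm.cdf((w_plus - mu + 0.5) / sigma))
        else:
            p = float(2.0 * ss.norm.sf(abs(z)))
    return w_plus, float(min(p, 1.0)), float(z)


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p·m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)
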