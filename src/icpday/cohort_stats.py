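"""Baseline-table comparisons, FDR control, logistic ORs and correlations.

Group comparisons follow the usual table-one conventions: continuous
variables are tested parametrically (t-test / one-way ANOVA) only when a
Kolmogorov-Smirnov normality check (Lilliefors-corrected, since the moments
are estimated) passes in every group, otherwise Wilcoxon rank-sum /
Kruskal-Wallis; categorical variables use the chi-square test, switching to
Fisher's exact on 2x2 tables with any expected cell below 5.  All p-values
of a table are jointly corrected with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "bh_adjust",
    "compare_groups",
    "multivariate_logistic",
    "fluid_icp_correlation",
]


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = x[np.isfinite(x)]
    if x.size < 5 or np.ptp(x) == 0:
        return False
    return lilliefors(x, dist="norm")[1] > alpha


def _continuous_test(groups: list[np.ndarray]) -> tuple[str, float]:
    if all(_is_normal(g) for g in groups):
        if len(groups) == 2:
            res = stats.ttest_ind(*groups)
            return "t-test", float(res.pvalue)
        return "anova", float(stats.f_oneway(*groups).pvalue)
    if len(groups) == 2:
        return "wilcoxon", float(stats.mannwhitneyu(*groups, alternative="two-sided").pvalue)
    return "kruskal", float(stats.kruskal(*groups).pvalue)


def _categorical_test(table: np.ndarray) -> tuple[str, float]:
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        return "fisher", float(stats.fisher_exact(table)[1])
    return "chi-square", float(stats.chi2_contingency(table, correction=False)[1])


def compare_groups(
    table: pd.DataFrame,
    grouping: str,
    variables: list[str] | None = None,
    categorical: list[str] | None = None,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Table-one style group comparison with BH-FDR across all rows.

    Continuous rows report ``mean ± sd`` per group, categorical rows
    ``n (pct%)`` per level (one test per variable on the full contingency
    table).  Variables constant over the whole cohort get p = 1.
    """
    groups = table[grouping]
    levels = [l for l in groups.dropna().unique()]
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    if variables is None:
        variables = [c for c in table.columns if c != grouping]
    categorical = set(categorical or [])

    rows = []
    for var in variables:
        col = table[var]
        is_cat = var in categorical or not pd.api.types.is_numeric_dtype(col) or col.nunique() <= 2
        summ: dict[str, str] = {}
        if col.dropna().nunique() <= 1:
            test, p = "constant", 1.0
            for lev in levels:
                summ[f"group_{lev}"] = "--"
        elif is_cat:
            ct = pd.crosstab(col, groups).reindex(columns=levels)
            test, p = _categorical_test(ct.to_numpy())
            for lev in levels:
                n_g = int((groups == lev).sum())
                parts = [
                    f"{v}: {int(ct.loc[v, lev])} ({100 * ct.loc[v, lev] / n_g:.1f}%)"
                    for v in ct.index
                ]
                summ[f"group_{lev}"] = "; ".join(parts)
        else:
            vals = [col[groups == lev].dropna().to_numpy(dtype=float) for lev in levels]
            test, p = _continuous_test(vals)
            for lev, v in zip(levels, vals):
                summ[f"group_{lev}"] = f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
        rows.append({"variable": var, **summ, "test": test, "p_value": p})

    out = pd.DataFrame(rows)
    reject, p_adj = bh_adjust(out["p_value"].to_numpy(), q=alpha_fdr)
    out["p_adjusted"] = p_adj
    out["fdr_significant"] = reject
    return out


def multivariate_logistic(
    outcome,
    covariates: pd.DataFrame,
    screen_p: float = 0.1,
    always_keep: tuple[str, ...] = ("age",),
) -> pd.DataFrame:
    """Multivariable logistic regression with a univariable entry screen.

    Covariates with univariable p < ``screen_p`` (always-keep names retained
    regardless) enter a joint maximum-likelihood logistic model; the table
    reports Wald odds ratios with 95% CIs.  On separation the model refits
    with a small L2 penalty and the CIs are marked missing.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    if y.size <= 10 * X.shape[1]:
        warnings.warn("fewer than 10 events-per-variable guideline subjects; estimates may be unstable")

    keep = []
    for colname in X.columns:
        base = next((a for a in always_keep if colname == a or colname.startswith(a + "_")), None)
        if base is not None:
            keep.append(colname)
            continue
        x = X[colname].to_numpy()
        if x.std() == 0:
            continue
        fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(maxiter=100)
        if fit.pvalues[1] < screen_p:
            keep.append(colname)
    if not keep:
        return pd.DataFrame(columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"])

    design = sm.add_constant(X[keep].to_numpy())
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse).all():
            raise np.linalg.LinAlgError
        params, bse, pvals = fit.params[1:], fit.bse[1:], fit.pvalues[1:]
    except Exception:
        warnings.warn("separation in logistic model; ridge-penalized point estimates, no Wald CIs")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
            alpha=1.0, L1_wt=0.0
        )
        params = np.asarray(fit.params)[1:]
        bse = np.full(len(keep), np.nan)
        pvals = np.full(len(keep), np.nan)
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "variable": keep,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvals,
        }
    )


def fluid_icp_correlation(
    fluid_balance, icp_mean, strata
) -> pd.DataFrame:
    """Pearson correlation between first-day fluid balance and ICP_mean,
    per stratum (e.g. ICU death vs survived); reports r, R^2 and the
    two-sided p.  Strata with < 3 subjects or zero variance come out NaN."""
    fluid = np.asarray(fluid_balance, dtype=float)
    icp = np.asarray(icp_mean, dtype=float)
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        x, y = fluid[sel], icp[sel]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            rows.append({"stratum": s, "n": int(x.size), "r": np.nan, "r2": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"stratum": s, "n": int(x.size), "r": float(r), "r2": float(r**2), "p_value": float(p)})
    return pd.DataFrame(rows)
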