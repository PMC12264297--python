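"""Confounder screening, propensity scores and stabilized IPTW effects.

The high/low ICP group defined by the survival cut-point is treated as a
binary "treatment".  Candidate baseline covariates are screened into the
propensity model when they are associated with the outcome (univariable
p < 0.1) or when adjusting for them moves the treatment coefficient by more
than 10% (relative).  The propensity score is a logistic model with
penalized-spline smooths for continuous covariates (a plain linear logistic
fit when the smoother is off).  Stabilized inverse-probability weights then
target the ATT, ATU or ATE, and the effect is the odds ratio from a weighted
logistic regression of the outcome on treatment, with bootstrap (default) or
robust-sandwich confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

__all__ = [
    "PSModelSpec",
    "EffectEstimate",
    "screen_confounders",
    "fit_propensity",
    "stabilized_weights",
    "standardized_mean_differences",
    "estimate_effect",
]

ESTIMANDS = ("ATT", "ATU", "ATE")


@dataclass
class PSModelSpec:
    candidate_covariates: tuple[str, ...] = ("age", "gender", "gcs_min", "apsiii", "oasis", "sofa")
    screen_p_threshold: float = 0.1
    screen_beta_change: float = 0.1  # relative change in the treatment coefficient
    smoother: bool = True
    ps_clip: tuple[float, float] = (0.01, 0.99)

    def __post_init__(self) -> None:
        if not 0 < self.screen_p_threshold < 1:
            raise ValueError("screen_p_threshold must lie in (0, 1)")
        if self.screen_beta_change <= 0:
            raise ValueError("screen_beta_change must be positive")


@dataclass
class EffectEstimate:
    estimand: str
    estimate: float                 # odds ratio
    ci_low: float
    ci_high: float
    p_value: float
    weights: np.ndarray
    balance_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    ci_method: str = "bootstrap"


def _as_design(covariates: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design columns (string/categorical covariates dummy-coded)."""
    X = covariates[columns].copy()
    return pd.get_dummies(X, drop_first=True, dtype=float)


def _logit_fit(y: np.ndarray, X: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    return model.fit(maxiter=100)


def screen_confounders(
    covariates: pd.DataFrame,
    treatment,
    outcome,
    spec: PSModelSpec | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Select covariates by outcome association or treatment-coefficient shift.

    A covariate enters the propensity model when its univariable logistic
    association with the outcome has p below the threshold, or when adding it
    to ``outcome ~ treatment`` changes the treatment log-odds coefficient by
    more than the relative tolerance.  Constant covariates are skipped with a
    warning.  Returns the selected names and a per-covariate log.
    """
    spec = spec or PSModelSpec()
    t = np.asarray(treatment, dtype=float)
    y = np.asarray(outcome, dtype=float)
    base = _logit_fit(y, sm.add_constant(t))
    beta0 = base.params[1]

    rows, selected = [], []
    for name in spec.candidate_covariates:
        col = covariates[name]
        design = _as_design(covariates, [name]).to_numpy()
        if design.shape[1] == 0 or np.all(design.std(axis=0) == 0):
            warnings.warn(f"covariate {name!r} is constant; skipped")
            rows.append({"covariate": name, "p_outcome": np.nan,
                         "beta_change": np.nan, "selected": False, "note": "constant"})
            continue
        uni = _logit_fit(y, sm.add_constant(design))
        p_out = float(uni.pvalues[1:].min())
        adj = _logit_fit(y, sm.add_constant(np.column_stack([t, design])))
        beta1 = adj.params[1]
        # relative change-in-estimate; absolute when the base treatment
        # coefficient is near zero (a relative criterion is unstable there)
        change = abs(beta1 - beta0) / abs(beta0) if abs(beta0) > 0.1 else abs(beta1 - beta0)
        keep = (p_out < spec.screen_p_threshold) or (change > spec.screen_beta_change)
        if keep:
            selected.append(name)
        rows.append({"covariate": name, "p_outcome": p_out,
                     "beta_change": float(change), "selected": keep, "note": ""})
    return selected, pd.DataFrame(rows)


def fit_propensity(
    covariates: pd.DataFrame,
    treatment,
    spec: PSModelSpec | None = None,
    selected: list[str] | None = None,
) -> np.ndarray:
    """Propensity scores P(treated | covariates), clipped away from {0, 1}.

    With the smoother on, continuous covariates (more than 10 distinct
    values) enter through B-spline bases (df = 4), approximating a
    generalized additive fit; otherwise the model is linear in the
    covariates.  An empty covariate set yields the marginal treatment
    prevalence for everyone.  Perfect separation falls back to an L2-ridge
    logistic fit with a warning.
    """
    spec = spec or PSModelSpec()
    t = np.asarray(treatment, dtype=float)
    if t.min() == t.max():
        raise ValueError("need both treated and control subjects")
    names = list(spec.candidate_covariates if selected is None else selected)
    names = [n for n in names if n in covariates.columns]
    if not names:
        ps = np.full(t.size, t.mean())
        return np.clip(ps, *spec.ps_clip)

    parts = []
    for name in names:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 10 and spec.smoother:
            basis = patsy.dmatrix(
                "bs(x, df=4, include_intercept=False) - 1",
                {"x": np.asarray(col, float)},
                return_type="dataframe",
            )
            basis.columns = [f"{name}_s{i}" for i in range(basis.shape[1])]
            parts.append(basis.to_numpy())
        else:
            parts.append(_as_design(covariates, [name]).to_numpy())
    X = sm.add_constant(np.column_stack(parts))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(t, X, family=sm.families.Binomial()).fit(maxiter=200)
        ps = np.asarray(fit.fittedvalues)
        if not np.isfinite(ps).all():
            raise ValueError("non-finite fitted propensity")
    except Exception:
        warnings.warn("propensity model separation; falling back to ridge logistic")
        from sklearn.linear_model import LogisticRegression

        Xl = _as_design(covariates, names).to_numpy()
        clf = LogisticRegression(C=1.0, max_iter=1000).fit(Xl, t)
        ps = clf.predict_proba(Xl)[:, 1]
    return np.clip(ps, *spec.ps_clip)


def stabilized_weights(ps, treatment, estimand: str = "ATE") -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights.

    ATE: treated P(T=1)/ps, controls P(T=0)/(1-ps).
    ATT: treated 1, controls ps/(1-ps).
    ATU: treated (1-ps)/ps, controls 1.
    """
    ps = np.asarray(ps, dtype=float)
    t = np.asarray(treatment, dtype=bool)
    if ((ps <= 0) | (ps >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if estimand == "ATE":
        p1 = t.mean()
        w = np.where(t, p1 / ps, (1 - p1) / (1 - ps))
    elif estimand == "ATT":
        w = np.where(t, 1.0, ps / (1 - ps))
    elif estimand == "ATU":
        w = np.where(t, (1 - ps) / ps, 1.0)
    else:
        raise ValueError(f"estimand must be one of {ESTIMANDS}")
    return w


def standardized_mean_differences(
    covariates: pd.DataFrame, treatment, weights=None
) -> pd.Series:
    """Absolute standardized mean differences (treated vs control), optionally
    under weighting; the denominator is the unweighted pooled sd."""
    t = np.asarray(treatment, dtype=bool)
    w = np.ones(t.size) if weights is None else np.asarray(weights, dtype=float)
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        m1 = np.average(x[t], weights=w[t])
        m0 = np.average(x[~t], weights=w[~t])
        sd = np.sqrt((x[t].var(ddof=1) + x[~t].var(ddof=1)) / 2)
        out[col] = abs(m1 - m0) / sd if sd > 0 else 0.0
    return pd.Series(out, name="smd")


def _weighted_or(y: np.ndarray, t: np.ndarray, w: np.ndarray) -> float:
    """Odds ratio from a weighted logistic regression of y on t; falls back
    to a continuity-corrected weighted 2x2 when an arm has no events."""
    arms_ok = all(
        (w[(t == a)] * y[(t == a)]).sum() > 0 and (w[(t == a)] * (1 - y[(t == a)])).sum() > 0
        for a in (0, 1)
    )
    if not arms_ok:
        warnings.warn("zero (weighted) events in an arm; continuity-corrected OR")
        a = (w * (t * y)).sum() + 0.5
        b = (w * (t * (1 - y))).sum() + 0.5
        c = (w * ((1 - t) * y)).sum() + 0.5
        d = (w * ((1 - t) * (1 - y))).sum() + 0.5
        return float(a * d / (b * c))
    X = sm.add_constant(t.astype(float))
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(maxiter=100)
    return float(np.exp(fit.params[1]))


def estimate_effect(
    outcome,
    treatment,
    covariates: pd.DataFrame | None = None,
    spec: PSModelSpec | None = None,
    estimand: str = "ATT",
    weights=None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> EffectEstimate:
    """Weighted odds-ratio treatment effect with uncertainty.

    When ``covariates`` are given, the propensity model and weights are
    (re)fit internally — including inside every bootstrap resample, so the
    interval reflects design uncertainty.  Precomputed ``weights`` may be
    supplied instead (bootstrap then resamples subjects with their weights
    fixed).  ``ci_method='robust'`` replaces the bootstrap with an HC1
    sandwich interval from the weighted logistic fit.
    """
    y = np.asarray(outcome, dtype=float)
    t = np.asarray(treatment, dtype=float)
    spec = spec or PSModelSpec()
    if estimand not in ESTIMANDS:
        raise ValueError(f"estimand must be one of {ESTIMANDS}")

    def _weights_for(idx: np.ndarray) -> np.ndarray:
        if covariates is not None:
            ps = fit_propensity(covariates.iloc[idx], t[idx], spec)
            return stabilized_weights(ps, t[idx], estimand)
        if weights is not None:
            return np.asarray(weights, dtype=float)[idx]
        return np.ones(idx.size)

    all_idx = np.arange(y.size)
    w = _weights_for(all_idx)
    if (w[t == 1].sum() <= 0) or (w[t == 0].sum() <= 0):
        raise ValueError("both arms need positive total weight")
    or_hat = _weighted_or(y, t, w)

    balance_before = standardized_mean_differences(covariates, t) if covariates is not None else None
    balance = pd.DataFrame()
    if balance_before is not None:
        balance = pd.DataFrame(
            {"smd_unweighted": balance_before,
             "smd_weighted": standardized_mean_differences(covariates, t, w)}
        )

    if ci_method == "robust":
        X = sm.add_constant(t)
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
            maxiter=100, cov_type="HC1"
        )
        lo, hi = np.exp(fit.conf_int()[1])
        p = float(fit.pvalues[1])
        return EffectEstimate(estimand, or_hat, float(lo), float(hi), p, w, balance, "robust")

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, y.size, size=y.size)
        if len(np.unique(t[idx])) < 2:
            boots[b] = np.nan
            continue
        try:
            wb = _weights_for(idx)
            boots[b] = np.log(_weighted_or(y[idx], t[idx], wb))
        except Exception:
            boots[b] = np.nan
    boots = boots[np.isfinite(boots)]
    if boots.size < max(20, n_boot // 5):
        raise RuntimeError("too many failed bootstrap resamples")
    lo, hi = np.exp(np.percentile(boots, [2.5, 97.5]))
    se = boots.std(ddof=1)
    from scipy import stats as _st

    p = float(2 * _st.norm.sf(abs(np.log(or_hat)) / se)) if se > 0 else 1.0
    return EffectEstimate(estimand, or_hat, float(lo), float(hi), p, w, balance, "bootstrap")
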