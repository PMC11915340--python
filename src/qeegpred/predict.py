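"""Group statistics, model building, and validation.

Implements the clinical prediction-model workflow: per-feature group
comparison with test choice guided by Shapiro-Wilk normality
(t-test / Mann-Whitney U; chi-square or Fisher's exact for categoricals),
Benjamini-Hochberg FDR correction, univariable logistic screening
(FDR-adjusted p < 0.20), backward-stepwise multivariable logistic
regression (likelihood-ratio removal at p > 0.10), collinearity check via
VIF, nomogram point scale, ROC/AUC with DeLong CI, calibration curve with
the Hosmer-Lemeshow test, decision-curve analysis, and Harrell bootstrap
optimism correction of the apparent AUC.

The binary outcome codes the encephalopathy-bound group as 1 and the
benign group as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compare_groups",
    "fdr_correct",
    "univariable_screen",
    "iqr_categorize",
    "LogisticModel",
    "fit_backward_logistic",
    "vif",
    "NomogramScale",
    "nomogram_scale",
    "roc_auc",
    "calibration",
    "decision_curve",
    "bootstrap_validate",
    "apply_model",
]


# --------------------------------------------------------------------------
# group comparison and screening
# --------------------------------------------------------------------------

def _is_categorical(x: pd.Series) -> bool:
    if not pd.api.types.is_numeric_dtype(x):
        return True
    return x.nunique(dropna=True) <= 2


def compare_groups(ft: pd.DataFrame, outcome: str = "group",
                   features: list[str] | None = None,
                   categorical: list[str] | None = None,
                   alpha_normality: float = 0.05,
                   yates: bool = False) -> pd.DataFrame:
    """Per-feature two-group comparison with data-driven test choice.

    Continuous features: Shapiro-Wilk in each group; independent-samples
    t-test if both are consistent with normality, Mann-Whitney U otherwise.
    Categorical features: Pearson chi-square (no continuity correction by
    default), Fisher's exact when any expected cell count is below 5
    (2x2 tables).  All tests two-tailed.  Returns a table with the raw and
    BH-FDR-adjusted p-values.
    """
    y = ft[outcome]
    groups = sorted(y.dropna().unique())
    if len(groups) != 2:
        raise ValueError("outcome must have exactly two groups")
    if features is None:
        features = [c for c in ft.columns if c not in (outcome, "subject_id")]
    categorical = set(categorical or [])
    rows = []
    for feat in features:
        x = ft[feat]
        mask = x.notna() & y.notna()
        x, yy = x[mask], y[mask]
        a = x[yy == groups[0]]
        b = x[yy == groups[1]]
        if x.nunique() <= 1:
            rows.append({"feature": feat, "test": "none", "statistic": np.nan,
                         "p": np.nan, "note": "zero variance"})
            continue
        if feat in categorical or _is_categorical(x):
            tab = pd.crosstab(x, yy).to_numpy()
            expected = scipy.stats.contingency.expected_freq(tab)
            if (expected < 5).any() and tab.shape == (2, 2):
                stat, p = np.nan, scipy.stats.fisher_exact(tab)[1]
                test = "fisher"
            else:
                stat, p, _, _ = scipy.stats.chi2_contingency(tab, correction=yates)
                test = "chi2"
        else:
            normal = all(
                len(g) >= 3 and scipy.stats.shapiro(g).pvalue > alpha_normality
                for g in (a, b)
            )
            if normal:
                stat, p = scipy.stats.ttest_ind(a, b)
                test = "t"
            else:
                stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
                test = "mannwhitney"
        rows.append({"feature": feat, "test": test, "statistic": stat,
                     "p": p, "note": ""})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = fdr_correct(out.loc[valid, "p"].to_numpy())
    return out


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # near-collinear candidate sets make the Newton Hessian singular;
            # quasi-Newton still yields the ML fit and a usable covariance
            return model.fit(disp=0, maxiter=500, method="bfgs")


def univariable_screen(ft: pd.DataFrame, outcome: str = "group",
                       features: list[str] | None = None,
                       keep_threshold: float = 0.20) -> tuple[list[str], pd.DataFrame]:
    """One-predictor logistic fits; keep features with FDR-adjusted p < 0.20.

    Wald p-values of the slope are FDR-corrected across the feature family.
    Constant features are excluded; fits showing separation are retained
    with a warning (their evidence is strong, not absent).
    """
    if features is None:
        features = [c for c in ft.columns if c not in (outcome, "subject_id")]
    y = ft[outcome].to_numpy(dtype=float)
    rows = []
    for feat in features:
        x = ft[feat].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"feature {feat!r} is constant; excluded from screen")
            rows.append({"feature": feat, "coef": np.nan, "p": np.nan,
                         "note": "constant"})
            continue
        X = sm.add_constant(x)
        try:
            res = _fit_logit(y, X)
            p = float(res.pvalues[1])
            coef = float(res.params[1])
            note = ""
            if not res.mle_retvals.get("converged", True) or not np.isfinite(p):
                warnings.warn(f"separation/convergence issue for {feat!r}; retained")
                p, note = 0.0, "separation"
        except Exception:
            warnings.warn(f"separation/convergence issue for {feat!r}; retained")
            coef, p, note = np.nan, 0.0, "separation"
        rows.append({"feature": feat, "coef": coef, "p": p, "note": note})
    tab = pd.DataFrame(rows)
    valid = tab["p"].notna()
    tab["p_fdr"] = np.nan
    if valid.any():
        tab.loc[valid, "p_fdr"] = fdr_correct(tab.loc[valid, "p"].to_numpy())
    selected = tab.loc[valid & (tab["p_fdr"] < keep_threshold), "feature"].tolist()
    return selected, tab


def iqr_categorize(values, cutpoints: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Quartile categories 0-3 from training cut-points (Q1, Q2, Q3).

    When ``cutpoints`` is given (validation data) they are reused; values
    below the training minimum fall in the lowest category, above the
    maximum in the highest.  Degenerate (tied) quartiles collapse to fewer
    categories with a warning.
    """
    x = np.asarray(values, dtype=float)
    if cutpoints is None:
        cutpoints = np.quantile(x, [0.25, 0.5, 0.75])
        uniq = np.unique(cutpoints)
        if len(uniq) < len(cutpoints):
            warnings.warn("tied quartiles: fewer than 4 categories")
            cutpoints = uniq
    codes = np.searchsorted(cutpoints, x, side="left")
    return codes, np.asarray(cutpoints, dtype=float)


# --------------------------------------------------------------------------
# multivariable model
# --------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Fitted multivariable logistic model with its encodings and metadata."""

    predictors: list[str]
    coefficients: dict[str, float]          # per design column, log-odds
    intercept: float
    encodings: dict[str, np.ndarray] = field(default_factory=dict)  # var -> IQR cutpoints
    column_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    feature_sd: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    llf: float = np.nan
    n_obs: int = 0
    outcome: str = "group"

    def design_columns(self, var: str) -> list[str]:
        return [c for c in self.coefficients if c == var or c.startswith(var + "::")]

    @property
    def standardized_coefficients(self) -> dict[str, float]:
        """Log-odds per SD increase for continuous design columns."""
        return {
            c: b * self.feature_sd[c]
            for c, b in self.coefficients.items() if c in self.feature_sd
        }


def _design_matrix(ft: pd.DataFrame, variables: list[str],
                   encodings: dict[str, np.ndarray]) -> pd.DataFrame:
    """Design columns for the given variables; IQR-categorised variables are
    dummy-coded against the lowest quartile (columns ``var::qK``)."""
    cols = {}
    for var in variables:
        if var not in ft.columns:
            raise KeyError(var)
        x = ft[var].to_numpy(dtype=float)
        if var in encodings:
            codes, _ = iqr_categorize(x, encodings[var])
            n_levels = len(encodings[var]) + 1
            for lev in range(1, n_levels):
                cols[f"{var}::q{lev + 1}"] = (codes == lev).astype(float)
        else:
            cols[var] = x
    return pd.DataFrame(cols, index=ft.index)


def fit_backward_logistic(ft: pd.DataFrame, candidates: list[str],
                          outcome: str = "group",
                          categorize: list[str] | None = None,
                          removal_p: float = 0.10) -> LogisticModel:
    """Backward-stepwise maximum-likelihood logistic regression.

    Variables in ``categorize`` are first converted to quartile categories
    (cut-points stored for reuse on new data) and dummy-coded.  Elimination
    removes, one at a time, the variable whose likelihood-ratio removal
    test has the largest p-value above ``removal_p``; a categorical
    variable's dummies are removed as a block.  Deterministic given data.
    """
    y = ft[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    encodings = {}
    for var in categorize or []:
        if var in candidates:
            _, cuts = iqr_categorize(ft[var].to_numpy(dtype=float))
            encodings[var] = cuts
    if candidates and len(ft) <= 10 * len(candidates):
        warnings.warn(
            f"n={len(ft)} is small for {len(candidates)} candidates "
            "(events-per-variable guidance)"
        )

    current = list(candidates)

    def fit_set(vars_):
        X = _design_matrix(ft, vars_, encodings)
        Xc = sm.add_constant(X.to_numpy(), has_constant="add")
        res = _fit_logit(y, Xc)
        return res, list(X.columns)

    if not current:
        warnings.warn("no candidates: intercept-only model")
        res = _fit_logit(y, np.ones((len(y), 1)))
        return LogisticModel([], {}, float(res.params[0]), encodings,
                             converged=True, llf=float(res.llf),
                             n_obs=len(y), outcome=outcome)

    res, cols = fit_set(current)
    while len(current) > 0:
        worst, worst_p = None, -1.0
        for var in current:
            reduced = [v for v in current if v != var]
            if reduced:
                res_red, _ = fit_set(reduced)
                llf_red = res_red.llf
            else:
                llf_red = _fit_logit(y, np.ones((len(y), 1))).llf
            df = len([c for c in cols if c == var or c.startswith(var + "::")])
            lr = 2.0 * (res.llf - llf_red)
            p = scipy.stats.chi2.sf(max(lr, 0.0), df)
            if p > worst_p:
                worst, worst_p = var, p
        if worst_p > removal_p:
            current.remove(worst)
            if not current:
                warnings.warn("all candidates eliminated: intercept-only model")
                res0 = _fit_logit(y, np.ones((len(y), 1)))
                return LogisticModel([], {}, float(res0.params[0]), encodings,
                                     converged=True, llf=float(res0.llf),
                                     n_obs=len(y), outcome=outcome)
            res, cols = fit_set(current)
        else:
            break

    X = _design_matrix(ft, current, encodings)
    if not np.isfinite(res.params).all():
        raise RuntimeError("non-finite coefficients: separation or collinearity")
    coefs = dict(zip(X.columns, map(float, res.params[1:])))
    ranges = {c: (float(X[c].min()), float(X[c].max())) for c in X.columns}
    sds = {c: float(X[c].std(ddof=0)) for c in X.columns
           if c in current}  # continuous columns only
    return LogisticModel(
        predictors=current,
        coefficients=coefs,
        intercept=float(res.params[0]),
        encodings={v: encodings[v] for v in encodings if v in current},
        column_ranges=ranges,
        feature_sd=sds,
        converged=bool(res.mle_retvals.get("converged", True)),
        llf=float(res.llf),
        n_obs=len(y),
        outcome=outcome,
    )


def vif(ft: pd.DataFrame, predictors: list[str],
        encodings: dict[str, np.ndarray] | None = None) -> dict[str, float]:
    """Variance inflation factors 1/(1-R^2) per design column.

    Each column is linearly regressed on the remaining columns (categoricals
    dummy-coded).  Exact collinearity yields ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs >= 2 predictors")
    X = _design_matrix(ft, predictors, encodings or {}).to_numpy()
    n, p = X.shape
    out = {}
    cols = list(_design_matrix(ft, predictors, encodings or {}).columns)
    for j in range(p):
        xj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        ss_tot = ((xj - xj.mean()) ** 2).sum()
        if ss_tot == 0:
            out[cols[j]] = np.inf
            continue
        r2 = 1.0 - (resid ** 2).sum() / ss_tot
        out[cols[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# --------------------------------------------------------------------------
# nomogram
# --------------------------------------------------------------------------

@dataclass
class NomogramScale:
    """Point scale of a fitted model: per-column points and total -> probability.

    The design column with the largest |coefficient x observed range| spans
    0-100 points; other columns scale proportionally.  The total-points axis
    maps to predicted probability through the logistic inverse link, so the
    nomogram reproduces the model's probabilities exactly (up to point
    rounding when read off a printed axis).
    """

    log_odds_per_point: float
    base_log_odds: float                  # intercept + sum of per-column bases
    column_base: dict[str, float]         # beta * x at the zero-point end
    coefficients: dict[str, float]
    column_ranges: dict[str, tuple[float, float]]

    def points(self, row: dict[str, float] | pd.Series) -> dict[str, float]:
        return {
            c: (self.coefficients[c] * float(row[c]) - self.column_base[c])
            / self.log_odds_per_point
            for c in self.coefficients
        }

    def total_points(self, row) -> float:
        return float(sum(self.points(row).values()))

    def probability(self, total_points: float) -> float:
        return float(expit(self.base_log_odds
                           + self.log_odds_per_point * total_points))


def nomogram_scale(model: LogisticModel) -> NomogramScale:
    """Build the point scale of a fitted model from its training ranges."""
    if not model.coefficients:
        raise ValueError("nomogram requires a model with >= 1 predictor")
    spans = {}
    for c, b in model.coefficients.items():
        lo, hi = model.column_ranges[c]
        spans[c] = abs(b * (hi - lo))
    max_span = max(spans.values())
    if max_span == 0:
        raise ValueError("all predictors have zero range")
    zero_range = [c for c, s in spans.items() if s == 0]
    for c in zero_range:
        warnings.warn(f"predictor column {c!r} has zero range; carries 0 points")
    scale = max_span / 100.0             # log-odds per point
    base = {}
    for c, b in model.coefficients.items():
        lo, hi = model.column_ranges[c]
        base[c] = min(b * lo, b * hi)
    return NomogramScale(
        log_odds_per_point=scale,
        base_log_odds=model.intercept + sum(base.values()),
        column_base=base,
        coefficients=dict(model.coefficients),
        column_ranges=dict(model.column_ranges),
    )


# --------------------------------------------------------------------------
# discrimination, calibration, clinical utility
# --------------------------------------------------------------------------

def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # mid-rank placements
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, ci_method: str = "delong",
            n_boot: int = 2000, seed=None, alpha: float = 0.05
            ) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney concordance, ties at 1/2) with 95% CI.

    CI by the DeLong method (default) or a percentile bootstrap.
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(scores, labels))
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(labels)
        vals = []
        while len(vals) < n_boot:
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) < 2:
                continue
            vals.append(roc_auc_score(labels[idx], scores[idx]))
        ci = tuple(np.quantile(vals, [alpha / 2, 1 - alpha / 2]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return auc, ci


def calibration(probabilities, labels, n_bins: int = 10
                ) -> tuple[pd.DataFrame, float, float, int]:
    """Decile-of-risk calibration bins and the Hosmer-Lemeshow statistic.

    Returns ``(bins, hl_statistic, hl_p, df)`` with df = bins - 2.  Empty or
    degenerate deciles are merged with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    try:
        groups = pd.qcut(p, n_bins, labels=False, duplicates="drop")
    except ValueError:
        groups = np.zeros(len(p), dtype=int)
    n_groups = int(groups.max()) + 1
    if n_groups < n_bins:
        warnings.warn(f"merged calibration bins: {n_groups} of {n_bins} used")
    rows = []
    hl = 0.0
    for g in range(n_groups):
        m = groups == g
        n_g = int(m.sum())
        if n_g == 0:
            continue
        obs = float(y[m].sum())
        exp = float(p[m].sum())
        rows.append({"bin": g, "n": n_g, "mean_predicted": float(p[m].mean()),
                     "observed_rate": obs / n_g, "observed": obs, "expected": exp})
        denom = exp * (1.0 - exp / n_g)
        if denom > 0:
            hl += (obs - exp) ** 2 / denom
    df = max(n_groups - 2, 1)
    p_hl = float(scipy.stats.chi2.sf(hl, df))
    return pd.DataFrame(rows), float(hl), p_hl, df


def decision_curve(probabilities, labels,
                   thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    NB_model(pt) = TP/N - (FP/N) * pt/(1-pt), classifying positive when the
    predicted probability is >= pt; NB_all uses prevalence; NB_none is 0.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.991, 0.01), 3)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        classed = p >= pt
        tp = float((classed & (y == 1)).sum())
        fp = float((classed & (y == 0)).sum())
        rows.append({
            "threshold": pt,
            "nb_model": tp / n - fp / n * odds,
            "nb_all": prev - (1.0 - prev) * odds,
            "nb_none": 0.0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# internal validation and application
# --------------------------------------------------------------------------

def default_model_pipeline(features: list[str],
                           categorize: list[str] | None = None,
                           keep_threshold: float = 0.20,
                           removal_p: float = 0.10,
                           max_candidates: int | None = None):
    """Screen-then-stepwise pipeline as a refittable model specification.

    If the screen passes more candidates than one per ten subjects (an
    events-per-variable guard), only the smallest adjusted p-values enter
    the multivariable step.
    """
    def fit(ft: pd.DataFrame, outcome: str = "group") -> LogisticModel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, tab = univariable_screen(ft, outcome, features,
                                               keep_threshold)
            cap = max_candidates if max_candidates is not None \
                else max(2, len(ft) // 10)
            if len(selected) > cap:
                ranked = (tab.set_index("feature").loc[selected, "p_fdr"]
                          .sort_values(kind="stable"))
                selected = list(ranked.index[:cap])
            cat = [c for c in (categorize or []) if c in selected]
            return fit_backward_logistic(ft, selected, outcome, cat, removal_p)
    return fit


def apply_model(model: LogisticModel, ft_new: pd.DataFrame) -> np.ndarray:
    """Predicted probability per subject; training encodings are reused."""
    missing = [v for v in model.predictors if v not in ft_new.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    if not model.predictors:
        return np.full(len(ft_new), expit(model.intercept))
    X = _design_matrix(ft_new, model.predictors, model.encodings)
    eta = model.intercept + sum(
        model.coefficients[c] * X[c].to_numpy() for c in model.coefficients
    )
    return expit(eta)


def bootstrap_validate(ft: pd.DataFrame, model_spec, outcome: str = "group",
                       B: int = 1000, seed=None) -> dict:
    """Harrell optimism-corrected AUC of a refittable modelling pipeline.

    ``model_spec(ft, outcome)`` must re-run the full pipeline (screening and
    stepwise selection included, to avoid optimism leakage).  For each of B
    bootstrap resamples the pipeline is refit; optimism is the mean of
    (AUC on the resample) - (resample model's AUC on the original data) and
    is subtracted from the apparent AUC.  One-class resamples are redrawn
    (count reported).
    """
    rng = np.random.default_rng(seed)
    y = ft[outcome].to_numpy(dtype=float)
    model = model_spec(ft, outcome)
    p_app = apply_model(model, ft)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    from sklearn.metrics import roc_auc_score

    auc_apparent = float(roc_auc_score(y, p_app)) if model.predictors else 0.5
    optimism = []
    redrawn = 0
    n = len(ft)
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            redrawn += 1
            continue
        fb = ft.iloc[idx].reset_index(drop=True)
        try:
            mb = model_spec(fb, outcome)
        except Exception:
            redrawn += 1
            continue
        if mb.predictors:
            auc_boot = float(roc_auc_score(yb, apply_model(mb, fb)))
            auc_orig = float(roc_auc_score(y, apply_model(mb, ft)))
        else:
            auc_boot = auc_orig = 0.5
        optimism.append(auc_boot - auc_orig)
        b += 1
    opt = float(np.mean(optimism)) if optimism else 0.0
    return {
        "auc_apparent": auc_apparent,
        "optimism": opt,
        "auc_corrected": auc_apparent - opt,
        "n_boot": B,
        "n_redrawn": redrawn,
        "model": model,
    }
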