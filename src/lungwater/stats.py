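"""Cohort-level diagnostic statistics.

Group comparisons with a Shapiro-Wilk normality gate, correlation,
univariable and forward-stepwise multivariable linear regression with
collinearity screening, empirical ROC analysis with Youden's index (DeLong
confidence interval for the AUC), and prevalence-based diagnostic
performance (sensitivity, specificity, predictive values, positive and
inverse negative likelihood ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InputError, ParameterError

ALPHA_NORMALITY = 0.05


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------
@dataclass
class GroupComparison:
    variable: str
    test_used: str  # "t" | "mann_whitney" | "chi2"
    summaries: dict
    p_value: float


def compare_groups(
    values, group_labels, variable_kind: str = "continuous", variable: str = ""
) -> GroupComparison:
    """Two-group comparison with the normality gate.

    Continuous: Shapiro-Wilk per group at alpha 0.05; both normal -> Student
    t-test (two-sided), otherwise Mann-Whitney U. Categorical: chi-squared
    on the contingency table (no continuity correction).
    """
    values = np.asarray(values)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise InputError("values and group labels must align")
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise InputError(f"expected exactly 2 groups, got {len(groups)}")

    if variable_kind == "categorical":
        table = pd.crosstab(group_labels, values).to_numpy()
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        summaries = {
            str(g): {str(v): int(c) for v, c in
                     pd.Series(values[group_labels == g]).value_counts().items()}
            for g in groups
        }
        return GroupComparison(variable, "chi2", summaries, float(p))

    a = values[group_labels == groups[0]].astype(float)
    b = values[group_labels == groups[1]].astype(float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 observations")

    def is_normal(x: np.ndarray) -> bool:
        if len(x) < 3 or np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue > ALPHA_NORMALITY

    normal = is_normal(a) and is_normal(b)
    if normal:
        p = float(sps.ttest_ind(a, b).pvalue)
        test = "t"
        summaries = {
            str(groups[0]): {"mean": float(a.mean()), "sd": float(a.std(ddof=1))},
            str(groups[1]): {"mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        }
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        test = "mann_whitney"

        def med_iqr(x):
            return {
                "median": float(np.median(x)),
                "q1": float(np.percentile(x, 25)),
                "q3": float(np.percentile(x, 75)),
            }

        summaries = {str(groups[0]): med_iqr(a), str(groups[1]): med_iqr(b)}
    return GroupComparison(variable, test, summaries, p)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Product-moment by default; pass ``method="spearman"`` for the rank
    variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------
@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    youden_cutoff: float
    youden_index: float


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative scores."""

    def midrank(x: np.ndarray) -> np.ndarray:
        return sps.rankdata(x, method="average")

    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    tx = midrank(pos)
    ty = midrank(neg)
    tz = midrank(allv)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_youden(values, labels) -> RocResult:
    """Empirical ROC over all observed thresholds, AUC with DeLong 95 % CI,
    and the Youden-optimal cut-off (ties broken toward higher specificity,
    i.e. the higher threshold).

    A value >= threshold is called positive.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be present")

    pos = values[labels]
    neg = values[~labels]
    thresholds = np.unique(values)
    # candidate cuts: each observed value plus one above the maximum
    cuts = np.concatenate([thresholds, [thresholds[-1] + 1.0]])
    sens = np.array([(pos >= c).mean() for c in cuts])
    spec = np.array([(neg < c).mean() for c in cuts])

    auc, var = _delong_auc_variance(pos, neg)
    se = np.sqrt(var)
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    j = sens + spec - 1.0
    best = j.max()
    # ties toward higher specificity = higher cutoff
    idx = int(np.flatnonzero(np.isclose(j, best))[-1])
    return RocResult(
        thresholds=cuts,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_95=ci,
        youden_cutoff=float(cuts[idx]),
        youden_index=float(best),
    )


def binormal_auc(mu_neg: float, sd_neg: float, mu_pos: float, sd_pos: float) -> float:
    """Closed-form AUC of two Gaussian classes: Phi(dmu / sqrt(s1^2+s2^2))."""
    return float(sps.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_neg, sd_pos)))


# ---------------------------------------------------------------------------
# diagnostic performance
# ---------------------------------------------------------------------------
@dataclass
class DiagnosticPerformance:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    inv_lr_neg: float
    prevalence: float


def diagnostic_performance(
    sensitivity: float, specificity: float, prevalence: float
) -> DiagnosticPerformance:
    """Predictive values and likelihood ratios from sens/spec and prevalence.

    lr_pos = sens/(1-spec); inv_lr_neg = spec/(1-sens); PPV and NPV by
    Bayes' rule at the given prevalence. Degenerate ratios are flagged
    infinite.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ParameterError(f"{name} must be in [0, 1]")
    if not 0 < prevalence < 1:
        raise ParameterError("prevalence must be in (0, 1)")
    sens, spec, prev = sensitivity, specificity, prevalence
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    inv_lr_neg = spec / (1 - sens) if sens < 1 else float("inf")
    ppv_den = sens * prev + (1 - spec) * (1 - prev)
    npv_den = (1 - sens) * prev + spec * (1 - prev)
    ppv = sens * prev / ppv_den if ppv_den > 0 else float("nan")
    npv = spec * (1 - prev) / npv_den if npv_den > 0 else float("nan")
    return DiagnosticPerformance(sens, spec, ppv, npv, lr_pos, inv_lr_neg, prev)


def diagnostic_performance_at_cutoff(
    values, labels, cutoff: float, prevalence: float | None = None
) -> DiagnosticPerformance:
    """Empirical sens/spec at a cut-off (>= cutoff positive), then the
    formula path at the sample prevalence unless one is supplied."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be present")
    sens = float((values[labels] >= cutoff).mean())
    spec = float((values[~labels] < cutoff).mean())
    prev = float(labels.mean()) if prevalence is None else prevalence
    return diagnostic_performance(sens, spec, prev)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------
@dataclass
class RegressionTable:
    """Univariable scan plus stepwise multivariable model."""

    univariable: pd.DataFrame  # index covariate; columns r_squared, p_value
    retained: pd.DataFrame  # index covariate; columns coef, t, p_value
    global_r2: float
    excluded_collinear: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def univariable_scan(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Simple linear regression of the outcome on each covariate.

    Returns a DataFrame with per-covariate R² and two-sided p; constant
    covariates are flagged with NaN.
    """
    if outcome not in table.columns:
        raise InputError(f"outcome {outcome!r} not in table")
    y = table[outcome].astype(float)
    rows = {}
    for cov in table.columns:
        if cov == outcome:
            continue
        x = table[cov].astype(float)
        if x.nunique() <= 1:
            rows[cov] = {"r_squared": np.nan, "p_value": np.nan, "note": "constant"}
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows[cov] = {
            "r_squared": float(model.rsquared),
            "p_value": float(model.pvalues.iloc[1]),
            "note": "",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def stepwise_multivariable(
    table: pd.DataFrame,
    outcome: str,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    collinearity_r: float = 0.7,
) -> RegressionTable:
    """Forward stepwise linear regression with collinearity screening.

    Candidates are covariates with univariable p < ``entry_p``. Collinear
    pairs (|Pearson r| >= ``collinearity_r``) are resolved before entry by
    keeping the member with the smaller univariable p (the exclusion is
    logged with its partner). Forward steps add the best remaining candidate
    whose coefficient p < ``entry_p``; after each addition, members with
    p >= ``removal_p`` are removed.
    """
    uni = univariable_scan(table, outcome)
    y = table[outcome].astype(float)
    notes: list[str] = []

    candidates = [c for c in uni.index if uni.loc[c, "p_value"] < entry_p]
    excluded: list[tuple[str, str]] = []
    if candidates:
        # collinearity screen among candidates, worse univariable p loses
        ordered = sorted(candidates, key=lambda c: uni.loc[c, "p_value"])
        corr = table[candidates].astype(float).corr().abs()
        kept: list[str] = []
        for c in ordered:
            partner = next(
                (k for k in kept if corr.loc[c, k] >= collinearity_r), None
            )
            if partner is None:
                kept.append(c)
            else:
                excluded.append((c, partner))
        # restore column order for deterministic tie handling
        candidates = [c for c in uni.index if c in kept]

    included: list[str] = []
    removed_last: str | None = None
    for _ in range(100):
        remaining = [c for c in candidates if c not in included and c != removed_last]
        best, best_p = None, entry_p
        for c in remaining:
            X = sm.add_constant(table[included + [c]].astype(float))
            fit = sm.OLS(y, X).fit()
            p = float(fit.pvalues[c])
            if p < best_p:
                best, best_p = c, p
        if best is None:
            break
        included.append(best)
        removed_last = None
        # backward removal pass
        while included:
            X = sm.add_constant(table[included].astype(float))
            fit = sm.OLS(y, X).fit()
            pvals = fit.pvalues[included]
            worst = pvals.idxmax()
            if float(pvals[worst]) >= removal_p:
                included.remove(worst)
                removed_last = worst
                notes.append(f"{worst} removed (p={float(pvals[worst]):.3f})")
            else:
                break

    if included:
        X = sm.add_constant(table[included].astype(float))
        fit = sm.OLS(y, X).fit()
        retained = pd.DataFrame(
            {
                "coef": fit.params[included].astype(float),
                "t": fit.tvalues[included].astype(float),
                "p_value": fit.pvalues[included].astype(float),
            }
        )
        global_r2 = float(fit.rsquared)
    else:
        retained = pd.DataFrame(columns=["coef", "t", "p_value"])
        global_r2 = 0.0
        notes.append("empty model: no candidate passed the entry threshold")

    return RegressionTable(
        univariable=uni,
        retained=retained,
        global_r2=global_r2,
        excluded_collinear=excluded,
        notes=notes,
    )
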