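"""Model comparison and evaluation statistics.

A binary rule and a continuous classifier are compared like-for-like by
measuring the continuous model's *sensitivity at the fixed specificity* the
rule achieves.  Supporting machinery: exact (Clopper–Pearson) binomial
confidence intervals, rank-based AUC, weak-calibration assessment
(intercept ``a``, slope ``b_L``, and a 2-df likelihood-ratio unreliability
test), variable importance, inter-rater kappa, and descriptive cohort
tables with between-split tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

from .featurize import impute_symptom_type_median


@dataclass
class MetricEstimate:
    """A point estimate with its confidence interval and CI method."""
    metric: str
    point: float
    ci_low: float
    ci_high: float
    method: str            # exact_binomial | bootstrap_percentile | cv_mean_se
    n_effective: int


class SensitivityAtSpecificity(NamedTuple):
    sensitivity: float
    threshold: float
    specificity: float      # specificity actually attained at the threshold
    degenerate: bool        # True when only the everything-negative cut qualifies


def sensitivity_at_specificity(scores, labels, target_specificity: float
                               ) -> SensitivityAtSpecificity:
    """Sensitivity of ``score >= threshold`` at the smallest threshold whose
    specificity reaches the target.

    No interpolation between attainable operating points: the continuous
    model is only credited with thresholds it can actually realize.  The
    all-negative cut (threshold above every score, specificity 1) is always
    a candidate, so any target ≤ 1 is attainable; when it is the *only*
    qualifying cut the result is flagged degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pos, neg = scores[labels == 1], scores[labels == 0]
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    for t in thresholds:  # ascending: smallest qualifying cut wins
        spec = np.mean(neg < t)
        if spec >= target_specificity:
            sens = float(np.mean(pos >= t)) if np.isfinite(t) else 0.0
            return SensitivityAtSpecificity(
                sens, float(t), float(spec), not np.isfinite(t))
    raise AssertionError("unreachable: infinite threshold has specificity 1")


def exact_binomial_ci(successes: int, n: int, level: float = 0.95
                      ) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval from beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else stats.beta.ppf(
        alpha / 2, successes, n - successes + 1)
    high = 1.0 if successes == n else stats.beta.ppf(
        1 - alpha / 2, successes + 1, n - successes)
    return float(low), float(high)


def round_ci_percent(low: float, high: float) -> tuple[int, int]:
    """Round CI bounds to whole percent for reporting (e.g. 96–100%)."""
    return int(round(low * 100)), int(round(high * 100))


def auc(scores, labels) -> float:
    """Rank-based AUC (concordance probability); ties count one half."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CalibrationReport:
    """Weak-calibration summary: intercept a, slope b_L, 2-df unreliability
    test, and a LOESS-smoothed observed-vs-predicted curve for plotting."""
    intercept_a: float
    slope_bL: float
    unreliability_stat: float
    unreliability_df: int
    unreliability_p: float
    curve: pd.DataFrame   # columns: predicted, observed (smoothed)


def calibration_assess(probabilities, labels, smoother_span: float = 0.75,
                       eps: float = 1e-6) -> CalibrationReport:
    """Assess weak calibration of predicted probabilities.

    Outcomes are refit on the logit of the prediction,
    ``logit P(y=1) = a + b_L * logit(p̂)``; perfect weak calibration is
    (a, b_L) = (0, 1).  The unreliability statistic is the likelihood-ratio
    chi-square comparing this 2-parameter recalibration to the fixed
    (0, 1) model, on 2 degrees of freedom.  The LOESS curve is returned for
    plotting only and plays no part in the test.
    """
    import statsmodels.api as sm

    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1 - eps)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    logit_p = np.log(p / (1 - p))
    if np.allclose(logit_p, logit_p[0]):
        raise ValueError("degenerate probabilities: slope undefined")

    X = sm.add_constant(logit_p)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    a, b = float(fit.params[0]), float(fit.params[1])

    # log-likelihood of the fixed (a=0, b=1) model is just the likelihood of
    # the stated probabilities themselves
    ll_fixed = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    lr = max(0.0, 2.0 * (float(fit.llf) - ll_fixed))
    p_value = float(stats.chi2.sf(lr, df=2))

    smooth = sm.nonparametric.lowess(y, p, frac=smoother_span)
    curve = pd.DataFrame(smooth, columns=["predicted", "observed"])
    return CalibrationReport(a, b, lr, 2, p_value, curve)


def variable_importance(model, X: pd.DataFrame, y=None,
                        method: str = "standardized_coefficient",
                        seed: int = 0, n_repeats: int = 10) -> pd.DataFrame:
    """Feature importance table for a fitted model.

    ``standardized_coefficient`` reads the penalized-logistic coefficients on
    the standardized-predictor scale (zero-variance columns are exactly 0);
    ``permutation`` measures the mean AUC drop when one column is permuted,
    on the data supplied (held-out preferred).
    """
    if method == "standardized_coefficient":
        coef = getattr(model, "coef_std_", None)
        if coef is None:
            raise ValueError(
                "standardized coefficients are only defined for the "
                "penalized logistic models")
        table = pd.DataFrame({"feature": list(X.columns),
                              "importance": np.asarray(coef, dtype=float)})
    elif method == "permutation":
        if y is None:
            raise ValueError("permutation importance needs labels")
        result = permutation_importance(
            model, X, np.asarray(y).astype(int), scoring="roc_auc",
            n_repeats=n_repeats, random_state=seed)
        table = pd.DataFrame({"feature": list(X.columns),
                              "importance": result.importances_mean})
    else:
        raise ValueError(f"unknown importance method {method!r}")
    table["method"] = method
    return table.sort_values("importance", key=np.abs, ascending=False,
                             kind="stable").reset_index(drop=True)


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two raters: (p_o − p_e) / (1 − p_e)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    categories = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in categories:
        p_e += np.mean(a == c) * np.mean(b == c)
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def fisher_exact_rxc(table: np.ndarray, n_sim: int = 20000,
                     seed: int = 0) -> float:
    """Fisher exact p-value for an r×c contingency table.

    2×2 tables use the exact hypergeometric test; larger tables use a seeded
    Monte-Carlo estimate: sample tables with the observed margins and count
    those whose multivariate-hypergeometric probability does not exceed the
    observed table's (the construction behind R's simulated Fisher p).
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)

    from scipy.special import gammaln

    def table_logp(t):
        return (gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
                - gammaln(table.sum() + 1) - gammaln(t + 1).sum())

    obs_logp = table_logp(table)
    # sample fixed-margin tables by permuting individual column labels
    labels = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    tol = 1e-9
    for _ in range(n_sim):
        rng.shuffle(labels)
        t = np.zeros_like(table)
        start = 0
        for i, r in enumerate(row_m):
            seg = labels[start:start + r]
            t[i] = np.bincount(seg, minlength=len(col_m))
            start += r
        if table_logp(t) <= obs_logp + tol:
            hits += 1
    return float((hits + 1) / (n_sim + 1))


def descriptive_table(cohort: pd.DataFrame, truth: pd.DataFrame,
                      seed: int = 0) -> pd.DataFrame:
    """Characteristics of the cohort by train/test split with between-split
    tests: two-sample t-test for age, Fisher exact for categorical rows.
    Symptom type is median-imputed (descriptively only) before tabulation."""
    df = cohort.merge(truth, on="participant_id")
    splits = [s for s in ("train", "test") if (df["split"] == s).any()]
    single = len(splits) < 2
    rows = []

    def fmt_n_pct(mask, split):
        sub = df[df["split"] == split]
        k = int(mask[df["split"] == split].sum())
        return f"{k} ({100 * k / len(sub):.1f}%)" if len(sub) else "0"

    rows.append({"variable": "N",
                 **{s: str(int((df['split'] == s).sum())) for s in splits},
                 "p_value": np.nan})

    age = {s: df.loc[df["split"] == s, "age"].astype(float) for s in splits}
    p_age = np.nan
    if not single:
        p_age = float(stats.ttest_ind(age["train"], age["test"]).pvalue)
    rows.append({"variable": "Age - mean (SD)",
                 **{s: f"{age[s].mean():.1f} ({age[s].std(ddof=1):.1f})"
                    for s in splits},
                 "p_value": p_age})

    for label, mask in [("Female - N (%)", df["sex"] == "F"),
                        ("In metro - N (%)", df["in_metro"].astype(bool))]:
        p = np.nan
        if not single:
            tab = pd.crosstab(df["split"], mask).reindex(["train", "test"])
            p = fisher_exact_rxc(tab.to_numpy(), seed=seed)
        rows.append({"variable": label,
                     **{s: fmt_n_pct(mask, s) for s in splits}, "p_value": p})

    stype = impute_symptom_type_median(df["symptom_type"])
    tab = pd.crosstab(df["split"], stype)
    p_stype = np.nan
    if not single:
        p_stype = fisher_exact_rxc(
            tab.reindex(["train", "test"]).to_numpy(), seed=seed)
    rows.append({"variable": "Symptom type - N (%)", "p_value": p_stype,
                 **{s: "" for s in splits}})
    for t in [c for c in ("asymptomatic", "retinal", "TIA", "stroke")
              if c in tab.columns]:
        rows.append({"variable": f"  {t}",
                     **{s: fmt_n_pct(stype == t, s) for s in splits},
                     "p_value": np.nan})
    out = pd.DataFrame(rows)
    if single:
        out.attrs["note"] = "single split: between-split tests omitted"
    return out


def power_exclude_sensitivity(n_cases: int, true_sensitivity: float,
                              comparison: float, level: float = 0.95) -> float:
    """Probability that the exact CI for observed sensitivity excludes (lies
    entirely above) a comparison value, given the true sensitivity.

    Sums the binomial probability of every case count whose Clopper–Pearson
    lower bound exceeds the comparison sensitivity.
    """
    power = 0.0
    for x in range(n_cases + 1):
        low, _ = exact_binomial_ci(x, n_cases, level)
        if low > comparison:
            power += float(stats.binom.pmf(x, n_cases, true_sensitivity))
    return power
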