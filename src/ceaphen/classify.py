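"""The five-model ladder for symptomatic-status classification.

Ordered by increasing complexity:

1. ``Rule_DX`` — the current-state method: symptomatic iff the index
   discharge abstract carries a symptomatic-cluster diagnosis coded as a
   most-responsible or preadmit diagnosis type (no parameters, binary
   output);
2. ``Logistic_HOSP`` — elastic-net logistic regression on hospital
   discharge variables only;
3. ``Logistic_DX`` — adds physician-claims diagnosis features;
4. ``Logistic_ALL`` — adds claimed-service features;
5. ``Forest_ALL`` — random forest on all variables.

Learned models follow a 4-step workflow: (1) hyperparameter tuning by
repeated stratified cross-validation on the training split (10-fold,
3-repeat, mean held-out AUC); (2) performance assessment by 10-fold
10-repeat cross-validation (mean ± SE over the 100 fold estimates);
(3) a final fit on the complete training split; (4) test-split evaluation by
2000 bootstrap resamples (percentile CIs).  The hyperparameter *search
strategy* is pluggable — the contract fixes only the resampling scheme and
selection criterion — and defaults to seeded random search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .admindata import SYMPTOMATIC_CLUSTERS, default_cluster_map, parse_diagnoses
from .evaluate import MetricEstimate, auc

DX_TYPE_POLICY_DEFAULT = ("most_responsible", "preadmit")


def rule_classify(diagnoses, dx_type_policy=DX_TYPE_POLICY_DEFAULT) -> str:
    """Classify one index abstract by discharge diagnosis alone.

    Symptomatic iff any diagnosis maps to a symptomatic cluster (ischemic
    stroke, TIA, retinal, cerebral) *and* its diagnosis type passes the
    policy.  An event coded only as a secondary diagnosis — the scheduled
    re-admission pattern — is invisible to the rule, which is precisely why
    it is insensitive.
    """
    if isinstance(diagnoses, str):
        diagnoses = parse_diagnoses(diagnoses)
    cmap = default_cluster_map()
    for code, dx_type in diagnoses:
        if dx_type in dx_type_policy and cmap.icd10(code) in SYMPTOMATIC_CLUSTERS:
            return "symptomatic"
    return "asymptomatic"


class DischargeRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier over the HOSP feature columns.

    Operates on a feature matrix whose ``hosp_<cluster>`` indicators were
    built under the same diagnosis-type policy as :func:`rule_classify`;
    predicts 1 (symptomatic) iff any symptomatic-cluster indicator fires.
    ``fit`` only records the class labels (there is nothing to learn).
    """

    _rule_columns = tuple(f"hosp_{c}" for c in sorted(SYMPTOMATIC_CLUSTERS))

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _flags(self, X: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self._rule_columns if c in X.columns]
        if not cols:
            raise ValueError("feature matrix lacks hosp_<cluster> columns")
        return (X[cols].to_numpy() > 0).any(axis=1).astype(int)

    def predict(self, X):
        check_is_fitted(self)
        return self._flags(X)

    def predict_proba(self, X):
        pred = self.predict(X)
        return np.column_stack([1 - pred, pred]).astype(float)


class ElasticNetLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Elastic-net penalized logistic regression with glmnet-style parameters.

    ``mixture`` in [0, 1] is the L1 proportion of the combined penalty
    (0 = ridge, 1 = lasso) and ``penalty`` (λ > 0) its overall strength on
    the mean-log-likelihood scale, translated internally to sklearn's
    ``C = 1 / (n·λ)``.  Predictors are standardized internally (the glmnet
    convention); ``coef_std_`` exposes coefficients on that standardized
    scale for variable-importance reporting, zero-variance columns pinned
    to exactly 0.
    """

    def __init__(self, mixture: float = 0.5, penalty: float = 0.01,
                 max_iter: int = 5000, tol: float = 1e-6):
        self.mixture = mixture
        self.penalty = penalty
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if not 0.0 <= self.mixture <= 1.0:
            raise ValueError("mixture must be in [0, 1]")
        if self.penalty <= 0:
            raise ValueError("penalty must be > 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required to fit")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._nonconst = sd > 0
        self._sd = np.where(self._nonconst, sd, 1.0)
        Z = (X - self._mu) / self._sd
        C = 1.0 / (len(y) * self.penalty)
        self._lr = LogisticRegression(
            solver="saga", l1_ratio=self.mixture, C=C,
            max_iter=self.max_iter, tol=self.tol, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._lr.fit(Z[:, self._nonconst], y)
        coef = np.zeros(X.shape[1])
        coef[self._nonconst] = self._lr.coef_[0]
        self.coef_std_ = coef

        # polish the (unpenalized) intercept by 1-D Newton at fixed slopes:
        # a no-op at a converged joint optimum, but saga can stall on the
        # intercept when the penalty is extreme
        b0 = float(self._lr.intercept_[0])
        eta_fixed = Z @ coef
        y1 = (y == self.classes_[1]).astype(float)
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(eta_fixed + b0)))
            g = float(np.mean(p - y1))
            h = float(np.mean(p * (1 - p)))
            if h < 1e-12 or abs(g) < 1e-12:
                break
            b0 -= g / h

        self.coef_ = coef / self._sd
        self.intercept_ = float(b0 - np.sum(self.coef_ * self._mu))
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class SymptomaticForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with the tuning surface used here: number of candidate
    variables per split (working range 2–20), minimum node size, and number
    of trees.  Probabilities are plain ensemble vote/leaf-frequency averages
    (no out-of-bag scoring: evaluation happens on a held-out year)."""

    def __init__(self, candidates_per_split: int = 5, min_node_size: int = 5,
                 n_trees: int = 500, seed: int = 0):
        self.candidates_per_split = int(candidates_per_split)
        self.min_node_size = int(min_node_size)
        self.n_trees = int(n_trees)
        self.seed = seed

    def fit(self, X, y):
        p = X.shape[1]
        if not 1 <= self.candidates_per_split <= p:
            raise ValueError(
                f"candidates_per_split={self.candidates_per_split} outside [1, {p}]")
        if not 2 <= self.candidates_per_split <= 20:
            warnings.warn("candidates_per_split outside the working range [2, 20]")
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.candidates_per_split,
            min_samples_leaf=self.min_node_size, random_state=self.seed)
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        self.classes_ = self._rf.classes_
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_rf")
        return self._rf.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self._rf.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Model ladder specification


@dataclass
class ModelSpec:
    name: str
    feature_set: str            # HOSP | DX | ALL | discharge-rule
    family: str                 # rule | elastic_net | random_forest
    hyper_ranges: dict = field(default_factory=dict)

    def make(self, seed: int = 0, **hypers):
        if self.family == "rule":
            return DischargeRuleClassifier()
        if self.family == "elastic_net":
            return ElasticNetLogisticClassifier(**hypers)
        if self.family == "random_forest":
            return SymptomaticForestClassifier(seed=seed, **hypers)
        raise ValueError(f"unknown family {self.family!r}")


_EN_RANGES = {"mixture": (0.0, 1.0), "log10_penalty": (-4.0, 0.0)}
_RF_RANGES = {"candidates_per_split": (2, 20), "min_node_size": (1, 20),
              "n_trees": (200, 800)}

MODEL_LADDER = [
    ModelSpec("Rule_DX", "discharge-rule", "rule"),
    ModelSpec("Logistic_HOSP", "HOSP", "elastic_net", dict(_EN_RANGES)),
    ModelSpec("Logistic_DX", "DX", "elastic_net", dict(_EN_RANGES)),
    ModelSpec("Logistic_ALL", "ALL", "elastic_net", dict(_EN_RANGES)),
    ModelSpec("Forest_ALL", "ALL", "random_forest", dict(_RF_RANGES)),
]


def sample_candidates(spec: ModelSpec, n_candidates: int,
                      rng: np.random.Generator,
                      n_features: int | None = None) -> list[dict]:
    """Seeded random-search candidates within the spec's hyperparameter ranges."""
    out = []
    for _ in range(n_candidates):
        if spec.family == "elastic_net":
            lo, hi = spec.hyper_ranges["log10_penalty"]
            out.append({
                "mixture": float(rng.uniform(*spec.hyper_ranges["mixture"])),
                "penalty": float(10.0 ** rng.uniform(lo, hi)),
            })
        elif spec.family == "random_forest":
            c_lo, c_hi = spec.hyper_ranges["candidates_per_split"]
            if n_features is not None:
                c_hi = min(c_hi, n_features)
            out.append({
                "candidates_per_split": int(rng.integers(c_lo, c_hi + 1)),
                "min_node_size": int(rng.integers(
                    spec.hyper_ranges["min_node_size"][0],
                    spec.hyper_ranges["min_node_size"][1] + 1)),
                "n_trees": int(rng.integers(
                    spec.hyper_ranges["n_trees"][0],
                    spec.hyper_ranges["n_trees"][1] + 1)),
            })
        else:
            raise ValueError("rule model has no hyperparameters to sample")
    return out


def fit_elastic_net(X, y, mixture: float, penalty: float
                    ) -> ElasticNetLogisticClassifier:
    return ElasticNetLogisticClassifier(mixture=mixture, penalty=penalty).fit(X, y)


def fit_random_forest(X, y, candidates_per_split: int, min_node_size: int,
                      n_trees: int, seed: int = 0) -> SymptomaticForestClassifier:
    return SymptomaticForestClassifier(
        candidates_per_split=candidates_per_split, min_node_size=min_node_size,
        n_trees=n_trees, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# Tune / assess / bootstrap workflow


def _scores(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(1)]


def _cv_fold_metrics(estimator, X, y, folds, repeats, seed, metrics):
    """Per-held-out-fold metric values over a repeated stratified K-fold."""
    X = X.reset_index(drop=True) if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} participants for {folds}-fold CV")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    values = {name: [] for name in metrics}
    skipped = 0
    for tr, te in cv.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            skipped += 1
            continue
        model = clone(estimator).fit(X.iloc[tr], y[tr])
        s = _scores(model, X.iloc[te])
        for name, fn in metrics.items():
            values[name].append(fn(s, y[te]))
    if skipped:
        warnings.warn(f"{skipped} single-class folds skipped")
    return {k: np.asarray(v) for k, v in values.items()}, skipped


def tune(spec: ModelSpec, X, y, candidates: list[dict] | None = None,
         folds: int = 10, repeats: int = 3, seed: int = 0,
         n_candidates: int = 10, metric=auc) -> dict:
    """Choose the hyperparameter combination maximizing mean held-out AUC
    over a repeated stratified K-fold grid (seeded and deterministic)."""
    if spec.family == "rule":
        return {}
    rng = np.random.default_rng(seed)
    if candidates is None:
        candidates = sample_candidates(spec, n_candidates, rng, X.shape[1])
    if len(candidates) == 1:
        return dict(candidates[0])
    best, best_score = None, -np.inf
    for cand in candidates:
        est = spec.make(seed=seed, **cand)
        vals, _ = _cv_fold_metrics(est, X, y, folds, repeats, seed,
                                   {"m": metric})
        score = float(np.mean(vals["m"])) if len(vals["m"]) else -np.inf
        if score > best_score:
            best, best_score = dict(cand), score
    return best


def assess_cv(spec: ModelSpec, hypers: dict, X, y, folds: int = 10,
              repeats: int = 10, seed: int = 0,
              metrics: dict | None = None) -> dict[str, MetricEstimate]:
    """Cross-validated performance: mean and standard error over the
    folds×repeats held-out fold estimates, reported as mean ± 1.96·SE."""
    metrics = metrics or {"auc": auc}
    est = spec.make(seed=seed, **hypers)
    vals, skipped = _cv_fold_metrics(est, X, y, folds, repeats, seed, metrics)
    out = {}
    for name, arr in vals.items():
        if len(arr) == 0:
            raise ValueError(f"no usable folds for metric {name}")
        mean = float(np.mean(arr))
        se = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out[name] = MetricEstimate(name, mean, mean - 1.96 * se,
                                   mean + 1.96 * se, "cv_mean_se", len(arr))
    return out


def bootstrap_test_eval(model, X_test, y_test, B: int = 2000, seed: int = 0,
                        metrics: dict | None = None,
                        max_redraws: int = 100) -> dict[str, MetricEstimate]:
    """Test-split evaluation by bootstrap: point estimate on the full test
    set, empirical 95% CI from the 2.5th/97.5th percentiles of B resampled
    metric values.  Single-class resamples are redrawn (and counted)."""
    metrics = metrics or {"auc": auc}
    y = np.asarray(y_test).astype(int)
    if len(y) == 0:
        raise ValueError("empty test set")
    X = (X_test.reset_index(drop=True) if isinstance(X_test, pd.DataFrame)
         else pd.DataFrame(X_test))
    s_full = _scores(model, X)
    rng = np.random.default_rng(seed)
    boot = {name: np.empty(B) for name in metrics}
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) > 1:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        for name, fn in metrics.items():
            boot[name][b] = fn(s_full[idx], y[idx])
    out = {}
    for name, fn in metrics.items():
        point = float(fn(s_full, y))
        lo, hi = np.percentile(boot[name], [2.5, 97.5])
        out[name] = MetricEstimate(name, point, float(lo), float(hi),
                                   "bootstrap_percentile", len(y))
        out[name].n_redraws = redraws
    return out
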