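"""End-to-end orchestration: simulate → prepare → featurize → train → report.

A :class:`RunConfig` fully determines a run: generator parameters, feature
configuration, the model list, resampling settings, bootstrap size, and one
seed per stage (so stages can be re-run independently).  ``run_pipeline``
executes the stages in order into a run directory, logging the resolved
configuration and writing a manifest with checksums of every output file;
the same config re-executes to byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admindata, classify, evaluate, featurize, synthdata
from .evaluate import auc, sensitivity_at_specificity

log = logging.getLogger("ceaphen")

LEARNED_MODELS = ("Logistic_HOSP", "Logistic_DX", "Logistic_ALL", "Forest_ALL")
ALL_MODELS = ("Rule_DX",) + LEARNED_MODELS
#: models that need physician-claims tables
CLAIMS_MODELS = ("Logistic_DX", "Logistic_ALL", "Forest_ALL")


@dataclass
class RunConfig:
    generator: synthdata.GeneratorParams = field(
        default_factory=synthdata.GeneratorParams)
    models: tuple[str, ...] = ALL_MODELS
    include_claims: bool = True
    tune_candidates: int = 8
    tune_folds: int = 10
    tune_repeats: int = 3
    assess_folds: int = 10
    assess_repeats: int = 10
    bootstrap_B: int = 2000
    seeds: dict = field(default_factory=lambda: {
        "simulate": 0, "tune": 1, "assess": 2, "bootstrap": 3, "importance": 4})
    out_dir: str = "ceaphen_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("generator"), dict):
            d["generator"] = synthdata.GeneratorParams(**d["generator"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def smoke(cls, n: int = 50, seed: int = 0, out_dir: str = "ceaphen_smoke"
              ) -> "RunConfig":
        """A small configuration for end-to-end smoke runs."""
        return cls(
            generator=synthdata.GeneratorParams(n_participants=n, seed=seed),
            tune_candidates=2, tune_folds=5, tune_repeats=1,
            assess_folds=5, assess_repeats=2, bootstrap_B=100,
            seeds={k: seed + i for i, k in enumerate(
                ("simulate", "tune", "assess", "bootstrap", "importance"))},
            out_dir=out_dir)


def _estimate_row(model: str, split: str, est) -> dict:
    return {"model": model, "split": split, "metric": est.metric,
            "point": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "method": est.method, "n": est.n_effective}


def prepare_tables(truth, participants, discharges, claims, test_year: int):
    """Cohort assembly plus the standard claim preparation: window trim,
    de-duplication, 3-character ICD-9 truncation."""
    cohort = admindata.assemble_cohort(
        discharges, test_year=test_year, participants=participants)
    index_dates = cohort.set_index("participant_id")["index_date"]
    claims = claims[claims["participant_id"].isin(cohort["participant_id"])]
    claims = admindata.trim_window(claims, index_dates)
    claims = admindata.dedupe_claims(claims)
    claims = claims.assign(icd9_raw=claims["icd9_raw"].map(admindata.truncate_icd9))
    return cohort, claims


def train_and_evaluate(fm: pd.DataFrame, config: RunConfig,
                       feature_config: featurize.FeatureConfig | None = None):
    """Run the model ladder on a prepared feature matrix.

    Returns (performance table, calibration table, importance table,
    rule summary dict, fitted models dict).  The rule's specificity on the
    combined splits sets the matched-specificity margin for every
    continuous model, mirroring the like-to-like comparison design.
    """
    sets = featurize.feature_sets(fm.columns, feature_config)
    y_all = fm["label"].to_numpy()
    train_mask = (fm["split"] == "train").to_numpy()
    specs = {s.name: s for s in classify.MODEL_LADDER}

    requested = [m for m in config.models if m in specs]
    skipped = []
    if not config.include_claims:
        skipped = [m for m in requested if m in CLAIMS_MODELS]
        for m in skipped:
            log.warning("model %s skipped: claims tables excluded by config", m)
        requested = [m for m in requested if m not in CLAIMS_MODELS]

    # --- rule-based classification (combined splits, as a fixed rule) -----
    rule = classify.DischargeRuleClassifier().fit(fm, y_all)
    rule_pred = rule.predict(fm)
    tp = int(np.sum((rule_pred == 1) & (y_all == 1)))
    fn = int(np.sum((rule_pred == 0) & (y_all == 1)))
    tn = int(np.sum((rule_pred == 0) & (y_all == 0)))
    fp = int(np.sum((rule_pred == 1) & (y_all == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    sens_ci = evaluate.exact_binomial_ci(tp, tp + fn) if tp + fn else (np.nan,) * 2
    spec_ci = evaluate.exact_binomial_ci(tn, tn + fp) if tn + fp else (np.nan,) * 2
    rule_summary = {
        "sensitivity": sens, "sensitivity_ci": sens_ci, "n_cases": tp + fn,
        "specificity": spec, "specificity_ci": spec_ci, "n_controls": tn + fp,
    }
    target_spec = spec

    perf_rows = [
        _estimate_row("Rule_DX", "combined", evaluate.MetricEstimate(
            "sensitivity", sens, *sens_ci, "exact_binomial", tp + fn)),
        _estimate_row("Rule_DX", "combined", evaluate.MetricEstimate(
            "specificity", spec, *spec_ci, "exact_binomial", tn + fp)),
    ]

    def sens_at_matched(s, y):
        return sensitivity_at_specificity(s, y, target_spec).sensitivity

    metrics = {"auc": auc, "sens_at_matched_spec": sens_at_matched}

    calib_rows, imp_rows, fitted = [], [], {"Rule_DX": rule}
    X_te = fm.loc[~train_mask]
    y_te = y_all[~train_mask]
    for name in requested:
        if name == "Rule_DX":
            continue
        spec_ = specs[name]
        cols = sets[spec_.feature_set]
        X_tr = fm.loc[train_mask, cols]
        y_tr = y_all[train_mask]
        t0 = time.perf_counter()
        hypers = classify.tune(
            spec_, X_tr, y_tr, folds=config.tune_folds,
            repeats=config.tune_repeats, seed=config.seeds["tune"],
            n_candidates=config.tune_candidates)
        cv = classify.assess_cv(
            spec_, hypers, X_tr, y_tr, folds=config.assess_folds,
            repeats=config.assess_repeats, seed=config.seeds["assess"],
            metrics=metrics)
        model = spec_.make(seed=config.seeds["assess"], **hypers).fit(X_tr, y_tr)
        boot = classify.bootstrap_test_eval(
            model, X_te[cols], y_te, B=config.bootstrap_B,
            seed=config.seeds["bootstrap"], metrics=metrics)
        log.info("model %s: hypers=%s (%.1fs)", name, hypers,
                 time.perf_counter() - t0)

        fitted[name] = model
        for mname, est in cv.items():
            perf_rows.append(_estimate_row(name, "train_cv", est))
        for mname, est in boot.items():
            perf_rows.append(_estimate_row(name, "test_bootstrap", est))

        p_test = model.predict_proba(X_te[cols])[:, 1]
        try:
            cal = evaluate.calibration_assess(p_test, y_te)
            calib_rows.append({
                "model": name, "intercept_a": cal.intercept_a,
                "slope_bL": cal.slope_bL,
                "unreliability_stat": cal.unreliability_stat,
                "unreliability_df": cal.unreliability_df,
                "unreliability_p": cal.unreliability_p})
        except ValueError as err:
            log.warning("calibration for %s not assessable: %s", name, err)

        if spec_.family == "elastic_net":
            imp = evaluate.variable_importance(
                model, fm.loc[train_mask, cols], method="standardized_coefficient")
        else:
            imp = evaluate.variable_importance(
                model, X_te[cols], y_te, method="permutation",
                seed=config.seeds["importance"])
        imp["model"] = name
        imp_rows.append(imp)

    performance = pd.DataFrame(perf_rows)
    calibration = pd.DataFrame(calib_rows)
    importance = (pd.concat(imp_rows, ignore_index=True)
                  if imp_rows else pd.DataFrame())
    rule_summary["skipped_models"] = skipped
    return performance, calibration, importance, rule_summary, fitted


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir``; returns the path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        config.save(out / "config.yaml")
        gen = dataclasses.replace(config.generator,
                                  seed=config.seeds["simulate"])

        t0 = time.perf_counter()
        truth, participants, discharges, claims = synthdata.generate_dataset(gen)
        admindata.write_tables(out / "tables", {
            "participants": participants, "truth": truth,
            "discharges": discharges, "claims": claims})
        timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        cohort, claims_prep = prepare_tables(
            truth, participants, discharges, claims, gen.test_year)
        admindata.write_tables(out / "tables", {"cohort": cohort})
        fm = featurize.build_feature_matrix(cohort, discharges, claims_prep, truth)
        fm.to_csv(out / "features.csv")
        sets = featurize.feature_sets(fm.columns)
        (out / "feature_sets.json").write_text(json.dumps(sets, indent=2))
        timings["featurize"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        performance, calibration, importance, rule_summary, _ = \
            train_and_evaluate(fm, config)
        timings["train_evaluate"] = time.perf_counter() - t0

        performance.to_csv(out / "performance.csv", index=False)
        calibration.to_csv(out / "calibration.csv", index=False)
        importance.to_csv(out / "importance.csv", index=False)
        desc = evaluate.descriptive_table(cohort, truth,
                                          seed=config.seeds["simulate"])
        desc.to_csv(out / "descriptive.csv", index=False)
        (out / "rule_summary.json").write_text(
            json.dumps(rule_summary, indent=2, default=float))

        manifest = {}
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name not in ("manifest.json", "run.log"):
                manifest[str(f.relative_to(out))] = hashlib.sha256(
                    f.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("run complete; stage wall times: %s",
                 {k: f"{v:.1f}s" for k, v in timings.items()})
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
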