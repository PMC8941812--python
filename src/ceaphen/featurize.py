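"""Engineer participant-level features from claims and discharge abstracts.

Physician claims are many-to-one (many service lines per participant) and
are collapsed to one analytic row per participant by a 4-step workflow:

1. **clustering** — map each claim to diagnosis events (via the ICD-9
   cluster map, split by provider specialty) and/or service events (via the
   fee-item category map);
2. **reduction** — drop conceptual duplicates, e.g. the same diagnosis by
   the same provider type on different days, keeping the occurrence nearest
   to surgery;
3. **weighting** — value each event by its recency relative to the index
   surgery (exponential decay by default);
4. **summarizing** — collapse each participant's events into one row, taking
   the maximum weight for diagnosis features (presence strength) and the sum
   of weights for service features (weighted volume).

Discharge-abstract variables (demographics, admission category, diagnosis
cluster indicators) form the HOSP predictor set; adding claim diagnoses
gives DX; adding claimed services gives ALL.  The sets are nested by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .admindata import (CLUSTERS, SYMPTOM_TYPE_ORDER, default_cluster_map,
                        parse_diagnoses, truncate_icd9)

EVENT_COLUMNS = ["participant_id", "kind", "category", "specialty_flag",
                 "days_before_index", "weight"]


def load_fee_categories(path: str | Path | None = None) -> dict[str, str]:
    """Load the fee-item -> service-category map (a labelled reconstruction)."""
    if path is None:
        text = (resources.files("ceaphen.data") / "fee_items.tsv").read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fee, category = line.split()
        out[fee] = category
    return out


@dataclass
class FeatureConfig:
    """Declarative configuration of the claims feature workflow.

    ``specialty_flags`` lists the specialties split out as their own flag on
    diagnosis features; everything else collapses to "other".  Service
    categories listed in ``service_reduce`` are reduced like diagnoses
    (single best event); categories absent from it keep every event so the
    summary can count weighted volume.
    """

    half_life_days: float = 90.0
    weight_scheme: str = "exponential"   # exponential | linear | step
    specialty_flags: tuple[str, ...] = ("neurologist",)
    fee_categories: dict[str, str] = field(default_factory=load_fee_categories)
    service_reduce: dict[str, bool] = field(default_factory=dict)
    diagnosis_summary: str = "max"
    service_summary: str = "sum"
    dx_type_policy: tuple[str, ...] = ("most_responsible", "preadmit")

    @property
    def service_categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.fee_categories.values())))


def weight_event(days_before_index, half_life_days: float = 90.0,
                 scheme: str = "exponential"):
    """Recency weight of an event ``days_before_index`` days before surgery.

    Exponential (default): ``2**(-max(d, 0)/half_life)``, so a claim on the
    day of surgery weighs 1 and one 90 days earlier weighs 0.5.  Post-op
    claims (negative days, inside the 7-day tail) weigh 1.  ``linear`` and
    ``step`` are provided as alternatives; all are monotonically
    non-increasing in days and bounded in (0, 1].
    """
    d = np.maximum(np.asarray(days_before_index, dtype=float), 0.0)
    if scheme == "exponential":
        w = np.power(2.0, -d / half_life_days)
    elif scheme == "linear":
        w = np.maximum(1.0 - d / 184.0, 1.0 / 184.0)
    elif scheme == "step":
        w = np.where(d <= 30, 1.0, np.where(d <= 90, 0.5, 0.25))
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w if w.ndim else float(w)


def cluster_claims(claims: pd.DataFrame, index_dates: pd.Series,
                   config: FeatureConfig | None = None) -> pd.DataFrame:
    """Step 1+3: map claims to weighted diagnosis/service events.

    Each claim yields up to two events: a diagnosis event when its truncated
    ICD-9 code hits a cluster (flagged by provider specialty), and a service
    event when its fee item matches a category.  Unmatched claims yield no
    events.  Weights are attached here so reduction can keep the
    nearest-to-surgery occurrence.
    """
    config = config or FeatureConfig()
    cmap = default_cluster_map()
    if claims.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    idx = pd.to_datetime(claims["participant_id"].map(index_dates))
    days = (idx - pd.to_datetime(claims["service_date"])).dt.days

    rows = []
    for (pid, icd9, fee, specialty, d) in zip(
            claims["participant_id"], claims["icd9_raw"], claims["fee_item"],
            claims["specialty"], days):
        d = int(d)
        cluster = cmap.icd9(truncate_icd9(icd9))
        if cluster is not None:
            flag = specialty if specialty in config.specialty_flags else "other"
            rows.append((pid, "diagnosis", cluster, flag, d))
        category = config.fee_categories.get(str(fee))
        if category is not None:
            rows.append((pid, "service", category, "", d))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS[:-1])
    events["weight"] = weight_event(events["days_before_index"],
                                    config.half_life_days, config.weight_scheme)
    return events


def reduce_events(events: pd.DataFrame,
                  config: FeatureConfig | None = None) -> pd.DataFrame:
    """Step 2: collapse conceptual duplicates to the highest-weight event.

    Diagnosis events sharing (participant, category, specialty flag) reduce
    to the single occurrence nearest to surgery (maximum weight).  Service
    events reduce the same way only for categories configured ``reduce=True``;
    otherwise every occurrence is retained so the summary can sum them.
    """
    config = config or FeatureConfig()
    if events.empty:
        return events.copy()
    key = ["participant_id", "kind", "category", "specialty_flag"]
    reduce_svc = events["category"].map(
        lambda c: bool(config.service_reduce.get(c, False)))
    reducible = (events["kind"] == "diagnosis") | reduce_svc
    to_reduce = events.loc[reducible]
    kept = events.loc[~reducible]
    if len(to_reduce):
        best = to_reduce.loc[to_reduce.groupby(key, sort=False)["weight"].idxmax()]
    else:
        best = to_reduce
    out = pd.concat([best, kept]).sort_index().reset_index(drop=True)
    return out


def claim_feature_columns(config: FeatureConfig) -> tuple[list[str], list[str]]:
    """Column names of the claim-diagnosis (DX) and service (ALL) features."""
    flags = list(config.specialty_flags) + ["other"]
    dx_cols = [f"dx_{cluster}_{flag}" for cluster in CLUSTERS for flag in flags]
    svc_cols = [f"svc_{cat}" for cat in config.service_categories]
    return dx_cols, svc_cols


def summarize_participants(events: pd.DataFrame, participant_ids,
                           config: FeatureConfig | None = None) -> pd.DataFrame:
    """Step 4: one row per participant; max weight for diagnoses, summed
    weights for services.  Participants with no events get all-zero rows
    (absence of a code is informative, not missing)."""
    config = config or FeatureConfig()
    dx_cols, svc_cols = claim_feature_columns(config)
    out = pd.DataFrame(0.0, index=pd.Index(participant_ids, name="participant_id"),
                       columns=dx_cols + svc_cols)
    if events.empty:
        return out

    dx = events.loc[events["kind"] == "diagnosis"]
    agg = config.diagnosis_summary
    for (pid, cat, flag), grp in dx.groupby(
            ["participant_id", "category", "specialty_flag"], sort=False):
        col = f"dx_{cat}_{flag}"
        if pid in out.index and col in out.columns:
            out.loc[pid, col] = grp["weight"].max() if agg == "max" else grp["weight"].sum()

    svc = events.loc[events["kind"] == "service"]
    agg = config.service_summary
    for (pid, cat), grp in svc.groupby(["participant_id", "category"], sort=False):
        col = f"svc_{cat}"
        if pid in out.index and col in out.columns:
            out.loc[pid, col] = grp["weight"].sum() if agg == "sum" else grp["weight"].max()
    return out


def build_discharge_features(cohort: pd.DataFrame, abstracts: pd.DataFrame,
                             config: FeatureConfig | None = None) -> pd.DataFrame:
    """HOSP predictor set: demographics, admission category one-hot, and one
    binary indicator per diagnosis cluster on the index abstract.

    The cluster indicators honour the same diagnosis-type policy as the
    rule-based classifier (most-responsible or preadmit by default), so the
    simplest learned model sees exactly the information the rule sees plus
    demographics and admission route.
    """
    config = config or FeatureConfig()
    cmap = default_cluster_map()

    # index abstract = abstract at the participant's index admission date
    merged = cohort.merge(
        abstracts, on="participant_id", how="left", suffixes=("", "_abs"))
    merged = merged.loc[
        pd.to_datetime(merged["admit_date"]) == pd.to_datetime(merged["index_date"])]
    merged = merged.drop_duplicates("participant_id", keep="first")
    missing = set(cohort["participant_id"]) - set(merged["participant_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} cohort participants lack an index abstract")

    merged = merged.set_index("participant_id").loc[cohort["participant_id"]]
    out = pd.DataFrame(index=merged.index)
    out["age"] = merged["age"].astype(float)
    out["sex_female"] = (merged["sex"] == "F").astype(float)
    out["in_metro"] = merged["in_metro"].astype(float)
    for cat in ("emergent", "urgent", "elective"):
        out[f"adm_{cat}"] = (merged["admission_category"] == cat).astype(float)
    for cluster in CLUSTERS:
        out[f"hosp_{cluster}"] = 0.0
    for pid, cell in merged["diagnoses"].items():
        for code, dx_type in parse_diagnoses(cell):
            if dx_type not in config.dx_type_policy:
                continue
            cluster = cmap.icd10(code)
            if cluster is not None:
                out.loc[pid, f"hosp_{cluster}"] = 1.0
    return out


def build_feature_matrix(cohort: pd.DataFrame, abstracts: pd.DataFrame,
                         claims: pd.DataFrame, truth: pd.DataFrame | None = None,
                         config: FeatureConfig | None = None,
                         standardize_age: bool = True) -> pd.DataFrame:
    """Assemble the full participant × feature matrix with split and label.

    Claims must already be trimmed and de-duplicated.  Age is standardized
    to zero mean / unit variance using *training-split* moments only, so the
    held-out year never leaks into the scaling.  Predictor columns contain
    no missing values: an unobserved code is a structural zero.
    """
    config = config or FeatureConfig()
    hosp = build_discharge_features(cohort, abstracts, config)
    index_dates = cohort.set_index("participant_id")["index_date"]
    events = reduce_events(
        cluster_claims(claims, index_dates, config), config)
    claim_feats = summarize_participants(events, cohort["participant_id"], config)

    fm = hosp.join(claim_feats)
    fm["split"] = cohort.set_index("participant_id")["split"]
    if truth is not None:
        status = truth.set_index("participant_id")["true_status"]
        fm["label"] = (status.reindex(fm.index) == "symptomatic").astype(int)
    if standardize_age:
        train_age = fm.loc[fm["split"] == "train", "age"]
        mu, sd = train_age.mean(), train_age.std(ddof=0)
        fm["age"] = (fm["age"] - mu) / (sd if sd > 0 else 1.0)
    assert not fm.drop(columns=["split"]).isna().any().any(), \
        "predictor columns must have no missing values"
    return fm


def feature_sets(fm_columns, config: FeatureConfig | None = None) -> dict[str, list[str]]:
    """The three nested predictor sets: HOSP ⊂ DX ⊂ ALL."""
    config = config or FeatureConfig()
    cols = list(fm_columns)
    hosp = [c for c in cols if c in ("age", "sex_female", "in_metro")
            or c.startswith("adm_") or c.startswith("hosp_")]
    dx_extra = [c for c in cols if c.startswith("dx_")]
    svc_extra = [c for c in cols if c.startswith("svc_")]
    return {"HOSP": hosp, "DX": hosp + dx_extra, "ALL": hosp + dx_extra + svc_extra}


def impute_symptom_type_median(values: pd.Series) -> pd.Series:
    """Median-impute missing symptom types on the ordinal scale
    asymptomatic < retinal < TIA < stroke (lower median on ties).

    Used only for descriptive reporting — predictors cannot be missing.
    """
    codes = values.map({t: i for i, t in enumerate(SYMPTOM_TYPE_ORDER)})
    observed = codes.dropna()
    if observed.empty:
        raise ValueError("cannot impute: all symptom types missing")
    ranked = np.sort(observed.to_numpy())
    median_code = int(ranked[(len(ranked) - 1) // 2])  # lower median on ties
    out = values.copy()
    out[codes.isna()] = SYMPTOM_TYPE_ORDER[median_code]
    return out


class ClaimsFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper over the 4-step claims workflow.

    ``fit`` records the participant order and training-split age moments;
    ``transform`` runs clustering → reduction → weighting → summarizing and
    returns the assembled feature matrix.  Kept sklearn-compatible so the
    workflow composes with pipelines and model selection.
    """

    def __init__(self, config: FeatureConfig | None = None,
                 standardize_age: bool = True):
        self.config = config
        self.standardize_age = standardize_age

    def fit(self, cohort: pd.DataFrame, y=None):
        self.config_ = self.config or FeatureConfig()
        self.participants_ = list(cohort["participant_id"])
        return self

    def transform(self, tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
        return build_feature_matrix(
            tables["cohort"], tables["discharges"], tables["claims"],
            tables.get("truth"), self.config_ if hasattr(self, "config_")
            else self.config, self.standardize_age)
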