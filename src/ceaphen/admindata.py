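"""Data model and preparation for linked hospital-discharge and physician-claims tables.

The package works with four flat tables (participants, truth, discharge
abstracts, physician claims), carried in memory as :class:`pandas.DataFrame`
objects and on disk as CSV with ISO-8601 dates.  This module provides the
readers/writers, cohort assembly from carotid-endarterectomy (CEA)
intervention codes, the pre-surgery event-window trim, claim de-duplication,
ICD code normalization, and the diagnosis-cluster maps that group ICD-10-CA
and 3-character ICD-9 codes into the five clinical concepts used throughout:
ischemic stroke, TIA, retinal ischemia, cerebral symptoms, and (asymptomatic)
carotid stenosis.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Canadian Classification of Interventions codes identifying a carotid
#: endarterectomy, stored dot-stripped ("1.JE.57" -> "1JE57").
CEA_CCI_CODES = frozenset({"1JE57", "1JE50", "1JE87"})

#: The five diagnosis clusters; the first four indicate a symptomatic event.
CLUSTERS = ("ischemic_stroke", "tia", "retinal", "cerebral", "stenosis")
SYMPTOMATIC_CLUSTERS = frozenset({"ischemic_stroke", "tia", "retinal", "cerebral"})

DX_TYPES = ("most_responsible", "preadmit", "secondary")
ADMISSION_CATEGORIES = ("emergent", "urgent", "elective")

#: Ordinal coding of symptom type used for descriptive median imputation.
SYMPTOM_TYPE_ORDER = ("asymptomatic", "retinal", "TIA", "stroke")

CLAIM_KEY = ["participant_id", "service_date", "icd9_raw", "fee_item", "specialty"]


def normalize_code(code: str) -> str:
    """Normalize an ICD or CCI code: strip dots and whitespace, upper-case."""
    return str(code).replace(".", "").strip().upper()


def truncate_icd9(code: str) -> str:
    """Truncate an ICD-9 diagnosis code to its first 3 significant characters.

    The code is dot-stripped first, so ``"435.9" -> "435"`` and
    ``"362.34" -> "362"``.  V- and E-prefixed codes keep their prefix inside
    the 3 retained characters.  A code shorter than 3 characters after
    stripping is returned unchanged with a warning.
    """
    stripped = normalize_code(code)
    if not stripped:
        raise ValueError("empty ICD-9 code")
    if len(stripped) < 3:
        warnings.warn(f"ICD-9 code {code!r} shorter than 3 characters; left unchanged")
        return stripped
    return stripped[:3]


class ClusterMap:
    """Diagnosis-cluster maps loaded from plain-text mapping files.

    ICD-10-CA rules are prefix rules with longest-prefix-wins semantics, so a
    specific rule (``G453 -> retinal``) overrides a general one
    (``G45 -> tia``) and an explicit ``none`` carves out an exclusion
    (``I636``).  ICD-9 rules are exact matches on truncated 3-character codes.
    Passing alternate files swaps in jurisdictional variants.
    """

    def __init__(self, icd10_path: str | Path | None = None,
                 icd9_path: str | Path | None = None):
        self.icd10_rules = self._load(icd10_path, "icd10_clusters.tsv")
        self.icd9_rules = self._load(icd9_path, "icd9_clusters.tsv")
        self._validate()

    @staticmethod
    def _load(path, default_name):
        if path is None:
            text = (resources.files("ceaphen.data") / default_name).read_text()
        else:
            text = Path(path).read_text()
        rules: dict[str, str | None] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pattern, cluster = line.split()
            pattern = normalize_code(pattern)
            if pattern in rules:
                raise ValueError(f"duplicate pattern {pattern!r} in cluster map")
            rules[pattern] = None if cluster == "none" else cluster
        return rules

    def _validate(self):
        for rules in (self.icd10_rules, self.icd9_rules):
            for pattern, cluster in rules.items():
                if cluster is not None and cluster not in CLUSTERS:
                    raise ValueError(f"unknown cluster {cluster!r} for {pattern!r}")

    def icd10(self, code: str) -> str | None:
        """Map an ICD-10-CA code to its cluster, or None when unclustered."""
        code = normalize_code(code)
        best = None
        best_len = -1
        for pattern, cluster in self.icd10_rules.items():
            if code.startswith(pattern) and len(pattern) > best_len:
                best, best_len = cluster, len(pattern)
        return best

    def icd9(self, code: str) -> str | None:
        """Map a truncated 3-character ICD-9 code to its cluster, or None."""
        return self.icd9_rules.get(normalize_code(code))


_DEFAULT_MAP: ClusterMap | None = None


def default_cluster_map() -> ClusterMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = ClusterMap()
    return _DEFAULT_MAP


def map_icd10_cluster(code: str) -> str | None:
    return default_cluster_map().icd10(code)


def map_icd9_cluster(code: str) -> str | None:
    return default_cluster_map().icd9(code)


# ---------------------------------------------------------------------------
# Diagnosis / intervention list serialization
#
# A discharge abstract carries a *list* of typed diagnoses; the flat table
# stores it in one cell as "CODE|dx_type;CODE|dx_type" and interventions as
# "CODE;CODE", keeping the tables plain delimited text that round-trips
# exactly.

def format_diagnoses(diagnoses: list[tuple[str, str]]) -> str:
    parts = []
    for code, dx_type in diagnoses:
        if dx_type not in DX_TYPES:
            raise ValueError(f"unknown dx_type {dx_type!r}")
        parts.append(f"{normalize_code(code)}|{dx_type}")
    return ";".join(parts)


def parse_diagnoses(cell: str) -> list[tuple[str, str]]:
    if not isinstance(cell, str) or not cell:
        return []
    out = []
    for part in cell.split(";"):
        code, dx_type = part.split("|")
        out.append((code, dx_type))
    return out


def format_interventions(codes: list[str]) -> str:
    return ";".join(normalize_code(c) for c in codes)


def parse_interventions(cell: str) -> list[str]:
    if not isinstance(cell, str) or not cell:
        return []
    return cell.split(";")


# ---------------------------------------------------------------------------
# Cohort assembly and data preparation


def assemble_cohort(abstracts: pd.DataFrame,
                    cea_codes: frozenset[str] | set[str] = CEA_CCI_CODES,
                    test_year: int | None = None,
                    participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the one-row-per-participant cohort table from discharge abstracts.

    A participant enters the cohort if any abstract lists a CEA intervention
    code; the index procedure is the *earliest* qualifying admission
    (ties broken by discharge date, then record order).  ``split`` is "test"
    exactly when the index year equals ``test_year``, mirroring a final-year
    holdout.  Demographics are merged in from ``participants`` when given.
    """
    cea_codes = {normalize_code(c) for c in cea_codes}
    has_cea = abstracts["interventions"].map(
        lambda cell: any(c in cea_codes for c in parse_interventions(cell)))
    qualifying = abstracts.loc[has_cea].copy()
    if qualifying.empty:
        warnings.warn("no abstracts carry a CEA intervention code; empty cohort")
        cohort = pd.DataFrame(columns=["participant_id", "index_date",
                                       "index_year", "split"])
        return cohort

    qualifying["_order"] = np.arange(len(qualifying))
    qualifying = qualifying.sort_values(
        ["participant_id", "admit_date", "discharge_date", "_order"],
        kind="stable")
    index_rows = qualifying.groupby("participant_id", as_index=False).first()

    cohort = pd.DataFrame({
        "participant_id": index_rows["participant_id"],
        "index_date": pd.to_datetime(index_rows["admit_date"]),
    })
    cohort["index_year"] = cohort["index_date"].dt.year
    if test_year is None:
        test_year = int(cohort["index_year"].max())
    cohort["split"] = np.where(cohort["index_year"] == test_year, "test", "train")
    if participants is not None:
        cohort = cohort.merge(participants, on="participant_id", how="left")
    return cohort.reset_index(drop=True)


def trim_window(events: pd.DataFrame,
                index_dates: pd.Series | pd.Timestamp | str,
                date_col: str = "service_date",
                pre_days: int = 183,
                post_days: int = 7,
                closed_lower: bool = True,
                closed_upper: bool = True) -> pd.DataFrame:
    """Keep events inside the pre-surgery window around each index date.

    The window is ``[index - pre_days, index + post_days]``, closed on both
    ends by default (both boundaries configurable).  Six months is encoded as
    183 days; the 7-day post-procedure tail guards against claim-date error.
    ``index_dates`` is either a single date applied to all events or a Series
    indexed by participant_id.
    """
    if events.empty:
        return events.copy()
    dates = pd.to_datetime(events[date_col])
    if isinstance(index_dates, pd.Series):
        idx = events["participant_id"].map(index_dates)
        idx = pd.to_datetime(idx)
    else:
        idx = pd.Series(pd.to_datetime(index_dates), index=events.index)
    delta = (dates - idx).dt.days
    lo, hi = -pre_days, post_days
    keep = (delta >= lo) if closed_lower else (delta > lo)
    keep &= (delta <= hi) if closed_upper else (delta < hi)
    return events.loc[keep.fillna(False)].reset_index(drop=True)


def dedupe_claims(claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate claim lines produced by billing adjudication.

    Rows identical on (participant, service date, diagnosis, fee item,
    specialty) collapse to one; the adjudication sequence number is ignored
    in the key, keeping the first-seen row.
    """
    if claims.empty:
        return claims.copy()
    return (claims.drop_duplicates(subset=CLAIM_KEY, keep="first")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Table IO

TABLE_NAMES = ("participants", "truth", "discharges", "claims")
_DATE_COLS = {
    "discharges": ["admit_date", "discharge_date"],
    "claims": ["service_date"],
    "cohort": ["index_date"],
}
# columns that must survive as strings (fee items carry leading zeros)
_STR_COLS = ("participant_id", "fee_item", "icd9_raw", "specialty")


def write_tables(out_dir: str | Path, tables: dict[str, pd.DataFrame],
                 schema: bool = True) -> None:
    """Write tables as CSV (ISO-8601 dates) plus a JSON schema sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df = df.copy()
        for col in _DATE_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(out_dir / f"{name}.csv", index=False)
    if schema:
        desc = {
            name: {col: str(dtype) for col, dtype in df.dtypes.items()}
            for name, df in tables.items()
        }
        desc["_conventions"] = {
            "dates": "ISO-8601 (YYYY-MM-DD)",
            "claims": "one row per claim line; duplicates carry distinct adjudication_seq",
            "discharges.diagnoses": "semicolon list of CODE|dx_type",
            "discharges.interventions": "semicolon list of CCI codes, dot-stripped",
        }
        (out_dir / "schema.json").write_text(json.dumps(desc, indent=2))


def read_tables(in_dir: str | Path,
                names: tuple[str, ...] = TABLE_NAMES) -> dict[str, pd.DataFrame]:
    in_dir = Path(in_dir)
    out = {}
    for name in names:
        df = pd.read_csv(in_dir / f"{name}.csv",
                         dtype={c: str for c in _STR_COLS})
        for col in _DATE_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        out[name] = df
    return out
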