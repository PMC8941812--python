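"""Synthetic linked administrative data with a known symptomatic status.

The real study data — hospital discharge abstracts and physician claims
linked at the participant level — are restricted, so every downstream stage
is exercised on synthetic tables that emulate their structure: a latent
symptomatic status drives both the discharge coding (through the admission
route) and the claims pattern in the six months before surgery.

The generative mechanism mirrors how Canadian discharge coding loses the
symptomatic signal: a symptomatic participant admitted *emergently* for the
event and operated on during the same stay carries the event diagnosis as a
most-responsible or preadmit diagnosis type, and is therefore visible to a
discharge-code rule; a symptomatic participant re-admitted *electively* for
scheduled surgery after the event is coded for carotid stenosis only, and
the event is visible only in physician claims (neurologist stroke/TIA
diagnoses, head-CT fee items, symptom codes near the event day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .admindata import format_diagnoses, format_interventions

#: CEA intervention codes, dot-stripped, sampled uniformly for index abstracts.
_CEA_CODES = ("1JE57", "1JE50", "1JE87")

#: Symptom-type mix among symptomatic participants (retinal / TIA / stroke),
#: matching the observed cohort mix (~26% / 46% / 28% of symptomatic cases).
_SYMPTOM_TYPES = ("retinal", "TIA", "stroke")
_SYMPTOM_TYPE_P = (0.26, 0.465, 0.275)

#: Event diagnosis codes by symptom type: ICD-10-CA for discharge abstracts,
#: raw (pre-truncation) ICD-9 for physician claims.
_EVENT_ICD10 = {
    "stroke": ("I634", "I635", "I639", "I64"),
    "TIA": ("G458", "G459"),
    "retinal": ("G453", "H340", "H531"),
}
_EVENT_ICD9 = {
    "stroke": ("434.9", "436"),
    "TIA": ("435.9",),
    "retinal": ("362.3", "368.1"),
}

#: Background (noise) claim dictionary: decoy diagnoses — including 784,
#: which looks neurological but is deliberately unclustered — and routine
#: fee items.  One head-CT and one neurology-consult decoy keep the service
#: signal imperfect in the asymptomatic class.
_NOISE_ICD9 = ("784.0", "4019", "25000", "7862", "V4581", "729.5")
_NOISE_FEES = ("00100", "00101", "00108", "00730", "00731")
_HEADCT_FEE = "08610"
_CAROTID_IMG_FEES = ("08620", "08625")
_NEURO_CONSULT_FEE = "00510"


@dataclass
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Probabilities are all in [0, 1].  ``p_emergent_given_sympt`` and
    ``p_mrdx_event_given_emergent`` control how often the symptomatic event
    surfaces in discharge coding; their product is the asymptotic sensitivity
    of the discharge-code rule (plus ``p_elective_event_code``, default 0).
    """

    n_participants: int = 1000
    asympt_fraction: float = 0.30
    p_emergent_given_sympt: float = 0.33
    p_mrdx_event_given_emergent: float = 0.95
    p_elective_event_code: float = 0.0
    p_event_code_given_asympt: float = 0.0
    p_neurologist_dx_given_sympt: float = 0.60
    p_nonneuro_dx_given_sympt: float = 0.50
    p_headct_given_sympt: float = 0.70
    p_symptom_claim_given_sympt: float = 0.40
    p_headct_background: float = 0.04
    p_neuro_visit_background: float = 0.05
    background_noise_rate: float = 6.0
    duplicate_rate: float = 0.10
    missing_symptom_type_rate: float = 0.01
    event_day_distribution: str = "uniform"
    index_year_range: tuple[int, int] = (2008, 2016)
    test_year: int = 2016
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("asympt_fraction", "p_emergent_given_sympt",
                     "p_mrdx_event_given_emergent", "p_elective_event_code",
                     "p_event_code_given_asympt", "p_neurologist_dx_given_sympt",
                     "p_nonneuro_dx_given_sympt", "p_headct_given_sympt",
                     "p_symptom_claim_given_sympt", "p_headct_background",
                     "p_neuro_visit_background", "duplicate_rate",
                     "missing_symptom_type_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.background_noise_rate < 0:
            raise ValueError("background_noise_rate must be >= 0")
        if self.event_day_distribution not in ("uniform",):
            raise ValueError(
                f"unknown event_day_distribution {self.event_day_distribution!r}")
        self.index_year_range = tuple(self.index_year_range)

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_event_day(rng: np.random.Generator, params: GeneratorParams) -> int:
    # days before surgery; six months encoded as 183 days
    return int(rng.integers(0, 184))


def generate_dataset(params: GeneratorParams):
    """Generate the four linked tables: truth, participants, discharges, claims.

    Every participant gets exactly one index discharge abstract carrying a
    CEA intervention code.  Output is deterministic in (params, seed): the
    same parameters produce byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    ids = [f"P{i:06d}" for i in range(n)]

    # --- participants -----------------------------------------------------
    age = np.clip(np.round(rng.normal(72.0, 9.3, n)), 45, 95).astype(int)
    sex = np.where(rng.random(n) < 0.33, "F", "M")
    in_metro = rng.random(n) < 0.78
    y0, y1 = params.index_year_range
    index_year = rng.integers(y0, y1 + 1, n)
    # index date: a day within the index year (leap days avoided)
    doy = rng.integers(0, 365, n)
    index_date = pd.to_datetime(
        [f"{y}-01-01" for y in index_year]) + pd.to_timedelta(doy, unit="D")

    participants = pd.DataFrame({
        "participant_id": ids, "age": age, "sex": sex, "in_metro": in_metro,
    })

    # --- latent truth -----------------------------------------------------
    symptomatic = rng.random(n) >= params.asympt_fraction
    p_types = np.asarray(_SYMPTOM_TYPE_P) / np.sum(_SYMPTOM_TYPE_P)
    type_draw = rng.choice(len(_SYMPTOM_TYPES), size=n, p=p_types)
    symptom_type = np.where(
        symptomatic, np.asarray(_SYMPTOM_TYPES)[type_draw], "asymptomatic")
    event_day = np.array([_sample_event_day(rng, params) for _ in range(n)])
    missing_mask = rng.random(n) < params.missing_symptom_type_rate

    truth = pd.DataFrame({
        "participant_id": ids,
        "true_status": np.where(symptomatic, "symptomatic", "asymptomatic"),
        "symptom_type": symptom_type,
        "event_day": np.where(symptomatic, event_day.astype(float), np.nan),
    })
    truth.loc[missing_mask, "symptom_type"] = np.nan

    # --- discharge abstracts ---------------------------------------------
    disc_rows = []
    claim_rows = []
    for i in range(n):
        pid = ids[i]
        idx = index_date[i]
        sympt = bool(symptomatic[i])
        stype = symptom_type[i] if sympt else None
        e_day = int(event_day[i]) if sympt else None

        diagnoses = []
        if sympt and rng.random() < params.p_emergent_given_sympt:
            adm = "emergent"
            los = int(rng.integers(5, 15))
            if rng.random() < params.p_mrdx_event_given_emergent:
                code = _EVENT_ICD10[stype][rng.integers(len(_EVENT_ICD10[stype]))]
                dx_type = "most_responsible" if rng.random() < 0.7 else "preadmit"
                diagnoses.append((code, dx_type))
                diagnoses.append(("I652", "secondary"))
            else:
                diagnoses.append(("I652", "most_responsible"))
        else:
            adm = "urgent" if rng.random() < 0.10 else "elective"
            los = int(rng.integers(2, 6))
            leak_p = (params.p_elective_event_code if sympt
                      else params.p_event_code_given_asympt)
            if rng.random() < leak_p:
                pool = _EVENT_ICD10[stype or "TIA"]
                diagnoses.append((pool[rng.integers(len(pool))], "preadmit"))
            diagnoses.append(("I652", "most_responsible"))
        if rng.random() < 0.5:
            diagnoses.append(("I10", "secondary"))  # comorbidity filler

        disc_rows.append({
            "participant_id": pid,
            "admit_date": idx,
            "discharge_date": idx + pd.Timedelta(days=los),
            "admission_category": adm,
            "diagnoses": format_diagnoses(diagnoses),
            "interventions": format_interventions(
                [_CEA_CODES[rng.integers(len(_CEA_CODES))]]),
        })

        # --- physician claims for this participant -----------------------
        def add_claim(days_before, icd9, fee, specialty):
            claim_rows.append({
                "participant_id": pid,
                "service_date": idx - pd.Timedelta(days=int(days_before)),
                "icd9_raw": icd9,
                "fee_item": fee,
                "specialty": specialty,
                "adjudication_seq": 0,
            })

        # carotid-stenosis workup: everyone is being evaluated for surgery
        for _ in range(1 + int(rng.poisson(1.5))):
            add_claim(rng.integers(0, 151), "433.1",
                      _CAROTID_IMG_FEES[rng.integers(2)], "other")
        # background noise
        for _ in range(int(rng.poisson(params.background_noise_rate))):
            add_claim(rng.integers(-7, 184),
                      _NOISE_ICD9[rng.integers(len(_NOISE_ICD9))],
                      _NOISE_FEES[rng.integers(len(_NOISE_FEES))], "gp")
        if rng.random() < params.p_headct_background:
            add_claim(rng.integers(0, 184), "784.0", _HEADCT_FEE, "radiologist")
        if rng.random() < params.p_neuro_visit_background:
            add_claim(rng.integers(0, 184), "354.0", _NEURO_CONSULT_FEE,
                      "neurologist")

        if sympt:
            def near_event():
                # services trail the event by a few days, never past +7 post-op
                return max(e_day - int(rng.integers(0, 4)), -7)

            icd9_pool = _EVENT_ICD9[stype]
            if rng.random() < params.p_neurologist_dx_given_sympt:
                add_claim(near_event(), icd9_pool[rng.integers(len(icd9_pool))],
                          _NEURO_CONSULT_FEE, "neurologist")
            if rng.random() < params.p_nonneuro_dx_given_sympt:
                add_claim(near_event(), icd9_pool[rng.integers(len(icd9_pool))],
                          _NOISE_FEES[rng.integers(len(_NOISE_FEES))], "gp")
            if rng.random() < params.p_headct_given_sympt:
                add_claim(near_event(), "784.0", _HEADCT_FEE, "radiologist")
            if rng.random() < params.p_symptom_claim_given_sympt:
                add_claim(near_event(), "781.0",
                          _NOISE_FEES[rng.integers(len(_NOISE_FEES))], "gp")

    discharges = pd.DataFrame(disc_rows)
    claims = pd.DataFrame(claim_rows)

    # duplicate claim lines from billing adjudication: exact copies with a
    # distinct adjudication sequence number
    if len(claims) and params.duplicate_rate > 0:
        dup_mask = rng.random(len(claims)) < params.duplicate_rate
        dups = claims.loc[dup_mask].copy()
        dups["adjudication_seq"] = 1
        claims = (pd.concat([claims, dups], ignore_index=True)
                  .sort_values(["participant_id", "service_date", "fee_item",
                                "adjudication_seq"], kind="stable")
                  .reset_index(drop=True))

    return truth, participants, discharges, claims


def truth_prevalence(truth: pd.DataFrame) -> pd.Series:
    """Proportion of participants by symptom type (missing counted as 'missing')."""
    if truth.empty:
        raise ValueError("empty truth table")
    counts = truth["symptom_type"].fillna("missing").value_counts()
    return counts / counts.sum()
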