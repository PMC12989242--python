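"""Incident-cancer cohort construction from ICD-10 claims events.

Builds the analysis population: finds incident diagnoses (first cancer code
with a 24-month washout), fixes each patient's cancer group and hospital
from the first code, applies the exclusion cascade (adults only, hospitals
under a 1% share of diagnoses, sex/site mismatches, patients without any
report), windows the documents to −90/+365 days of the index code, and
derives the metastatic-at-diagnosis and one-year-mortality outcomes.

Conventions (explicit and tested): the washout interval is the open
interval (index − 730 d, index); document and mortality windows are
inclusive at both bounds; the metastatic window is [index, index + 90 d];
group assignment never looks at codes after the first one.
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionLog",
    "CohortParams",
    "is_cancer_code",
    "map_code_to_group",
    "find_incident_cases",
    "assign_group_hospital",
    "window_documents",
    "derive_outcomes",
    "apply_exclusions",
    "build_cohort",
]

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,2})?$")

#: (letter, low, high) inclusive ICD-10 ranges per primary-site group,
#: checked in order; C77-C79 are secondary neoplasms, never a primary group.
_GROUP_RANGES: list[tuple[str, int, int, str]] = [
    ("C", 50, 50, "Breast"),
    ("C", 18, 21, "Colorectal"),
    ("C", 33, 34, "Lung"),
    ("C", 61, 61, "Prostate"),
    ("C", 51, 58, "Gynaecological"),
    ("C", 60, 60, "Genitourinary"),
    ("C", 62, 68, "Genitourinary"),
    ("C", 43, 44, "Skin"),
    ("C", 81, 96, "Haematological"),
    ("C", 15, 17, "OtherGI"),
    ("C", 22, 26, "OtherGI"),
]

METASTASIS_PREFIXES = ("C77", "C78", "C79")


@dataclass
class CohortParams:
    washout_days: int = 730
    window_before: int = 90
    window_after: int = 365
    metastatic_window: int = 90
    hospital_min_share: float = 0.01
    paediatric_hospitals: tuple[str, ...] = ()
    metastasis_prefixes: tuple[str, ...] = METASTASIS_PREFIXES
    include_in_situ: bool = False  # add D00-D09, D37-D48 to the cancer set
    study_start: dt.date | None = dt.date(2019, 1, 1)
    study_end: dt.date | None = dt.date(2021, 6, 1)


@dataclass
class ExclusionLog:
    """Ordered record of the exclusion cascade."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("n_remaining must decrease monotonically")
        self.steps.append((name, n_removed, n_remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed", "n_remaining"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _code_number(code: str) -> int:
    return int(code[1:3])


def is_cancer_code(code: str, include_in_situ: bool = False) -> bool:
    """True for primary/secondary malignancy codes C00-C97 (optionally the
    in-situ and uncertain-behaviour D00-D09 / D37-D48 blocks)."""
    code = code.strip().upper()
    if not _ICD10_RE.match(code):
        return False
    num = _code_number(code)
    if code[0] == "C":
        return num <= 97
    if include_in_situ and code[0] == "D":
        return 0 <= num <= 9 or 37 <= num <= 48
    return False


def map_code_to_group(code: str) -> str:
    """Primary-site group of an ICD-10 cancer code (fallback: Other)."""
    code = code.strip().upper()
    if not _ICD10_RE.match(code):
        return "Other"
    num = _code_number(code)
    for letter, lo, hi, group in _GROUP_RANGES:
        if code[0] == letter and lo <= num <= hi:
            return group
    return "Other"


def _prepare_events(events: pd.DataFrame, params: CohortParams) -> pd.DataFrame:
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.date
    ev["_is_cancer"] = [is_cancer_code(c, params.include_in_situ) for c in ev["code"]]
    ev["_event_order"] = np.arange(len(ev))
    return ev


def find_incident_cases(
    events: pd.DataFrame, params: CohortParams | None = None
) -> dict[str, dt.date]:
    """Map each incident patient to their index date.

    A patient is incident iff their earliest cancer code inside the study
    window has no cancer code (of any date, in- or pre-window) in the open
    washout interval (index − washout_days, index).  Patients failing the
    washout are absent from the map entirely.
    """
    params = params or CohortParams()
    ev = _prepare_events(events, params)
    cancer = ev[ev["_is_cancer"]]
    out: dict[str, dt.date] = {}
    for pid, grp in cancer.groupby("patient_id", sort=True):
        dates = sorted(grp["date"])
        in_window = [
            d for d in dates
            if (params.study_start is None or d >= params.study_start)
            and (params.study_end is None or d <= params.study_end)
        ]
        if not in_window:
            continue
        index = in_window[0]
        prior = [d for d in dates if 0 < (index - d).days < params.washout_days]
        if prior:
            continue
        out[str(pid)] = index
    return out


def assign_group_hospital(
    events: pd.DataFrame,
    incident: Mapping[str, dt.date],
    params: CohortParams | None = None,
) -> pd.DataFrame:
    """Cancer group and hospital from the first (index-date) cancer code.

    Same-date ties break on lexicographic code then original event order.
    Later codes are never re-checked: the group is fixed at the first code.
    """
    params = params or CohortParams()
    ev = _prepare_events(events, params)
    rows = []
    cancer = ev[ev["_is_cancer"]]
    for pid, index in incident.items():
        day = cancer[(cancer["patient_id"] == pid) & (cancer["date"] == index)]
        day = day.sort_values(["code", "_event_order"])
        first = day.iloc[0]
        rows.append(
            {
                "patient_id": pid,
                "index_date": index,
                "index_code": first["code"],
                "cancer_group": map_code_to_group(first["code"]),
                "hospital_id": first["hospital_id"],
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "index_date", "index_code",
                       "cancer_group", "hospital_id"])


def window_documents(
    documents: pd.DataFrame,
    index_dates: Mapping[str, dt.date],
    params: CohortParams | None = None,
) -> pd.DataFrame:
    """Documents dated within [index − 90 d, index + 365 d], both inclusive,
    restricted to the three report types and to incident patients."""
    params = params or CohortParams()
    doc = documents.copy()
    doc["date"] = pd.to_datetime(doc["date"]).dt.date
    keep = []
    for row in doc.itertuples(index=False):
        idx = index_dates.get(row.patient_id)
        if idx is None or row.doc_type not in ("MDT", "CONSULTATION", "HOSPITALIZATION"):
            keep.append(False)
            continue
        delta = (row.date - idx).days
        keep.append(-params.window_before <= delta <= params.window_after)
    return doc[np.array(keep, dtype=bool)] if len(doc) else doc


def derive_outcomes(
    index_date: dt.date,
    patient_events: pd.DataFrame,
    death_date: dt.date | None,
    params: CohortParams | None = None,
) -> tuple[bool, bool]:
    """(metastatic_at_dx, died_within_1y) for one patient.

    Metastatic at diagnosis: any C77-C79 code in [index, index + 90 d].
    One-year death: death date present and <= index + 365 d (a death date
    before the index is a data inconsistency, warned and counted as died).
    """
    params = params or CohortParams()
    metastatic = False
    for row in patient_events.itertuples(index=False):
        code = str(row.code).strip().upper()
        if any(code.startswith(p) for p in params.metastasis_prefixes):
            d = row.date if isinstance(row.date, dt.date) else pd.Timestamp(row.date).date()
            if 0 <= (d - index_date).days <= params.metastatic_window:
                metastatic = True
                break
    died = False
    if death_date is not None and not pd.isna(death_date):
        delta = (death_date - index_date).days
        if delta < 0:
            warnings.warn(
                f"death date {death_date} precedes index {index_date}; "
                "treating as died within 1 year",
                stacklevel=2,
            )
            died = True
        else:
            died = delta <= params.window_after
    return metastatic, died


def apply_exclusions(
    candidates: pd.DataFrame,
    patients: pd.DataFrame,
    doc_counts: pd.DataFrame,
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Run the exclusion cascade over incident candidates.

    Order: (1) age < 18 at index; (2) hospital share < 1% of incident
    diagnoses (share computed once, before any exclusion) or paediatric
    hospital; (3) sex/site mismatch (male gynaecological, female prostate;
    male breast retained); (4) zero in-window documents.  Returns the
    surviving candidates (with age and document counts merged in) and the
    step-by-step log.
    """
    params = params or CohortParams()
    log = ExclusionLog()
    df = candidates.merge(
        patients[["patient_id", "sex", "birth_date"]], on="patient_id", how="left")
    df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.date
    df["age_at_dx"] = [
        (row.index_date - row.birth_date).days / 365.25
        for row in df.itertuples(index=False)
    ]
    log.add("incident candidates", 0, len(df))

    # hospital shares on the pre-exclusion incident denominator
    shares = df["hospital_id"].value_counts(normalize=True) if len(df) else pd.Series(dtype=float)

    n0 = len(df)
    df = df[df["age_at_dx"] >= 18.0]
    log.add("age under 18", n0 - len(df), len(df))

    n0 = len(df)
    small = {h for h, s in shares.items() if s < params.hospital_min_share}
    small |= set(params.paediatric_hospitals)
    df = df[~df["hospital_id"].isin(small)]
    log.add("hospital share below threshold or paediatric", n0 - len(df), len(df))

    n0 = len(df)
    mismatch = ((df["sex"] == "M") & (df["cancer_group"] == "Gynaecological")) | (
        (df["sex"] == "F") & (df["cancer_group"] == "Prostate"))
    df = df[~mismatch]
    log.add("sex and cancer-site mismatch", n0 - len(df), len(df))

    n0 = len(df)
    df = df.merge(doc_counts, on="patient_id", how="left")
    for c in ("n_mdt", "n_consult", "n_hosp"):
        df[c] = df[c].fillna(0).astype(int)
    df = df[df[["n_mdt", "n_consult", "n_hosp"]].sum(axis=1) >= 1]
    log.add("no document in window", n0 - len(df), len(df))
    return df.reset_index(drop=True), log


_DOC_TYPE_TO_COL = {"MDT": "n_mdt", "CONSULTATION": "n_consult",
                    "HOSPITALIZATION": "n_hosp"}


def build_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    documents: pd.DataFrame,
    doc_has_ps: Mapping[str, bool],
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """End-to-end cohort construction.

    ``documents`` needs columns doc_id, patient_id, doc_type, date;
    ``doc_has_ps`` maps doc_id to the extractor's document-level decision.
    Returns one row per included patient with the regression covariates and
    outcomes, plus the exclusion log.
    """
    params = params or CohortParams()
    incident = find_incident_cases(events, params)
    assigned = assign_group_hospital(events, incident, params)
    in_window = window_documents(documents, incident, params)

    counts = (
        in_window.groupby(["patient_id", "doc_type"]).size().unstack(fill_value=0)
        if len(in_window) else pd.DataFrame()
    )
    doc_counts = pd.DataFrame({"patient_id": assigned["patient_id"]})
    for t, col in _DOC_TYPE_TO_COL.items():
        if t in counts.columns:
            doc_counts[col] = (
                doc_counts["patient_id"].map(counts[t]).fillna(0).astype(int))
        else:
            doc_counts[col] = 0

    cohort, log = apply_exclusions(assigned, patients, doc_counts, params)

    ev = _prepare_events(events, params)
    pat = patients.set_index("patient_id")
    death_dates = pd.to_datetime(pat["death_date"], errors="coerce").dt.date

    met_flags, died_flags, has_ps_flags = [], [], []
    win_by_patient = (
        in_window.groupby("patient_id")["doc_id"].apply(list).to_dict()
        if len(in_window) else {}
    )
    for row in cohort.itertuples(index=False):
        pev = ev[ev["patient_id"] == row.patient_id]
        death = death_dates.get(row.patient_id)
        if pd.isna(death):
            death = None
        met, died = derive_outcomes(row.index_date, pev, death, params)
        met_flags.append(met)
        died_flags.append(died)
        has_ps_flags.append(
            any(bool(doc_has_ps.get(d, False))
                for d in win_by_patient.get(row.patient_id, [])))
    cohort = cohort.assign(
        metastatic_at_dx=met_flags, died_within_1y=died_flags, has_ps=has_ps_flags)
    cols = ["patient_id", "index_date", "index_code", "sex", "age_at_dx",
            "cancer_group", "hospital_id", "n_mdt", "n_consult", "n_hosp",
            "metastatic_at_dx", "has_ps", "died_within_1y"]
    return cohort[cols], log
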