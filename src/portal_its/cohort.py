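"""Eligibility rules and arm-labelled index-date assignment.

Portal patients anchor on their registration date and must be observed for
the full year before and after it.  Never-registered patients enter the
control pool once per calendar year (2010-2018, the portal era) in which the
July-1-anchored two-year window is fully observed — the open-cohort design.
Person-time before the 18th birthday is discarded before any window is
evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import pandas as pd

CONTROL_YEARS = range(2010, 2019)

#: minimum continuous coverage (in years) within 2009-2019 for controls
CONSECUTIVE_WINDOW = (pd.Timestamp("2009-01-01"), pd.Timestamp("2019-12-31"))


@dataclass(frozen=True)
class IndexRecord:
    patient_id: str
    arm: str  # "portal" | "control"
    index_date: pd.Timestamp
    index_year: int

    def __post_init__(self) -> None:
        if self.arm not in ("portal", "control"):
            raise ValueError(f"bad arm {self.arm!r}")
        if self.arm == "control" and not (
            self.index_date.month == 7 and self.index_date.day == 1
        ):
            raise ValueError("control index dates must fall on July 1")


@dataclass(frozen=True)
class Ineligible:
    patient_id: str
    reason: str


def _adult_window(patient) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Observation window trimmed to age >= 18."""
    start = pd.Timestamp(patient["obs_start"])
    end = pd.Timestamp(patient["obs_end"])
    adult = pd.Timestamp(patient["birth_date"]) + pd.DateOffset(years=18)
    return max(start, adult), end


def _covers_one_year_each_side(start, end, index_date) -> tuple[bool, str]:
    pre_ok = start <= index_date - pd.DateOffset(years=1)
    post_ok = end >= index_date + pd.DateOffset(years=1)
    if pre_ok and post_ok:
        return True, ""
    if not pre_ok and not post_ok:
        return False, "out_of_window"
    return False, "insufficient_pre" if not pre_ok else "insufficient_post"


def portal_index(patient) -> IndexRecord | Ineligible:
    """Index record for a portal registrant, or the reason it is ineligible.

    Requires a full calendar year of (adult) observation on each side of the
    registration date.
    """
    pid = str(patient["patient_id"])
    reg = patient.get("portal_date") if hasattr(patient, "get") else patient["portal_date"]
    if pd.isna(reg):
        raise ValueError(f"patient {pid} has no portal registration date")
    reg = pd.Timestamp(reg)
    start, end = _adult_window(patient)
    if reg < start or reg > end:
        return Ineligible(pid, "out_of_window")
    ok, reason = _covers_one_year_each_side(start, end, reg)
    if not ok:
        return Ineligible(pid, reason)
    return IndexRecord(pid, "portal", reg, reg.year)


def control_candidate_years(patient) -> list[IndexRecord]:
    """Open-cohort entries for a never-registered patient.

    One July-1 index record per calendar year 2010-2018 whose full two-year
    window is observed, provided the patient has at least two consecutive
    years of coverage within 2009-2019.
    """
    pid = str(patient["patient_id"])
    start, end = _adult_window(patient)
    lo = max(start, CONSECUTIVE_WINDOW[0])
    hi = min(end, CONSECUTIVE_WINDOW[1])
    if lo + pd.DateOffset(years=2) - pd.DateOffset(days=1) > hi:
        return []
    out = []
    for year in CONTROL_YEARS:
        idx = pd.Timestamp(year=year, month=7, day=1)
        ok, _ = _covers_one_year_each_side(start, end, idx)
        if ok:
            out.append(IndexRecord(pid, "control", idx, year))
    return out


@dataclass
class CohortResult:
    portal: list[IndexRecord]
    control: list[IndexRecord]
    exclusions: dict  # reason -> count
    excluded_patients: list[Ineligible]

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(r) for r in self.portal + self.control]
        return pd.DataFrame(
            rows, columns=["patient_id", "arm", "index_date", "index_year"]
        )

    def write(self, cohort_csv, exclusions_json) -> None:
        self.to_frame().to_csv(cohort_csv, index=False)
        with open(exclusions_json, "w") as fh:
            json.dump(self.exclusions, fh, indent=2, sort_keys=True)


def build_cohort(bundle) -> CohortResult:
    """Partition a bundle's patients into eligible portal/control records.

    Duplicate patient ids are a hard error; per-reason exclusion counts are
    returned for flow-diagram reporting.  Patients carrying a truthy
    ``focused_care`` column are dropped up front.
    """
    patients = bundle.patients if hasattr(bundle, "patients") else bundle
    if patients["patient_id"].duplicated().any():
        dups = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids: {sorted(set(dups))[:5]}")

    portal_records: list[IndexRecord] = []
    control_records: list[IndexRecord] = []
    excluded: list[Ineligible] = []

    for _, patient in patients.iterrows():
        pid = str(patient["patient_id"])
        if bool(patient.get("focused_care", False)):
            excluded.append(Ineligible(pid, "focused_care"))
            continue
        if pd.notna(patient.get("portal_date")):
            res = portal_index(patient)
            if isinstance(res, IndexRecord):
                portal_records.append(res)
            else:
                excluded.append(res)
        else:
            recs = control_candidate_years(patient)
            if recs:
                control_records.extend(recs)
            else:
                excluded.append(Ineligible(pid, "no_eligible_control_year"))

    exclusions: dict[str, int] = {}
    for e in excluded:
        exclusions[e.reason] = exclusions.get(e.reason, 0) + 1
    return CohortResult(portal_records, control_records, exclusions, excluded)
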