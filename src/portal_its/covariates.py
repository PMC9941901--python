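"""Index-date covariate assembly: 12-month lookback counts, diagnosis
flags, exact age, and the banded categorizations used in the baseline table.

The lookback window is half-open ``(index - 1 year, index]`` — activity
strictly more than one calendar year before the index date is excluded and
the index day itself is included.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from portal_its.cohort import IndexRecord
from portal_its.synthetic_emr import DX_CONDITIONS

#: prescription schedule classes excluded from distinct-medication counts
EXCLUDED_SCHEDULES = frozenset({"OTC", "ethical", "other", "NA"})

_MD_MEDS_BANDS = [(0, 0, "0"), (1, 2, "1-2"), (3, 5, "3-5"), (6, 10, "6-10")]
_NPPA_TC_BANDS = [(0, 0, "0"), (1, 2, "1-2")]


@dataclass
class CovariateVector:
    """Propensity-model inputs evaluated at one index record."""

    age_years: float
    sex: str
    rostered: bool
    dx_cad: bool
    dx_chf: bool
    dx_copd: bool
    dx_dm: bool
    dx_htn: bool
    md_visits_12m: int
    nppa_visits_12m: int
    tc_calls_12m: int
    distinct_meds_12m: int
    income_band: str | None = None
    education_band: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)


#: covariates entering the propensity model (income/education excluded:
#: recorded for too few patients)
PS_COVARIATES = (
    "age_years",
    "female",
    "rostered",
    "dx_cad",
    "dx_chf",
    "dx_copd",
    "dx_dm",
    "dx_htn",
    "md_visits_12m",
    "nppa_visits_12m",
    "tc_calls_12m",
    "distinct_meds_12m",
)


def lookback_counts(
    encounters: pd.DataFrame,
    prescriptions: pd.DataFrame,
    index_date,
) -> tuple[int, int, int, int]:
    """(md, nppa, tc, distinct_meds) in the year ending on ``index_date``.

    ``encounters``/``prescriptions`` must belong to a single patient.
    Distinct medications are unique ATC codes after dropping excluded
    schedule classes.
    """
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.DateOffset(years=1)

    md = nppa = tc = 0
    if len(encounters):
        if encounters["date"].isna().any():
            raise ValueError("undated encounter record")
        dates = pd.to_datetime(encounters["date"])
        in_win = (dates > lo) & (dates <= index_date)
        ch = encounters.loc[in_win, "channel"]
        md = int((ch == "MD").sum())
        nppa = int((ch == "NPPA").sum())
        tc = int((ch == "TC").sum())

    meds = 0
    if len(prescriptions):
        if prescriptions["date"].isna().any():
            raise ValueError("undated prescription record")
        dates = pd.to_datetime(prescriptions["date"])
        in_win = (dates > lo) & (dates <= index_date)
        sub = prescriptions.loc[in_win]
        keep = ~sub["schedule_class"].astype(str).isin(EXCLUDED_SCHEDULES)
        meds = int(sub.loc[keep, "atc_code"].nunique())
    return md, nppa, tc, meds


def diagnosis_flags(patient, index_date) -> dict[str, bool]:
    """Condition present iff its earliest coded onset is on or before index."""
    index_date = pd.Timestamp(index_date)
    out = {}
    for cond in DX_CONDITIONS:
        onset = patient.get(f"dx_{cond}_onset")
        out[f"dx_{cond}"] = bool(pd.notna(onset) and pd.Timestamp(onset) <= index_date)
    return out


def categorize(count, scheme: str) -> str:
    """Map a nonnegative count to its baseline-table band.

    md/meds: {0, 1-2, 3-5, 6-10, ≥11};  nppa/tc: {0, 1-2, ≥3}.  The top
    band is inclusive of its lower edge so the bands partition all counts.
    """
    if count < 0 or count != int(count):
        raise ValueError(f"count must be a nonnegative integer, got {count!r}")
    count = int(count)
    if scheme in ("md", "meds"):
        bands, top = _MD_MEDS_BANDS, "≥11"
    elif scheme in ("nppa", "tc"):
        bands, top = _NPPA_TC_BANDS, "≥3"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    for lo, hi, label in bands:
        if lo <= count <= hi:
            return label
    return top


def exact_age_years(birth_date, at_date) -> float:
    """Age in exact years: whole birthdays plus the fraction of the current
    age-year elapsed (so an 18th-birthday index gives exactly 18.0)."""
    birth = pd.Timestamp(birth_date)
    at = pd.Timestamp(at_date)
    if at < birth:
        raise ValueError("date precedes birth")
    whole = at.year - birth.year
    anniv = _safe_anniversary(birth, whole)
    if anniv > at:
        whole -= 1
        anniv = _safe_anniversary(birth, whole)
    nxt = _safe_anniversary(birth, whole + 1)
    frac = (at - anniv) / (nxt - anniv)
    return float(whole + frac)


def _safe_anniversary(birth: pd.Timestamp, years: int) -> pd.Timestamp:
    try:
        return birth.replace(year=birth.year + years)
    except ValueError:  # Feb 29 birthday in a common year
        return birth.replace(year=birth.year + years, day=28)


def covariate_vector(
    patient,
    index_record: IndexRecord,
    encounters: pd.DataFrame,
    prescriptions: pd.DataFrame,
) -> CovariateVector:
    """Assemble the full covariate vector for one eligible index record."""
    sex = patient.get("sex")
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        raise ValueError(f"missing sex for patient {patient['patient_id']}")
    idx = index_record.index_date
    md, nppa, tc, meds = lookback_counts(encounters, prescriptions, idx)
    flags = diagnosis_flags(patient, idx)

    def _opt(key):
        v = patient.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else str(v)

    return CovariateVector(
        age_years=exact_age_years(patient["birth_date"], idx),
        sex=str(sex),
        rostered=bool(patient["rostered"]),
        md_visits_12m=md,
        nppa_visits_12m=nppa,
        tc_calls_12m=tc,
        distinct_meds_12m=meds,
        income_band=_opt("income_band"),
        education_band=_opt("education_band"),
        **flags,
    )


def build_covariates(
    cohort_frame: pd.DataFrame,
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    prescriptions: pd.DataFrame,
) -> pd.DataFrame:
    """Covariate table keyed by (patient_id, arm, index_year).

    Vectorized equivalent of calling :func:`covariate_vector` per index
    record; the per-record function remains the reference implementation
    and the two are cross-checked in the test suite.
    """
    pat = patients.set_index("patient_id")
    recs = cohort_frame.copy()
    recs["index_date"] = pd.to_datetime(recs["index_date"])
    recs["lookback_lo"] = recs["index_date"] - pd.DateOffset(years=1)

    # sort event tables once; count via searchsorted per record
    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"])
    rx = prescriptions.copy()
    rx["date"] = pd.to_datetime(rx["date"])
    rx = rx[~rx["schedule_class"].astype(str).isin(EXCLUDED_SCHEDULES)]

    enc_by_pid = {
        (pid, ch): np.sort(g["date"].to_numpy())
        for (pid, ch), g in enc.groupby(["patient_id", "channel"], sort=False)
    }
    rx_by_pid = {
        pid: g.sort_values("date") for pid, g in rx.groupby("patient_id", sort=False)
    }

    rows = []
    for rec in recs.itertuples(index=False):
        pid = rec.patient_id
        patient = pat.loc[pid]
        idx = rec.index_date
        lo = rec.lookback_lo
        counts = {}
        for ch, col in (("MD", "md_visits_12m"), ("NPPA", "nppa_visits_12m"), ("TC", "tc_calls_12m")):
            dates = enc_by_pid.get((pid, ch))
            if dates is None:
                counts[col] = 0
            else:
                counts[col] = int(
                    np.searchsorted(dates, np.datetime64(idx), side="right")
                    - np.searchsorted(dates, np.datetime64(lo), side="right")
                )
        g = rx_by_pid.get(pid)
        if g is None:
            meds = 0
        else:
            d = g["date"].to_numpy()
            i0 = np.searchsorted(d, np.datetime64(lo), side="right")
            i1 = np.searchsorted(d, np.datetime64(idx), side="right")
            meds = int(g["atc_code"].iloc[i0:i1].nunique())
        flags = diagnosis_flags(patient, idx)
        rows.append(
            {
                "patient_id": pid,
                "arm": rec.arm,
                "index_year": rec.index_year,
                "index_date": idx,
                "age_years": exact_age_years(patient["birth_date"], idx),
                "female": patient["sex"] == "female",
                "sex": patient["sex"],
                "rostered": bool(patient["rostered"]),
                **flags,
                **counts,
                "distinct_meds_12m": meds,
                "income_band": patient.get("income_band", ""),
                "education_band": patient.get("education_band", ""),
            }
        )
    out = pd.DataFrame(rows)
    for col in ("female", "rostered", *(f"dx_{c}" for c in DX_CONDITIONS)):
        out[col] = out[col].astype(bool)
    return out
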