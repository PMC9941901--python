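"""Synthetic EMR generation.

Two levels of fidelity are provided:

* :func:`simulate_panel` draws matched person-year panels directly from the
  segmented-regression mean structure.  This is the fast path used by the
  Monte-Carlo coefficient-recovery studies.
* :func:`generate_population` emits a full EMR-style bundle (patients,
  dated encounters, prescriptions, provider messages) whose registration
  behaviour is covariate-driven, so that cohort construction, covariate
  derivation and propensity matching can all be exercised against known
  ground truth.

Counts are Poisson around a clamped linear mean: the mean structure is the
linear segmented model, clamped below at ``mean_floor`` to keep Poisson
rates valid.  Presets restrict year ranges so clamping never bites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CHANNELS = ("MD", "NPPA", "TC")

DX_CONDITIONS = ("cad", "chf", "copd", "dm", "htn")


@dataclass(frozen=True)
class CoefficientVector:
    """Eight coefficients of the two-arm segmented linear model.

    b0  control intercept
    b1  control pre-index slope
    b2  control level change at year 2 post-index
    b3  control slope change in the post-index period
    b4  portal-control intercept difference
    b5  portal-control pre-index slope difference
    b6  portal-control level-change difference
    b7  portal-control slope-change difference
    """

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    b7: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.b0, self.b1, self.b2, self.b3, self.b4, self.b5, self.b6, self.b7],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr) -> "CoefficientVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 coefficients, got shape {arr.shape}")
        return cls(*arr.tolist())


#: Published segmented-regression estimates used as generative ground truth.
#: Columns: physician visits, NP/PA visits, triage calls.
_PRESETS = {
    "paper-MD": CoefficientVector(1.572, 0.009, 0.002, 0.036, 0.008, 0.014, 0.417, -0.054),
    "paper-NPPA": CoefficientVector(0.618, 0.049, -0.011, -0.042, -0.018, -0.010, 0.069, 0.028),
    "paper-TC": CoefficientVector(0.335, 0.045, 0.062, 0.010, -0.033, -0.005, 0.102, -0.005),
}


def preset_coefficients(name: str, b0: float = 1.0, b1: float = 0.0) -> CoefficientVector:
    """Return a named coefficient preset.

    ``paper-MD`` / ``paper-NPPA`` / ``paper-TC`` are the published estimates
    for the three encounter channels; ``null`` has no arm, level or slope
    effects (``b2..b7 = 0``) with configurable baseline ``b0``, ``b1``.
    """
    if name == "null":
        return CoefficientVector(b0, b1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    try:
        return _PRESETS[name]
    except KeyError:
        valid = sorted(_PRESETS) + ["null"]
        raise KeyError(f"unknown preset {name!r}; valid names: {valid}") from None


def outcome_mean(
    coeffs: CoefficientVector,
    t,
    arm: str,
    mean_floor: float = 0.01,
):
    """Expected annual count at relative year ``t`` for the given arm.

    Computes ``max(mean_floor, b0 + b1*t + b2*P + b3*(t-2)*P +
    A*(b4 + b5*t + b6*P + b7*(t-2)*P))`` where ``P = 1 if t >= 2 else 0``
    and ``A = 1`` for the portal arm.  ``t`` may be a scalar or array of
    integers (relative years 0 and 1 are valid here; the fitting stage is
    what excludes them).
    """
    t_arr = np.asarray(t)
    if not np.issubdtype(t_arr.dtype, np.integer):
        if not np.all(t_arr == np.floor(t_arr)):
            raise ValueError(f"relative year must be an integer, got {t!r}")
        t_arr = t_arr.astype(int)
    if arm not in ("portal", "control"):
        raise ValueError(f"arm must be 'portal' or 'control', got {arm!r}")
    a = 1.0 if arm == "portal" else 0.0
    p = (t_arr >= 2).astype(float)
    c = coeffs
    mu = (
        c.b0
        + c.b1 * t_arr
        + c.b2 * p
        + c.b3 * (t_arr - 2) * p
        + a * (c.b4 + c.b5 * t_arr + c.b6 * p + c.b7 * (t_arr - 2) * p)
    )
    out = np.maximum(mean_floor, mu)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


@dataclass
class SynthConfig:
    """Configuration of the synthetic EMR generator."""

    n_patients: int
    seed: int
    calendar_start: str = "2002-01-01"
    calendar_end: str = "2019-12-31"
    portal_launch: str = "2010-01-01"
    #: logistic coefficients for annual registration propensity, applied to
    #: (1, standardized age, female, rostered, dx flags..., latent utilization)
    registration_logit_coeffs: dict = field(
        default_factory=lambda: {
            "intercept": -2.0,
            "age_z": -0.3,
            "female": 0.4,
            "rostered": 1.0,
            "dx_cad": 0.1,
            "dx_chf": 0.1,
            "dx_copd": 0.1,
            "dx_dm": 0.2,
            "dx_htn": 0.2,
            "util": 0.6,
        }
    )
    #: per-channel generative coefficients (preset name or CoefficientVector)
    channel_presets: dict = field(
        default_factory=lambda: {"MD": "paper-MD", "NPPA": "paper-NPPA", "TC": "paper-TC"}
    )
    pre_year_range: tuple = (-8, -1)
    post_year_range: tuple = (2, 8)
    noise: str = "poisson"
    random_intercept_sd: float = 0.0
    mean_floor: float = 0.01
    #: mean provider messages per registered patient per year
    messages_per_patient_year: float = 1.49
    #: mean minutes per provider message
    mean_minutes_per_message: float = 3.83

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.mean_floor <= 0:
            raise ValueError("mean_floor must be positive")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be nonnegative")
        if self.noise != "poisson":
            raise ValueError(f"unsupported noise model {self.noise!r}")

    def resolved_coeffs(self, channel: str) -> CoefficientVector:
        val = self.channel_presets[channel]
        if isinstance(val, CoefficientVector):
            return val
        if isinstance(val, (list, tuple, np.ndarray)):
            return CoefficientVector.from_array(val)
        return preset_coefficients(val)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("synthetic config must declare a seed")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pre_year_range" in raw:
            raw["pre_year_range"] = tuple(raw["pre_year_range"])
        if "post_year_range" in raw:
            raw["post_year_range"] = tuple(raw["post_year_range"])
        return cls(**raw)


@dataclass
class EMRBundle:
    """Synthetic EMR extract plus generative ground truth."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    prescriptions: pd.DataFrame
    messages: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        """Write the four delimited tables (ISO-8601 dates) to ``out_dir``."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name in ("patients", "encounters", "prescriptions", "messages"):
            getattr(self, name).to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)

    @classmethod
    def read(cls, in_dir) -> "EMRBundle":
        import os

        tables = {}
        for name in ("patients", "encounters", "prescriptions", "messages"):
            path = os.path.join(in_dir, f"{name}.csv")
            if not os.path.exists(path):
                raise FileNotFoundError(f"missing required table: {path}")
            tables[name] = pd.read_csv(path)
        date_cols = {
            "patients": ["birth_date", "obs_start", "obs_end", "portal_date"]
            + [f"dx_{c}_onset" for c in DX_CONDITIONS],
            "encounters": ["date"],
            "prescriptions": ["date"],
            "messages": ["sent_date"],
        }
        for name, cols in date_cols.items():
            for col in cols:
                if col in tables[name].columns:
                    tables[name][col] = pd.to_datetime(tables[name][col])
        return cls(truth={}, **tables)


# ---------------------------------------------------------------------------
# fast matched-panel simulation (Monte-Carlo recovery path)
# ---------------------------------------------------------------------------

def relative_years(pre_year_range, post_year_range) -> np.ndarray:
    """Integer relative years covered by the two closed ranges."""
    lo_pre, hi_pre = pre_year_range
    lo_post, hi_post = post_year_range
    if lo_pre > hi_pre or lo_post > hi_post:
        raise ValueError("year ranges must be nondecreasing")
    return np.concatenate(
        [np.arange(lo_pre, hi_pre + 1), np.arange(lo_post, hi_post + 1)]
    )


def simulate_panel(
    coeffs: CoefficientVector,
    n_per_arm: int,
    years,
    rng: np.random.Generator,
    mean_floor: float = 0.01,
) -> pd.DataFrame:
    """Draw a balanced matched person-year panel with Poisson counts.

    Returns columns ``patient_id, arm, t, count``; arm is 0 (control) or
    1 (portal); one row per patient per relative year in ``years``.
    """
    years = np.asarray(years, dtype=int)
    frames = []
    for a, arm in ((0, "control"), (1, "portal")):
        mu = outcome_mean(coeffs, years, arm, mean_floor=mean_floor)
        counts = rng.poisson(np.broadcast_to(mu, (n_per_arm, years.size)))
        pid_base = 0 if a == 0 else n_per_arm
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(np.arange(n_per_arm) + pid_base, years.size),
                    "arm": a,
                    "t": np.tile(years, n_per_arm),
                    "count": counts.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full EMR bundle generation
# ---------------------------------------------------------------------------

_ATC_POOL = [
    "A02BC02", "A10BA02", "B01AC06", "C03CA01", "C07AB02", "C08CA01",
    "C09AA05", "C10AA01", "C10AA05", "H03AA01", "J01CA04", "M01AE01",
    "N02BE01", "N05BA06", "N06AB04", "R03AC02", "R03BB04", "R06AE07",
    "S01AA11", "A12AX01",
]

_SCHEDULE_CLASSES = ["prescription", "OTC", "ethical", "other", "NA"]
_SCHEDULE_PROBS = [0.875, 0.049, 0.023, 0.029, 0.024]


def _year_span(index_date: pd.Timestamp, t: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open span (start, end] of relative year t.

    Year 0 is the 12 months preceding and including the index date; each
    step shifts the span by a calendar year (leap-safe).
    """
    end = index_date + pd.DateOffset(years=t)
    start = index_date + pd.DateOffset(years=t - 1)
    return start, end


def generate_population(config: SynthConfig) -> EMRBundle:
    """Generate a full synthetic EMR bundle.

    Each patient gets an observation window, demographics, diagnosis onsets
    and a latent utilization intercept.  Registration on the portal is a
    logistic function of those covariates and can only occur on or after the
    portal launch, with at least a year of observation on either side.
    Encounter counts per relative person-year are Poisson around the
    segmented-model mean; dates are placed uniformly within the year span.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cal_start = pd.Timestamp(config.calendar_start)
    cal_end = pd.Timestamp(config.calendar_end)
    launch = pd.Timestamp(config.portal_launch)

    # demographics and latent structure
    age_at_launch = rng.uniform(20.0, 82.0, size=n)
    birth = launch - pd.to_timedelta((age_at_launch * 365.25).round().astype(int), unit="D")
    female = rng.random(n) < 0.54
    rostered = rng.random(n) < 0.95
    util = rng.normal(0.0, 1.0, size=n)  # latent utilization propensity

    # observation windows: most patients span the whole calendar period
    full = rng.random(n) < 0.7
    start_off = np.where(full, 0, rng.integers(0, 3000, size=n))
    end_off = np.where(full, 0, rng.integers(0, 3000, size=n))
    obs_start = cal_start + pd.to_timedelta(start_off, unit="D")
    obs_end = cal_end - pd.to_timedelta(end_off, unit="D")
    swap = obs_start > obs_end
    obs_start = obs_start.where(~swap, cal_start)

    # diagnosis onsets: probability loosely increasing with age
    dx_onset = {}
    dx_flag_at_launch = {}
    base_p = {"cad": 0.035, "chf": 0.013, "copd": 0.025, "dm": 0.06, "htn": 0.17}
    window_days = np.maximum((obs_end - obs_start).days.to_numpy(), 1)
    for cond in DX_CONDITIONS:
        p = np.clip(base_p[cond] * (0.3 + age_at_launch / 50.0), 0, 0.9)
        has = rng.random(n) < p
        frac = rng.random(n)
        onset = obs_start + pd.to_timedelta((frac * window_days).astype(int), unit="D")
        dx_onset[cond] = onset.where(has, pd.NaT)
        dx_flag_at_launch[cond] = has & (onset <= launch)

    # registration propensity (annual hazard applied over the portal era)
    c = config.registration_logit_coeffs
    age_z = (age_at_launch - age_at_launch.mean()) / age_at_launch.std()
    logit = (
        c.get("intercept", -2.0)
        + c.get("age_z", 0.0) * age_z
        + c.get("female", 0.0) * female.astype(float)
        + c.get("rostered", 0.0) * rostered.astype(float)
        + sum(
            c.get(f"dx_{cond}", 0.0) * dx_flag_at_launch[cond].astype(float)
            for cond in DX_CONDITIONS
        )
        + c.get("util", 0.0) * util
    )
    with np.errstate(over="ignore"):
        p_reg = 1.0 / (1.0 + np.exp(-logit))

    registers = rng.random(n) < p_reg
    # registration date: uniform within the portion of the observation window
    # that is >= launch and leaves >= 1 year on each side
    earliest = np.maximum(
        np.maximum(obs_start.to_numpy(), np.datetime64(launch)),
        (obs_start + pd.DateOffset(years=1)).to_numpy(),
    )
    latest = (obs_end - pd.DateOffset(years=1)).to_numpy()
    span_days = (latest - earliest) / np.timedelta64(1, "D")
    feasible = span_days >= 0
    registers &= feasible
    reg_frac = rng.random(n)
    reg_offset = np.where(feasible, (reg_frac * np.maximum(span_days, 0)).astype(int), 0)
    portal_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    portal_date[registers] = pd.to_datetime(earliest[registers]) + pd.to_timedelta(
        reg_offset[registers], unit="D"
    )

    # pseudo-index for controls: July 1 of a random feasible year, used only
    # to anchor their generative time axis (truth; never exported)
    years_grid = np.arange(launch.year, cal_end.year)
    pseudo_year = rng.choice(years_grid, size=n)
    pseudo_index = pd.to_datetime([f"{y}-07-01" for y in pseudo_year])
    index_anchor = portal_date.to_numpy().copy()
    ctrl = ~registers
    index_anchor[ctrl] = pseudo_index[ctrl].to_numpy()
    index_anchor = pd.to_datetime(index_anchor)

    # income / education bands, recorded for ~1/3 of patients
    has_ses = rng.random(n) < 0.34
    income = rng.choice(
        ["<40k", "40-60k", "60-100k", ">100k"], size=n, p=[0.12, 0.15, 0.31, 0.42]
    )
    education = rng.choice(
        ["high_school_or_less", "college", "university_or_more"],
        size=n,
        p=[0.30, 0.30, 0.40],
    )
    income = np.where(has_ses, income, "")
    education = np.where(has_ses, education, "")

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": birth,
            "sex": np.where(female, "female", "male"),
            "rostered": rostered,
            "obs_start": obs_start,
            "obs_end": obs_end,
            "portal_date": portal_date.to_numpy(),
            "income_band": income,
            "education_band": education,
            **{f"dx_{cond}_onset": dx_onset[cond].to_numpy() for cond in DX_CONDITIONS},
        }
    )

    # person-year encounter counts per channel; the generator emits the full
    # contiguous year range (incl. 0 and 1) so plots have data there
    years = np.arange(config.pre_year_range[0], config.post_year_range[1] + 1)
    rand_int = (
        rng.normal(0.0, config.random_intercept_sd, size=n)
        if config.random_intercept_sd > 0
        else np.zeros(n)
    )

    pid_rep = np.repeat(np.arange(n), years.size)
    t_rep = np.tile(years, n)
    anchor_rep = index_anchor.to_numpy()[pid_rep]
    # leap-safe spans via vectorized DateOffset per distinct t
    starts = np.empty(t_rep.size, dtype="datetime64[ns]")
    ends = np.empty(t_rep.size, dtype="datetime64[ns]")
    anchor_idx = pd.to_datetime(anchor_rep)
    for t in years:
        mask = t_rep == t
        sub = pd.DatetimeIndex(anchor_idx[mask])
        starts[mask] = (sub + pd.DateOffset(years=int(t) - 1)).to_numpy()
        ends[mask] = (sub + pd.DateOffset(years=int(t))).to_numpy()
    obs_start_rep = obs_start.to_numpy()[pid_rep]
    obs_end_rep = obs_end.to_numpy()[pid_rep]
    # only emit person-years fully observed
    observed = (starts >= obs_start_rep) & (ends <= obs_end_rep)

    enc_frames = []
    n_floored = 0
    n_cells = 0
    arm_rep = registers[pid_rep]
    # latent utilization scales all channels multiplicatively on the mean
    util_mult = np.exp(0.35 * util)[pid_rep]
    for channel in CHANNELS:
        coeffs = config.resolved_coeffs(channel)
        mu_portal = outcome_mean(coeffs, years, "portal", config.mean_floor)
        mu_control = outcome_mean(coeffs, years, "control", config.mean_floor)
        mu_p_rep = np.tile(np.atleast_1d(mu_portal), n)
        mu_c_rep = np.tile(np.atleast_1d(mu_control), n)
        raw = np.where(arm_rep, mu_p_rep, mu_c_rep) * util_mult + rand_int[pid_rep]
        mu = np.maximum(config.mean_floor, raw)
        n_floored += int(np.sum((raw < config.mean_floor) & observed))
        n_cells += int(observed.sum())
        counts = rng.poisson(mu)
        counts[~observed] = 0
        total = int(counts.sum())
        if total:
            ev_pid = np.repeat(pid_rep, counts)
            ev_start = np.repeat(starts.astype("datetime64[D]").astype("int64"), counts)
            ev_end = np.repeat(ends.astype("datetime64[D]").astype("int64"), counts)
            # uniform within the half-open span (start, end]
            ev_day = ev_start + 1 + rng.integers(0, np.maximum(ev_end - ev_start, 1))
            ev_day = np.minimum(ev_day, ev_end)
            enc_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids[ev_pid],
                        "date": ev_day.astype("datetime64[D]"),
                        "channel": channel,
                    }
                )
            )
    if n_cells and n_floored / (3 * n_cells) > 0.05:
        logger.warning(
            "mean clamped at floor for %.1f%% of person-years; "
            "coefficient-recovery tests may be biased",
            100 * n_floored / (3 * n_cells),
        )
    encounters = (
        pd.concat(enc_frames, ignore_index=True)
        if enc_frames
        else pd.DataFrame(columns=["patient_id", "date", "channel"])
    )
    encounters = encounters.sort_values(
        ["patient_id", "date", "channel"], kind="stable"
    ).reset_index(drop=True)
    encounters["date"] = pd.to_datetime(encounters["date"])

    # prescriptions: Poisson per observed person-year, rate tied to latent
    # utilization so medication counts act as a confounder too
    rx_rate = np.maximum(config.mean_floor, 1.8 * np.exp(0.4 * util))[pid_rep]
    rx_counts = rng.poisson(np.where(observed, rx_rate, 0.0))
    total_rx = int(rx_counts.sum())
    if total_rx:
        rx_pid = np.repeat(pid_rep, rx_counts)
        rx_start = np.repeat(starts.astype("datetime64[D]").astype("int64"), rx_counts)
        rx_end = np.repeat(ends.astype("datetime64[D]").astype("int64"), rx_counts)
        rx_day = rx_start + 1 + rng.integers(0, np.maximum(rx_end - rx_start, 1))
        rx_day = np.minimum(rx_day, rx_end)
        prescriptions = pd.DataFrame(
            {
                "patient_id": patient_ids[rx_pid],
                "date": pd.to_datetime(rx_day.astype("datetime64[D]")),
                "atc_code": rng.choice(_ATC_POOL, size=total_rx),
                "schedule_class": rng.choice(
                    _SCHEDULE_CLASSES, size=total_rx, p=_SCHEDULE_PROBS
                ),
            }
        )
    else:
        prescriptions = pd.DataFrame(
            columns=["patient_id", "date", "atc_code", "schedule_class"]
        )
    prescriptions = prescriptions.sort_values(
        ["patient_id", "date", "atc_code"], kind="stable"
    ).reset_index(drop=True)

    # provider messages to registered patients, post-registration years only
    msg_rows = []
    reg_ids = np.flatnonzero(registers)
    for i in reg_ids:
        reg = portal_date.iloc[i]
        last = min(obs_end[i], cal_end)
        n_years = max(0, int((last - reg).days // 365))
        if n_years == 0:
            n_years = 1
        k = rng.poisson(config.messages_per_patient_year * n_years)
        if k == 0:
            continue
        offsets = rng.integers(0, max((last - reg).days, 1), size=k)
        minutes = rng.gamma(
            2.0, config.mean_minutes_per_message / 2.0, size=k
        ).round(2)
        msg_rows.append(
            pd.DataFrame(
                {
                    "provider_id": rng.choice(["DR01", "DR02"], size=k),
                    "patient_id": patient_ids[i],
                    "sent_date": reg + pd.to_timedelta(offsets, unit="D"),
                    "minutes": minutes,
                }
            )
        )
    messages = (
        pd.concat(msg_rows, ignore_index=True)
        if msg_rows
        else pd.DataFrame(columns=["provider_id", "patient_id", "sent_date", "minutes"])
    )

    truth = {
        "coefficients": {ch: config.resolved_coeffs(ch) for ch in CHANNELS},
        "registered": pd.Series(registers, index=patient_ids),
        "index_anchor": pd.Series(index_anchor, index=patient_ids),
        "registration_propensity": pd.Series(p_reg, index=patient_ids),
        "util": pd.Series(util, index=patient_ids),
    }
    return EMRBundle(patients, encounters, prescriptions, messages, truth)
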