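"""Person-year panel construction and the two-arm segmented regression.

The design row at relative year ``t`` for arm indicator ``A`` is

    (1, t, P, (t-2)*P, A, A*t, A*P, A*(t-2)*P),   P = 1{t >= 2}

so the period coefficient measures the level change in year 2 post-index
relative to the pre-index line, and the slope-change term is anchored
there.  Relative years 0 and 1 are excluded from fitting by default: year 0
carries the index-attribution spike and year 1 the transient post-adoption
spike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from portal_its.synthetic_emr import CoefficientVector

DESIGN_COLUMNS = (
    "intercept",
    "time",
    "period",
    "time_post",
    "portal",
    "portal_time",
    "portal_period",
    "portal_time_post",
)

#: report labels a-h in the order of DESIGN_COLUMNS
COEFFICIENT_LABELS = {
    "intercept": "a: control intercept",
    "time": "b: control pre-index slope",
    "period": "c: control level change at year 2 post-index",
    "time_post": "d: control post-index slope change",
    "portal": "e: portal-control intercept difference",
    "portal_time": "f: portal-control pre-index slope difference",
    "portal_period": "g: portal-control level-change difference",
    "portal_time_post": "h: portal-control slope-change difference",
}

DEFAULT_EXCLUDE_YEARS = frozenset({0, 1})


def design_row(t: int, a: int) -> np.ndarray:
    """Single design row; rejects the excluded relative years 0 and 1."""
    if t in (0, 1):
        raise ValueError(f"relative year {t} is excluded from the model")
    if int(t) != t:
        raise ValueError(f"relative year must be an integer, got {t!r}")
    if a not in (0, 1):
        raise ValueError(f"arm indicator must be 0 or 1, got {a!r}")
    p = 1.0 if t >= 2 else 0.0
    return np.array(
        [1.0, t, p, (t - 2) * p, a, a * t, a * p, a * (t - 2) * p], dtype=float
    )


def design_matrix(t: np.ndarray, a: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    p = (t >= 2).astype(float)
    return np.column_stack(
        [np.ones_like(t), t, p, (t - 2) * p, a, a * t, a * p, a * (t - 2) * p]
    )


@dataclass
class ITSFit:
    channel: str
    coefficients: CoefficientVector
    se_conventional: np.ndarray
    se_cluster: np.ndarray
    pvalues: np.ndarray
    n_person_years: int
    se_mode: str = "cluster-robust"
    labels: dict = field(default_factory=lambda: dict(COEFFICIENT_LABELS))

    @property
    def se(self) -> np.ndarray:
        return self.se_cluster if self.se_mode == "cluster-robust" else self.se_conventional

    def report(self) -> dict:
        coefs = self.coefficients.as_array()
        return {
            "channel": self.channel,
            "n_person_years": int(self.n_person_years),
            "se_mode": self.se_mode,
            "coefficients": {
                name: {
                    "label": self.labels[name],
                    "estimate": float(coefs[i]),
                    "se_conventional": float(self.se_conventional[i]),
                    "se_cluster": float(self.se_cluster[i]),
                    "p_value": float(self.pvalues[i]),
                }
                for i, name in enumerate(DESIGN_COLUMNS)
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2, sort_keys=True)


def _year_span(index_date: pd.Timestamp, t: int):
    """Half-open span (start, end] of relative year t; year 0 ends on the
    index date (leap-safe calendar arithmetic)."""
    return (
        index_date + pd.DateOffset(years=t - 1),
        index_date + pd.DateOffset(years=t),
    )


def build_panel(
    index_records: pd.DataFrame,
    encounters: pd.DataFrame,
    patients: pd.DataFrame,
    max_abs_year: int = 8,
) -> pd.DataFrame:
    """Per-channel annual counts for every fully-observed relative year.

    ``index_records`` needs columns patient_id, arm, index_date (one row
    per analysis patient, e.g. the matched records of both arms).  A row is
    emitted for relative year ``t`` in ``[-max_abs_year, max_abs_year]``
    only when the whole 12-month span lies inside the patient's (adult)
    observation window; zero-count years are retained.
    """
    from portal_its.cohort import _adult_window

    pat = patients.set_index("patient_id")
    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"])
    enc_by = {
        (pid, ch): np.sort(g["date"].to_numpy())
        for (pid, ch), g in enc.groupby(["patient_id", "channel"], sort=False)
    }

    rows = []
    for rec in index_records.itertuples(index=False):
        pid = rec.patient_id
        idx = pd.Timestamp(rec.index_date)
        start, end = _adult_window(pat.loc[pid])
        a = 1 if rec.arm == "portal" else 0
        for t in range(-max_abs_year, max_abs_year + 1):
            s, e = _year_span(idx, t)
            if s < start or e > end:
                continue
            counts = {}
            for ch, col in (("MD", "md"), ("NPPA", "nppa"), ("TC", "tc")):
                dates = enc_by.get((pid, ch))
                if dates is None:
                    counts[col] = 0
                else:
                    counts[col] = int(
                        np.searchsorted(dates, np.datetime64(e), side="right")
                        - np.searchsorted(dates, np.datetime64(s), side="right")
                    )
            mid = s + (e - s) / 2
            rows.append(
                {
                    "patient_id": pid,
                    "arm": a,
                    "t": t,
                    "period": int(t >= 2),
                    "calendar_year": int(mid.year),
                    **counts,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "t", "period", "calendar_year", "md", "nppa", "tc"],
    )


def fit_its(
    panel: pd.DataFrame,
    channel: str,
    exclude_years=DEFAULT_EXCLUDE_YEARS,
    se_mode: str = "cluster-robust",
    compute_cluster_se: bool = True,
) -> ITSFit:
    """OLS segmented regression of per-person-year counts for one channel.

    ``channel`` names the outcome column (md / nppa / tc, or ``count`` for
    directly simulated panels).  Conventional and cluster-robust (by
    patient) standard errors are both computed; ``se_mode`` selects which
    one drives the reported p-values.
    """
    if channel not in panel.columns:
        raise KeyError(f"no outcome column {channel!r} in panel")
    if se_mode not in ("cluster-robust", "conventional"):
        raise ValueError(f"bad se_mode {se_mode!r}")
    sub = panel[~panel["t"].isin(list(exclude_years))]
    arms = sub["arm"].unique()
    if len(arms) < 2:
        raise ValueError("panel must contain both arms")
    pre = sub.loc[sub["t"] < 2, "t"].nunique()
    post = sub.loc[sub["t"] >= 2, "t"].nunique()
    if pre < 2 or post < 2:
        raise ValueError(
            f"need >= 2 distinct pre and post years, got {pre} pre / {post} post"
        )

    X = design_matrix(sub["t"].to_numpy(), sub["arm"].to_numpy())
    y = sub[channel].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns that add no rank, scanning left to right
        bad, r_sofar = [], 0
        for i in range(X.shape[1]):
            r_new = np.linalg.matrix_rank(X[:, : i + 1])
            if r_new == r_sofar:
                bad.append(DESIGN_COLUMNS[i])
            r_sofar = r_new
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")

    ols = sm.OLS(y, X)
    res = ols.fit()
    se_conv = res.bse.copy()
    if compute_cluster_se:
        res_cl = res.get_robustcov_results(
            cov_type="cluster", groups=sub["patient_id"].to_numpy()
        )
        se_cl = np.asarray(res_cl.bse)
        pvals = (
            np.asarray(res_cl.pvalues) if se_mode == "cluster-robust" else res.pvalues
        )
    else:
        se_cl = np.full(8, np.nan)
        pvals = np.asarray(res.pvalues)
        se_mode = "conventional"
    return ITSFit(
        channel=channel,
        coefficients=CoefficientVector.from_array(res.params),
        se_conventional=np.asarray(se_conv),
        se_cluster=se_cl,
        pvalues=np.asarray(pvals),
        n_person_years=len(sub),
        se_mode=se_mode,
    )


def predicted_rate(fit: ITSFit, t: int, a: int) -> float:
    """Model-implied mean annual count at relative year ``t`` for arm ``a``."""
    return float(design_row(t, a) @ fit.coefficients.as_array())


def recovery_study(
    coeffs: CoefficientVector,
    n_per_arm: int,
    years,
    n_replicates: int,
    seed: int,
    mean_floor: float = 0.01,
) -> pd.DataFrame:
    """Monte-Carlo coefficient recovery: simulate matched panels from
    ``coeffs`` and refit; one row of estimates per replicate."""
    from portal_its.synthetic_emr import simulate_panel

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        panel = simulate_panel(coeffs, n_per_arm, years, rng, mean_floor)
        fit = fit_its(panel, "count", compute_cluster_se=False)
        rows.append(fit.coefficients.as_array())
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)
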