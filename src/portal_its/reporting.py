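"""Descriptive outputs: workload arithmetic, running-average registration
cohort curves, overlay plots, and file rendering.

All plotted numbers are materialized as CSV first; the figures are
side-effect-only so nothing downstream ever reads pixels.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REGISTRATION_GROUPS = {
    "2011-2012": (2011, 2012),
    "2013-2014": (2013, 2014),
    "2015-2016": (2015, 2016),
    "2017-2018": (2017, 2018),
}


@dataclass(frozen=True)
class WorkloadEstimate:
    mean_min_per_message: float
    messages_per_patient_year: float
    min_per_patient_year: float


def mean_message_time(minutes) -> float:
    """Arithmetic mean message-handling time, rounded to 2 decimals."""
    arr = np.asarray(list(minutes), dtype=float)
    if arr.size == 0:
        raise ValueError("no messages")
    if (arr < 0).any():
        raise ValueError("negative duration")
    return round(float(arr.mean()), 2)


def workload_estimate(
    mean_min_per_message: float, messages_per_patient_year: float
) -> WorkloadEstimate:
    """Annual provider minutes per portal patient (1-decimal product)."""
    if mean_min_per_message < 0 or messages_per_patient_year < 0:
        raise ValueError("inputs must be nonnegative")
    return WorkloadEstimate(
        mean_min_per_message=mean_min_per_message,
        messages_per_patient_year=messages_per_patient_year,
        min_per_patient_year=round(mean_min_per_message * messages_per_patient_year, 1),
    )


def messages_per_patient_year(
    messages: pd.DataFrame,
    patients: pd.DataFrame,
    year: int,
    denominator: str = "registered",
) -> float:
    """Provider-sent messages in ``year`` per portal patient.

    ``denominator='registered'`` counts every patient registered by the end
    of the year; ``'active'`` counts only patients who received a message.
    """
    sent = pd.to_datetime(messages["sent_date"])
    in_year = messages[(sent.dt.year == year)]
    if denominator == "registered":
        reg = pd.to_datetime(patients["portal_date"])
        denom = int((reg <= pd.Timestamp(year=year, month=12, day=31)).sum())
    elif denominator == "active":
        denom = int(in_year["patient_id"].nunique())
    else:
        raise ValueError(f"bad denominator {denominator!r}")
    if denom == 0:
        raise ValueError(f"no portal patients in denominator for {year}")
    return len(in_year) / denom


def running_average(series: dict, window: int = 3) -> dict:
    """Centered moving average; boundary years use available neighbors."""
    if window != 3:
        raise NotImplementedError("only the 3-year centered window is supported")
    years = sorted(series)
    out = {}
    for y in years:
        vals = [series[n] for n in (y - 1, y, y + 1) if n in series]
        out[y] = float(np.mean(vals))
    return out


def registration_cohort_series(
    panel: pd.DataFrame,
    registration_years: pd.Series,
    groups: dict | None = None,
    channels=("md", "nppa", "tc"),
    window: int = 3,
) -> pd.DataFrame:
    """Smoothed mean visits per calendar year by registration-year group.

    ``panel`` holds portal-arm person-years with a ``calendar_year``
    column; ``registration_years`` maps patient_id -> registration year.
    Returns tidy rows (group, channel, calendar_year, mean_visits,
    smoothed).
    """
    groups = dict(groups or DEFAULT_REGISTRATION_GROUPS)
    portal = panel[panel["arm"] == 1].copy()
    portal["reg_year"] = portal["patient_id"].map(registration_years)
    rows = []
    for name, (lo, hi) in groups.items():
        sub = portal[(portal["reg_year"] >= lo) & (portal["reg_year"] <= hi)]
        if sub.empty:
            logger.warning("registration group %s is empty; omitted", name)
            continue
        for ch in channels:
            means = sub.groupby("calendar_year")[ch].mean().to_dict()
            smooth = running_average(means, window)
            for year in sorted(means):
                rows.append(
                    {
                        "group": name,
                        "channel": ch,
                        "calendar_year": year,
                        "mean_visits": means[year],
                        "smoothed": smooth[year],
                    }
                )
    return pd.DataFrame(
        rows, columns=["group", "channel", "calendar_year", "mean_visits", "smoothed"]
    )


def observed_vs_fitted(panel: pd.DataFrame, fits: dict) -> pd.DataFrame:
    """Per (channel, arm, relative year): observed mean count and the ITS
    prediction (NaN in the excluded years)."""
    from portal_its.its import predicted_rate

    rows = []
    for ch, fit in fits.items():
        for (a, t), g in panel.groupby(["arm", "t"]):
            try:
                pred = predicted_rate(fit, int(t), int(a))
            except ValueError:
                pred = float("nan")
            rows.append(
                {
                    "channel": ch,
                    "arm": int(a),
                    "t": int(t),
                    "observed_mean": float(g[ch].mean()),
                    "fitted": pred,
                }
            )
    return pd.DataFrame(rows, columns=["channel", "arm", "t", "observed_mean", "fitted"])


def render_outputs(
    out_dir,
    balance: pd.DataFrame | None = None,
    matches: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    fits: dict | None = None,
    cohort_curves: pd.DataFrame | None = None,
    workload: WorkloadEstimate | None = None,
    make_plots: bool = True,
) -> dict:
    """Write every available artifact to ``out_dir``; returns a manifest of
    written files and a ``complete`` flag (False when the ITS fit was
    missing so overlay outputs were skipped)."""
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _path(name):
        return os.path.join(out_dir, name)

    if balance is not None:
        balance.to_csv(_path("balance.csv"))
        written.append("balance.csv")
    if matches is not None:
        matches.to_csv(_path("matches.csv"), index=False)
        written.append("matches.csv")
    if panel is not None:
        panel.to_csv(_path("panel.csv"), index=False)
        written.append("panel.csv")
    if workload is not None:
        with open(_path("workload.json"), "w") as fh:
            json.dump(workload.__dict__, fh, indent=2, sort_keys=True)
        written.append("workload.json")
    if cohort_curves is not None and len(cohort_curves):
        cohort_curves.to_csv(_path("cohort_curves.csv"), index=False)
        written.append("cohort_curves.csv")

    complete = True
    if fits:
        report = {ch: fit.report() for ch, fit in fits.items()}
        with open(_path("its_fit.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        written.append("its_fit.json")
        if panel is not None:
            ovf = observed_vs_fitted(panel, fits)
            ovf.to_csv(_path("its_overlay.csv"), index=False)
            written.append("its_overlay.csv")
            if make_plots:
                written.extend(_plot_overlays(ovf, out_dir))
    else:
        logger.warning("no ITS fits available; overlay outputs skipped")
        complete = False
    return {"files": written, "complete": complete}


def _plot_overlays(ovf: pd.DataFrame, out_dir) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for ch, g in ovf.groupby("channel"):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for a, label, color in ((0, "control", "tab:blue"), (1, "portal", "tab:red")):
            sub = g[g["arm"] == a].sort_values("t")
            ax.plot(sub["t"], sub["observed_mean"], "o", color=color, label=f"{label} observed")
            fitted = sub.dropna(subset=["fitted"])
            pre = fitted[fitted["t"] < 2]
            post = fitted[fitted["t"] >= 2]
            ax.plot(pre["t"], pre["fitted"], "-", color=color, alpha=0.7)
            ax.plot(post["t"], post["fitted"], "-", color=color, alpha=0.7)
        ax.axvline(0, color="gray", ls=":", lw=1)
        ax.set_xlabel("year relative to index date")
        ax.set_ylabel(f"mean annual {ch} encounters")
        ax.legend(frameon=False, fontsize=8)
        name = f"its_overlay_{ch}.png"
        fig.savefig(os.path.join(out_dir, name), dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(name)
    return written
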