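"""Propensity-score estimation, caliper/gap candidate construction, and the
iterative unique-first greedy one-to-one allocation, with balance
diagnostics.

Allocation rules, applied repeatedly until exhaustion:

1. any portal record with exactly one remaining candidate control is
   matched to it;
2. any control patient who remains a candidate of exactly one portal record
   is matched to that record;
3. when neither rule fires, the globally closest remaining
   (portal, control) pair by propensity distance is matched.

Both parties are removed from all candidate sets after every match, so the
result is matching without replacement and is deterministic: ties break on
propensity distance, then index-date gap, then patient id.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from portal_its.covariates import PS_COVARIATES

DEFAULT_CALIPER_MULT = 0.2
DEFAULT_MAX_GAP_DAYS = 366


class SeparationError(RuntimeError):
    """Raised when the propensity logistic regression is degenerate."""


@dataclass
class PropensityModel:
    coefficients: pd.Series  # term -> estimate
    scores: pd.Series  # record key -> fitted probability
    n_fitted: int
    covariate_names: tuple

    def logit_scores(self) -> pd.Series:
        s = self.scores
        return np.log(s / (1.0 - s))


@dataclass(frozen=True)
class MatchedPair:
    portal_record: str
    control_record: str
    portal_patient: str
    control_patient: str
    ps_distance: float
    gap_days: int
    allocation_round: int


def record_key(row) -> str:
    """Stable key for one index record: patient id + index year."""
    return f"{row['patient_id']}@{int(row['index_year'])}"


def _separating_covariate(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        hi = v[y == 1]
        lo = v[y == 0]
        if len(hi) and len(lo) and (hi.min() > lo.max() or lo.min() > hi.max()):
            return col
    return None


def fit_propensity(
    covariates: pd.DataFrame,
    covariate_names=PS_COVARIATES,
) -> PropensityModel:
    """Maximum-likelihood logistic regression of portal membership.

    ``covariates`` is the stacked index-record table (one row per portal
    record and per control person-year record) with an ``arm`` column.
    Income and education never enter the model.
    """
    df = covariates.copy()
    if "female" not in df.columns and "sex" in df.columns:
        df["female"] = df["sex"] == "female"
    y = (df["arm"] == "portal").to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("outcome label is constant; cannot fit propensity model")
    X = df[list(covariate_names)].astype(float)
    const = X.columns[X.nunique() <= 1]
    if len(const):
        raise SeparationError(f"degenerate covariates (constant): {list(const)}")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        sep = _separating_covariate(X, y)
        raise SeparationError(
            f"propensity fit failed ({exc}); separating covariate: {sep}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        sep = _separating_covariate(X, y)
        if sep is not None:
            raise SeparationError(f"perfect separation on covariate {sep!r}")
    scores = pd.Series(
        np.asarray(res.predict(Xc)), index=df.apply(record_key, axis=1).to_numpy()
    )
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    return PropensityModel(
        coefficients=pd.Series(res.params.to_numpy(), index=Xc.columns),
        scores=scores,
        n_fitted=len(df),
        covariate_names=tuple(covariate_names),
    )


def candidate_sets(
    portal_records: pd.DataFrame,
    control_records: pd.DataFrame,
    model: PropensityModel,
    caliper_mult: float = DEFAULT_CALIPER_MULT,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    caliper_scale: str = "logit",
) -> dict[str, dict[str, tuple[float, int]]]:
    """Candidate controls per portal record.

    A control person-year is a candidate when its propensity distance is
    within ``caliper_mult`` pooled-SD units (logit scale by default) and its
    index date is within ``max_gap_days`` of the portal index date.  Each
    distinct control patient contributes at most one record per portal
    record — the one with the closest score.

    Returns ``{portal_key: {control_key: (ps_distance, gap_days)}}``.
    """
    p_keys = portal_records.apply(record_key, axis=1).to_numpy()
    c_keys = control_records.apply(record_key, axis=1).to_numpy()
    if caliper_scale == "logit":
        all_scores = model.logit_scores()
    elif caliper_scale == "raw":
        all_scores = model.scores
    else:
        raise ValueError(f"caliper_scale must be 'logit' or 'raw', got {caliper_scale!r}")
    p_s = all_scores.loc[p_keys].to_numpy(dtype=float)
    c_s = all_scores.loc[c_keys].to_numpy(dtype=float)
    pooled_sd = float(np.std(np.concatenate([p_s, c_s]), ddof=1))
    caliper = caliper_mult * pooled_sd

    p_dates = pd.to_datetime(portal_records["index_date"]).to_numpy()
    c_dates = pd.to_datetime(control_records["index_date"]).to_numpy()
    c_pids = control_records["patient_id"].to_numpy()

    order = np.argsort(c_s, kind="stable")
    c_s_sorted = c_s[order]

    out: dict[str, dict[str, tuple[float, int]]] = {}
    gap_td = np.timedelta64(max_gap_days, "D")
    for i, pk in enumerate(p_keys):
        lo = np.searchsorted(c_s_sorted, p_s[i] - caliper, side="left")
        hi = np.searchsorted(c_s_sorted, p_s[i] + caliper, side="right")
        cand_idx = order[lo:hi]
        if len(cand_idx):
            gaps = np.abs(c_dates[cand_idx] - p_dates[i])
            cand_idx = cand_idx[gaps <= gap_td]
        best: dict[str, tuple[float, int, str]] = {}
        for j in cand_idx:
            dist = abs(float(c_s[j] - p_s[i]))
            gap = int(abs((c_dates[j] - p_dates[i]) / np.timedelta64(1, "D")))
            key = (dist, gap, c_keys[j])
            pid = c_pids[j]
            if pid not in best or key < best[pid]:
                best[pid] = key
        out[pk] = {ck: (dist, gap) for dist, gap, ck in best.values()}
    return out


def allocate_matches(
    candidates: dict[str, dict[str, tuple[float, int]]],
) -> tuple[list[MatchedPair], list[str]]:
    """Run the iterative unique-first allocation.

    Returns (matched pairs, unmatched portal keys).  Unmatched portal
    records are reported, never an error.
    """
    sets = {p: dict(cs) for p, cs in candidates.items()}
    membership: dict[str, set[str]] = {}
    patient_records: dict[str, set[str]] = {}
    for p, cs in sets.items():
        for c in cs:
            membership.setdefault(c, set()).add(p)
            patient_records.setdefault(c.rsplit("@", 1)[0], set()).add(c)

    heap: list[tuple[float, int, str, str]] = [
        (dist, gap, p, c) for p, cs in sets.items() for c, (dist, gap) in cs.items()
    ]
    heapq.heapify(heap)

    pairs: list[MatchedPair] = []
    matched_portals: set[str] = set()
    matched_controls: set[str] = set()
    rnd = 0

    def control_patient(ck: str) -> str:
        return ck.rsplit("@", 1)[0]

    # lazily-validated queues of rule-1 portals / rule-2 controls
    r1 = [p for p, cs in sets.items() if len(cs) == 1]
    heapq.heapify(r1)
    r2 = [c for c, ps in membership.items() if len(ps) == 1]
    heapq.heapify(r2)

    def commit(p: str, c: str, dist: float, gap: int) -> None:
        nonlocal rnd
        rnd += 1
        pairs.append(
            MatchedPair(
                portal_record=p,
                control_record=c,
                portal_patient=p.rsplit("@", 1)[0],
                control_patient=control_patient(c),
                ps_distance=dist,
                gap_days=gap,
                allocation_round=rnd,
            )
        )
        matched_portals.add(p)
        matched_controls.add(control_patient(c))
        for cc in sets.pop(p, {}):
            mem = membership.get(cc)
            if mem is not None:
                mem.discard(p)
                if len(mem) == 1:
                    heapq.heappush(r2, cc)
        # the matched control patient leaves every remaining set
        for ck in patient_records.pop(control_patient(c), set()):
            for pp in membership.pop(ck, set()):
                cs = sets.get(pp)
                if cs is not None:
                    cs.pop(ck, None)
                    if len(cs) == 1:
                        heapq.heappush(r1, pp)

    while True:
        matched = False
        while r1:
            p = heapq.heappop(r1)
            if p in sets and len(sets[p]) == 1:
                c, (dist, gap) = next(iter(sets[p].items()))
                commit(p, c, dist, gap)
                matched = True
                break
        if matched:
            continue
        while r2:
            c = heapq.heappop(r2)
            if c in membership and len(membership[c]) == 1:
                p = next(iter(membership[c]))
                dist, gap = sets[p][c]
                commit(p, c, dist, gap)
                matched = True
                break
        if matched:
            continue
        # rule 3: globally closest remaining pair
        best = None
        while heap:
            dist, gap, p, c = heap[0]
            if p not in sets or c not in sets.get(p, {}):
                heapq.heappop(heap)
                continue
            best = heapq.heappop(heap)
            break
        if best is None:
            break
        dist, gap, p, c = best
        commit(p, c, dist, gap)

    unmatched = sorted(set(candidates) - matched_portals)
    return pairs, unmatched


def match(
    covariates: pd.DataFrame,
    caliper_mult: float = DEFAULT_CALIPER_MULT,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    caliper_scale: str = "logit",
    ps_covariates=PS_COVARIATES,
):
    """Fit the propensity model and run the full matching pipeline.

    Returns (model, pairs, unmatched portal keys).
    """
    model = fit_propensity(covariates, ps_covariates)
    portal = covariates[covariates["arm"] == "portal"]
    control = covariates[covariates["arm"] == "control"]
    cands = candidate_sets(
        portal, control, model, caliper_mult, max_gap_days, caliper_scale
    )
    pairs, unmatched = allocate_matches(cands)
    return model, pairs, unmatched


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "portal_record": p.portal_record,
                "control_record": p.control_record,
                "portal_patient": p.portal_patient,
                "control_patient": p.control_patient,
                "ps_distance": p.ps_distance,
                "gap_days": p.gap_days,
                "allocation_round": p.allocation_round,
            }
            for p in pairs
        ],
        columns=[
            "portal_record",
            "control_record",
            "portal_patient",
            "control_patient",
            "ps_distance",
            "gap_days",
            "allocation_round",
        ],
    )


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def standardized_difference(summary_a, summary_b, kind: str) -> float:
    """Scale-free between-group difference.

    ``continuous``: summaries are (mean, sd); ``binary``: proportions.
    Returns 0 when both variances vanish and the means agree.
    """
    if kind == "binary":
        p1, p2 = float(summary_a), float(summary_b)
        for p in (p1, p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion outside [0, 1]: {p}")
        num = abs(p1 - p2)
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    elif kind == "continuous":
        m1, s1 = summary_a
        m2, s2 = summary_b
        num = abs(m1 - m2)
        denom = np.sqrt((s1**2 + s2**2) / 2.0)
    else:
        raise ValueError(f"kind must be 'continuous' or 'binary', got {kind!r}")
    if denom == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / denom)


_BINARY_COVS = ("female", "rostered", "dx_cad", "dx_chf", "dx_copd", "dx_dm", "dx_htn")
_CONTINUOUS_COVS = (
    "age_years",
    "md_visits_12m",
    "nppa_visits_12m",
    "tc_calls_12m",
    "distinct_meds_12m",
)


def _smd_frame(portal: pd.DataFrame, control: pd.DataFrame) -> pd.Series:
    out = {}
    for cov in _BINARY_COVS:
        out[cov] = standardized_difference(
            portal[cov].mean(), control[cov].mean(), "binary"
        )
    for cov in _CONTINUOUS_COVS:
        out[cov] = standardized_difference(
            (portal[cov].mean(), portal[cov].std(ddof=1)),
            (control[cov].mean(), control[cov].std(ddof=1)),
            "continuous",
        )
    return pd.Series(out)


def quintile_groups(scores: pd.Series) -> pd.Series:
    """Pooled-sample propensity quintile labels 0-4."""
    return pd.qcut(scores.rank(method="first"), 5, labels=False).astype(int)


def balance_table(
    covariates: pd.DataFrame,
    pairs: list[MatchedPair],
    model: PropensityModel,
) -> pd.DataFrame:
    """Pre/post-matching standardized differences plus score summaries."""
    if not pairs:
        raise ValueError("no matched pairs")
    keyed = covariates.copy()
    keyed["record"] = keyed.apply(record_key, axis=1)
    keyed = keyed.set_index("record")
    keyed["ps"] = model.scores

    pre_p = keyed[keyed["arm"] == "portal"]
    pre_c = keyed[keyed["arm"] == "control"]
    post_p = keyed.loc[[p.portal_record for p in pairs]]
    post_c = keyed.loc[[p.control_record for p in pairs]]

    tbl = pd.DataFrame(
        {
            "pre_portal_mean": pre_p[list(_BINARY_COVS + _CONTINUOUS_COVS)].mean(),
            "pre_control_mean": pre_c[list(_BINARY_COVS + _CONTINUOUS_COVS)].mean(),
            "pre_smd": _smd_frame(pre_p, pre_c),
            "post_portal_mean": post_p[list(_BINARY_COVS + _CONTINUOUS_COVS)].mean(),
            "post_control_mean": post_c[list(_BINARY_COVS + _CONTINUOUS_COVS)].mean(),
            "post_smd": _smd_frame(post_p, post_c),
        }
    )
    ps_row = pd.DataFrame(
        {
            "pre_portal_mean": [pre_p["ps"].mean()],
            "pre_control_mean": [pre_c["ps"].mean()],
            "pre_smd": [
                standardized_difference(
                    (pre_p["ps"].mean(), pre_p["ps"].std(ddof=1)),
                    (pre_c["ps"].mean(), pre_c["ps"].std(ddof=1)),
                    "continuous",
                )
            ],
            "post_portal_mean": [post_p["ps"].mean()],
            "post_control_mean": [post_c["ps"].mean()],
            "post_smd": [
                standardized_difference(
                    (post_p["ps"].mean(), post_p["ps"].std(ddof=1)),
                    (post_c["ps"].mean(), post_c["ps"].std(ddof=1)),
                    "continuous",
                )
            ],
        },
        index=["propensity_score"],
    )
    return pd.concat([ps_row, tbl])
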