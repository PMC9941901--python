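import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from portal_its import matching as M
from portal_its.matching import (
    MatchedPair,
    PropensityModel,
    SeparationError,
    allocate_matches,
    candidate_sets,
    fit_propensity,
    quintile_groups,
    standardized_difference,
)


def _records(rows):
    return pd.DataFrame(rows)


def _model(scores: dict) -> PropensityModel:
    s = pd.Series(scores, dtype=float)
    return PropensityModel(
        coefficients=pd.Series(dtype=float), scores=s, n_fitted=len(s),
        covariate_names=(),
    )


class TestFitPropensity:
    def _frame(self, x, label, n):
        return pd.DataFrame(
            {
                "patient_id": [f"Q{i}" for i in range(n)],
                "index_year": 2013,
                "arm": label,
                "x": x,
            }
        )

    def test_single_binary_covariate_log_odds_ratio(self):
        # 2x2 table: portal (x=1: 30, x=0: 10); control (x=1: 20, x=0: 40)
        parts = []
        k = 0
        for arm, x, n in [("portal", 1, 30), ("portal", 0, 10), ("control", 1, 20), ("control", 0, 40)]:
            f = self._frame([x] * n, arm, n)
            f["patient_id"] = [f"Q{k + i}" for i in range(n)]
            k += n
            parts.append(f)
        df = pd.concat(parts, ignore_index=True)
        model = fit_propensity(df, covariate_names=("x",))
        log_or = np.log((30 / 10) / (20 / 40))
        assert model.coefficients["x"] == pytest.approx(log_or, abs=1e-6)

    def test_null_covariates_give_flat_scores(self, rng):
        n = 4000
        df = pd.DataFrame(
            {
                "patient_id": [f"Q{i}" for i in range(n)],
                "index_year": 2013,
                "arm": np.where(rng.random(n) < 0.3, "portal", "control"),
                "x": rng.normal(size=n),
            }
        )
        model = fit_propensity(df, covariate_names=("x",))
        frac = (df["arm"] == "portal").mean()
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(model.scores.mean() - frac) < 3 * se
        assert model.scores.std() < 0.05

    def test_constant_label_rejected(self):
        df = self._frame([0, 1] * 10, "portal", 20)
        with pytest.raises(SeparationError):
            fit_propensity(df, covariate_names=("x",))

    def test_perfect_separation_names_covariate(self):
        df = pd.concat(
            [self._frame([1.0] * 20, "portal", 20), self._frame([0.0] * 20, "control", 20)],
            ignore_index=True,
        )
        df["patient_id"] = [f"Q{i}" for i in range(40)]
        with pytest.raises(SeparationError, match="x"):
            fit_propensity(df, covariate_names=("x",))


class TestCandidateSets:
    def _portal(self, key="P1@2013", date="2013-05-01"):
        pid, year = key.split("@")
        return _records(
            [{"patient_id": pid, "index_year": int(year), "index_date": pd.Timestamp(date)}]
        )

    def _controls(self, rows):
        return _records(
            [
                {"patient_id": pid, "index_year": y, "index_date": pd.Timestamp(f"{y}-07-01")}
                for pid, y in rows
            ]
        )

    def test_identical_scores_same_year(self):
        model = _model({"P1@2013": 0.4, "C1@2013": 0.4, "C2@2016": 0.4})
        cands = candidate_sets(
            self._portal(), self._controls([("C1", 2013), ("C2", 2016)]), model
        )
        assert set(cands["P1@2013"]) == {"C1@2013"}  # C2 fails the date gap

    def test_huge_score_gap_excluded(self):
        model = _model({"P1@2013": 0.99, "C1@2013": 0.01, "C2@2013": 0.985})
        cands = candidate_sets(
            self._portal(), self._controls([("C1", 2013), ("C2", 2013)]), model
        )
        assert set(cands["P1@2013"]) == {"C2@2013"}

    def test_one_record_per_control_patient(self):
        # the same control patient is in range in 2013 and 2014 (portal
        # index 2013-08-01 is within 366 days of both July 1 dates); only
        # the closer-scoring record is retained
        model = _model({"P1@2013": 0.40, "C1@2013": 0.41, "C1@2014": 0.405})
        cands = candidate_sets(
            self._portal(date="2013-08-01"),
            self._controls([("C1", 2013), ("C1", 2014)]),
            model,
            caliper_mult=10.0,  # wide caliper: isolate the dedupe rule
        )
        assert set(cands["P1@2013"]) == {"C1@2014"}

    def test_raw_scale_option(self):
        model = _model({"P1@2013": 0.4, "C1@2013": 0.45})
        raw = candidate_sets(
            self._portal(), self._controls([("C1", 2013)]), model, caliper_scale="raw"
        )
        assert isinstance(raw["P1@2013"], dict)
        with pytest.raises(ValueError):
            candidate_sets(self._portal(), self._controls([("C1", 2013)]), model,
                           caliper_scale="bogus")


class TestAllocateMatches:
    def _cands(self, mapping):
        # distances chosen so C-ids order by their numeric suffix
        out = {}
        for p, cs in mapping.items():
            out[p] = {c: (0.01 * int(c[1]), 100) for c in cs}
        return out

    def test_unique_first_then_collapse(self):
        pairs, unmatched = allocate_matches(self._cands({"P1": {"C1"}, "P2": {"C1", "C2"}}))
        assert {(p.portal_record, p.control_record) for p in pairs} == {
            ("P1", "C1"), ("P2", "C2"),
        }
        assert unmatched == []

    def test_unique_portal_then_remaining(self):
        pairs, _ = allocate_matches(self._cands({"P1": {"C1", "C2"}, "P2": {"C2"}}))
        assert {(p.portal_record, p.control_record) for p in pairs} == {
            ("P2", "C2"), ("P1", "C1"),
        }

    def test_empty_set_reported_not_error(self):
        pairs, unmatched = allocate_matches({"P1": {}})
        assert pairs == [] and unmatched == ["P1"]

    def test_closest_distance_breaks_ambiguity(self):
        cands = {
            "P1": {"C1": (0.05, 10), "C2": (0.01, 10)},
            "P2": {"C1": (0.02, 10), "C2": (0.03, 10)},
        }
        pairs, _ = allocate_matches(cands)
        got = {(p.portal_record, p.control_record) for p in pairs}
        assert got == {("P1", "C2"), ("P2", "C1")}

    def test_no_double_matching(self, rng):
        # random bipartite candidate structure: uniqueness invariants hold
        portals = [f"P{i}@2013" for i in range(40)]
        controls = [f"C{i}@2013" for i in range(30)]
        cands = {
            p: {
                c: (float(rng.random()), int(rng.integers(0, 366)))
                for c in rng.choice(controls, size=rng.integers(0, 6), replace=False)
            }
            for p in portals
        }
        pairs, unmatched = allocate_matches(cands)
        assert len({p.portal_record for p in pairs}) == len(pairs)
        assert len({p.control_patient for p in pairs}) == len(pairs)
        assert len(pairs) + len(unmatched) == len(portals)

    def test_order_invariance(self, rng):
        controls = [f"C{i}@2013" for i in range(25)]
        cands = {
            f"P{i}@2013": {
                c: (round(float(rng.random()), 6), int(rng.integers(0, 366)))
                for c in rng.choice(controls, size=rng.integers(1, 8), replace=False)
            }
            for i in range(30)
        }
        pairs1, _ = allocate_matches(cands)
        shuffled = {k: dict(reversed(list(v.items()))) for k, v in reversed(list(cands.items()))}
        pairs2, _ = allocate_matches(shuffled)
        key = lambda ps: sorted((p.portal_record, p.control_record) for p in ps)
        assert key(pairs1) == key(pairs2)


class TestStandardizedDifference:
    def test_sex_from_baseline_table(self):
        assert round(standardized_difference(0.598, 0.490, "binary"), 2) == 0.22

    def test_rostered_from_baseline_table(self):
        assert round(standardized_difference(0.988, 0.945, "binary"), 2) == 0.24

    def test_equal_groups_zero(self):
        assert standardized_difference((1.0, 2.0), (1.0, 2.0), "continuous") == 0.0

    def test_zero_variance_equal_means(self):
        assert standardized_difference((3.0, 0.0), (3.0, 0.0), "continuous") == 0.0

    def test_zero_variance_unequal_means_inf(self):
        assert standardized_difference(1.0, 0.0, "binary") == float("inf")

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            standardized_difference(1.2, 0.5, "binary")

    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_nonnegative_and_symmetric(self, p1, p2):
        d = standardized_difference(p1, p2, "binary")
        assert d >= 0
        assert d == standardized_difference(p2, p1, "binary")


class TestQuintiles:
    def test_pooled_quintiles_near_equal(self, rng):
        scores = pd.Series(rng.random(1003))
        groups = quintile_groups(scores)
        sizes = groups.value_counts()
        assert set(groups) == {0, 1, 2, 3, 4}
        assert sizes.max() - sizes.min() <= 1


@pytest.fixture(scope="module")
def matched(small_bundle):
    from portal_its.cohort import build_cohort
    from portal_its.covariates import build_covariates

    res = build_cohort(small_bundle)
    covs = build_covariates(
        res.to_frame(), small_bundle.patients, small_bundle.encounters,
        small_bundle.prescriptions,
    )
    model, pairs, unmatched = M.match(covs)
    return covs, model, pairs, unmatched


class TestEndToEndMatching:
    def test_constraints_reassertable(self, matched):
        covs, model, pairs, _ = matched
        logit = model.logit_scores()
        caliper = 0.2 * logit.std(ddof=1)
        keyed = covs.copy()
        keyed["record"] = keyed.apply(M.record_key, axis=1)
        dates = keyed.set_index("record")["index_date"]
        for p in pairs:
            assert abs(logit[p.portal_record] - logit[p.control_record]) <= caliper + 1e-12
            gap = abs((pd.Timestamp(dates[p.portal_record]) - pd.Timestamp(dates[p.control_record])).days)
            assert gap <= 366
            assert gap == p.gap_days

    def test_uniqueness(self, matched):
        _, _, pairs, _ = matched
        assert len({p.portal_patient for p in pairs}) == len(pairs)
        assert len({p.control_patient for p in pairs}) == len(pairs)

    def test_balance_improves_on_confounded_data(self, matched):
        covs, model, pairs, _ = matched
        bal = M.balance_table(covs, pairs, model)
        strong = bal[bal["pre_smd"] > 0.1]
        assert (strong["post_smd"] < strong["pre_smd"]).all()

    def test_twin_matching_smd_zero(self):
        # identical covariate rows in both arms: post-match SMDs all zero
        base = {
            "age_years": 50.0, "female": True, "rostered": True,
            "dx_cad": False, "dx_chf": False, "dx_copd": False,
            "dx_dm": False, "dx_htn": True,
            "md_visits_12m": 2, "nppa_visits_12m": 1, "tc_calls_12m": 0,
            "distinct_meds_12m": 3,
        }
        rows = []
        rng = np.random.default_rng(3)
        for i in range(60):
            tweak = dict(base, age_years=float(30 + i % 7), md_visits_12m=int(i % 4),
                         female=bool(i % 2))
            for arm, pid in (("portal", f"P{i}"), ("control", f"C{i}")):
                rows.append(
                    {"patient_id": pid, "arm": arm, "index_year": 2013,
                     "index_date": pd.Timestamp("2013-07-01"), **tweak}
                )
        covs = pd.DataFrame(rows)
        covs["age_years"] += rng.normal(0, 1e-9, len(covs))  # avoid exact separation
        model, pairs, _ = M.match(covs, ps_covariates=("age_years", "female", "md_visits_12m"))
        bal = M.balance_table(covs, pairs, model)
        assert (bal["post_smd"].drop("propensity_score") < 1e-6).all()
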