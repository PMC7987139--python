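"""Partly conditional Cox fitter: partial-likelihood oracles, sandwich
variance algebra, reporting, interactions, and proportional-hazards
diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from screenrisk import pc_cox
from screenrisk.pc_cox import (
    CovariateSpec,
    ModelFit,
    breslow_baseline,
    build_design,
    fit_pc_cox,
    hazard_ratio_table,
    ph_diagnostics,
    robust_sandwich,
)
from conftest import stacked_frame

BINARY_SPEC = CovariateSpec(include_age=False, factors=("family_history",))
NULL_SPEC = CovariateSpec(include_age=False, factors=())


def _binary_records(times, x, events, ids=None):
    n = len(times)
    return stacked_frame(
        ids if ids is not None else [f"w{i}" for i in range(n)],
        [0.0] * n, [55.0] * n, list(x), ["none"] * n, ["none"] * n,
        list(times), list(events),
    )


def _hand_partial_loglik(b, times, x, events, ties="breslow"):
    """Direct partial likelihood for a single binary covariate (oracle)."""
    ll = 0.0
    order = np.argsort(times)
    t, xx, ee = np.asarray(times)[order], np.asarray(x)[order], np.asarray(events)[order]
    for tk in np.unique(t[ee == 1]):
        d = (t == tk) & (ee == 1)
        at_risk = t >= tk
        w = np.exp(b * xx)
        tied = w[d]
        ll += b * xx[d].sum()
        for l in range(d.sum()):
            frac = l / d.sum() if ties == "efron" else 0.0
            ll -= np.log(w[at_risk].sum() - frac * tied.sum())
    return ll


class TestFit:
    def test_symmetric_data_gives_zero_beta(self):
        # dataset invariant under swapping the covariate's two levels
        times = [1, 2, 3, 1, 2, 3]
        x = [0, 0, 0, 1, 1, 1]
        df = _binary_records(times, x, [1] * 6)
        fit = fit_pc_cox(df, BINARY_SPEC)
        assert abs(fit.beta.iloc[0]) < 1e-10

    def test_six_record_toy_matches_grid_scan(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        x = [1, 0, 1, 1, 0, 0]
        events = [1, 1, 0, 1, 1, 1]
        df = _binary_records(times, x, events)
        fit = fit_pc_cox(df, BINARY_SPEC, ties="efron")
        res = minimize_scalar(
            lambda b: -_hand_partial_loglik(b, times, x, events, ties="efron"),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.beta.iloc[0] == pytest.approx(res.x, abs=1e-6)

    def test_score_norm_and_loglik_dominates_null(self, fit20, stacked20):
        assert fit20.final_grad_norm < 1e-8
        # log partial likelihood at beta exceeds its value at beta = 0
        X, _ = build_design(stacked20, fit20.spec)
        data = pc_cox._CoxData(
            X,
            stacked20.residual_time.to_numpy(float),
            stacked20.event.to_numpy(int),
            "efron",
        )
        ll0 = data.stats(np.zeros(X.shape[1]))[0]
        assert fit20.loglik >= ll0

    def test_no_events_rejected(self):
        df = _binary_records([1, 2], [0, 1], [0, 0])
        with pytest.raises(ValueError):
            fit_pc_cox(df, BINARY_SPEC)

    def test_separation_is_flagged(self):
        # the covariate perfectly orders events before censorings
        df = _binary_records([1, 2, 3, 9, 9, 9], [1, 1, 1, 0, 0, 0],
                             [1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_pc_cox(df, BINARY_SPEC)
        assert any("separation" in w for w in fit.warnings_)


class TestSandwich:
    def test_covariances_positive_semidefinite(self, fit20):
        for cov in (fit20.robust_cov, fit20.naive_cov):
            assert (np.linalg.eigvalsh(cov.to_numpy()) > -1e-10).all()

    def test_independent_records_robust_close_to_naive(self):
        rng = np.random.default_rng(12)
        n = 4000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
        c = rng.exponential(12, n)
        df = _binary_records(np.minimum(t, c), x, (t <= c).astype(int))
        fit = fit_pc_cox(df, BINARY_SPEC)
        assert fit.robust_se.iloc[0] / fit.naive_se.iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_within_cluster_duplication_algebra(self):
        """Doubling every record within its cluster leaves beta and the
        clustered sandwich unchanged while halving the naive variance
        (score-doubling algebra; Breslow ties keep the likelihood exactly
        proportional)."""
        rng = np.random.default_rng(5)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.2 * np.exp(0.4 * x)))
        c = rng.exponential(8, n)
        df = _binary_records(np.minimum(t, c), x, (t <= c).astype(int))
        dup = pd.concat([df, df], ignore_index=True)
        f1 = fit_pc_cox(df, BINARY_SPEC, ties="breslow")
        f2 = fit_pc_cox(dup, BINARY_SPEC, ties="breslow")
        assert f2.beta.iloc[0] == pytest.approx(f1.beta.iloc[0], abs=1e-8)
        assert f2.robust_se.iloc[0] == pytest.approx(f1.robust_se.iloc[0], abs=1e-6)
        assert f2.naive_se.iloc[0] == pytest.approx(
            f1.naive_se.iloc[0] / np.sqrt(2), rel=1e-6
        )

    def test_recompute_matches_stored(self, fit20, stacked20):
        orig = fit20.robust_cov.to_numpy().copy()
        rob = robust_sandwich(fit20, stacked20)
        assert np.allclose(rob.to_numpy(), orig)

    def test_single_cluster_rejected(self):
        df = _binary_records([1, 2, 3], [0, 1, 0], [1, 1, 0], ids=["w", "w", "w"])
        with pytest.raises(ValueError, match="cluster"):
            fit_pc_cox(df, BINARY_SPEC)


class TestHazardRatioTable:
    def test_worked_confidence_interval(self):
        """aHR 2.00 with CI (1.64, 2.44) from beta = ln 2, robust SE = 0.1."""
        terms = ["family_history"]
        fit = ModelFit(
            beta=pd.Series([np.log(2)], index=terms),
            naive_cov=pd.DataFrame([[0.01]], index=terms, columns=terms),
            robust_cov=pd.DataFrame([[0.01]], index=terms, columns=terms),
            baseline_times=np.array([1.0]),
            baseline_cumhaz=np.array([0.1]),
            n_records=1, n_clusters=1, n_events=1, iterations=1,
            final_grad_norm=0.0, loglik=0.0, ties="efron",
            spec=CovariateSpec(include_age=False, factors=("family_history",)),
        )
        df = _binary_records([4.0, 3.0], [1, 0], [1, 0])
        tab = hazard_ratio_table(fit, df)
        row = tab[(tab.variable == "family_history") & (tab.level == 1)].iloc[0]
        assert round(row.aHR, 2) == 2.00
        assert round(row.ci_low, 2) == 1.64
        # exp(ln 2 + 1.96 * 0.1) = 2.4331
        assert round(row.ci_high, 2) == 2.43

    def test_reference_levels_are_unity(self, fit20, stacked20):
        tab = hazard_ratio_table(fit20, stacked20)
        refs = tab[tab.display == "Ref."]
        assert (refs.aHR == 1.0).all()
        assert set(refs.level) == {0, "none"}

    def test_women_years_decompose_follow_up(self, toy_cohort):
        """Occupancy person-time per level sums to total follow-up, as in the
        published table's margin (beta is irrelevant to these columns)."""
        from screenrisk import build_stacked
        st_ = build_stacked(toy_cohort)
        spec = CovariateSpec(include_age=False,
                             factors=("family_history", "bbd_category"))
        terms = spec.term_names()
        eye = pd.DataFrame(np.eye(len(terms)) * 0.01, index=terms, columns=terms)
        fit = ModelFit(
            beta=pd.Series(0.0, index=terms), naive_cov=eye, robust_cov=eye,
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.01]),
            n_records=len(st_), n_clusters=6, n_events=2, iterations=1,
            final_grad_norm=0.0, loglik=0.0, ties="efron", spec=spec,
        )
        tab = hazard_ratio_table(fit, st_)
        total_fu = toy_cohort.outcomes.end_time.sum()
        for var in ["family_history", "bbd_category"]:
            block = tab[tab.variable == var]
            assert block.women_years.sum() == pytest.approx(total_fu)
            assert block.events.sum() == toy_cohort.n_events
        # hand check: w1 spends 2y in bbd 'none', then 3y in 'prior_biopsy_unknown'
        pbu = tab[(tab.variable == "bbd_category") & (tab.level == "prior_biopsy_unknown")].iloc[0]
        assert pbu.women_years == pytest.approx(3.0)
        assert pbu.events == 1


class TestInteractions:
    def test_null_interaction_type_i_error(self):
        from screenrisk import default_config, simulate_cohort, build_stacked
        rejections = 0
        pvals = []
        for rep in range(30):
            cfg = default_config(n_women=2500, seed=5000 + rep,
                                 baseline_hazard=0.004)
            st_ = build_stacked(simulate_cohort(cfg).cohort)
            tab = pc_cox.test_interactions(
                st_, pairs=[("age", "family_history")]
            )
            p = tab.p_value.iloc[0]
            if np.isfinite(p):
                pvals.append(p)
                rejections += p < 0.05
        # no generated interaction: rejection rate compatible with 5%
        assert rejections <= 7
        assert min(pvals) > 1e-5

    def test_strong_product_effect_detected(self):
        rng = np.random.default_rng(31)
        n = 6000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        eta = 0.3 * a + 0.3 * b + 1.0 * a * b
        t = rng.exponential(1 / (0.05 * np.exp(eta)))
        c = rng.exponential(15, n)
        df = stacked_frame(
            np.arange(n), 0.0, 55.0, a,
            np.where(b == 1, "prior_biopsy_unknown", "none"), "none",
            np.minimum(t, c), (t <= c).astype(int),
        )
        spec = CovariateSpec(include_age=False,
                             factors=("family_history", "bbd_category"))
        tab = pc_cox.test_interactions(df, spec,
                                       pairs=[("family_history", "bbd_category")])
        assert tab.p_value.iloc[0] < 0.05

    def test_collinear_candidate_reported_na(self):
        rng = np.random.default_rng(7)
        n = 400
        a = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.3 * a)))
        df = stacked_frame(
            np.arange(n), 0.0, 55.0, a,
            # bbd perfectly coincides with family history: the product term
            # duplicates the main effect
            np.where(a == 1, "prior_biopsy_unknown", "none"), "none",
            t, np.ones(n, dtype=int),
        )
        spec = CovariateSpec(include_age=False,
                             factors=("family_history", "bbd_category"))
        tab = pc_cox.test_interactions(df, spec,
                                       pairs=[("family_history", "bbd_category")])
        assert np.isnan(tab.p_value.iloc[0])
        assert tab.note.iloc[0] != ""


class TestPHDiagnostics:
    def test_proportional_exponential_groups_offset_ln2(self):
        rng = np.random.default_rng(13)
        n = 6000
        x = np.repeat([0, 1], n // 2)
        lam = 0.1 * np.where(x == 1, 2.0, 1.0)
        t = rng.exponential(1 / lam)
        df = _binary_records(t, x, np.ones(n, dtype=int))
        curves, summary = ph_diagnostics(df, "family_history")
        wide = curves.pivot(index="time", columns="level", values="loglog_surv")
        offset = (wide[1] - wide[0]).dropna()
        assert offset.median() == pytest.approx(np.log(2), abs=0.1)
        assert summary["spread_range"] < 0.35

    def test_identical_groups_offset_near_zero(self):
        rng = np.random.default_rng(14)
        n = 4000
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(10, n)
        df = _binary_records(t, x, np.ones(n, dtype=int))
        curves, _ = ph_diagnostics(df, "family_history")
        wide = curves.pivot(index="time", columns="level", values="loglog_surv")
        assert abs((wide[1] - wide[0]).dropna().median()) < 0.08

    def test_crossing_hazards_flagged(self):
        rng = np.random.default_rng(15)
        n = 6000
        x = np.repeat([0, 1], n // 2)
        # group 0 exponential; group 1 Weibull with increasing hazard: the
        # log(-log) curves are not parallel
        t = np.where(x == 0, rng.exponential(8.0, n), rng.weibull(3.0, n) * 9.0)
        df = _binary_records(t, x, np.ones(n, dtype=int))
        _, summary = ph_diagnostics(df, "family_history")
        assert summary["spread_range"] > 0.8

    def test_eventless_level_omitted(self):
        df = _binary_records([1, 2, 3, 4], [0, 0, 1, 1], [1, 1, 0, 0])
        with pytest.warns(UserWarning, match="omitted"):
            curves, summary = ph_diagnostics(df, "family_history")
        assert summary["omitted_levels"] == [1]


class TestBreslowBaseline:
    def test_single_event_null_model_increment(self):
        df = _binary_records([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0])
        fit = fit_pc_cox(df, NULL_SPEC)
        times, ch = breslow_baseline(fit, df)
        assert times[0] == 1.0
        assert ch[0] == pytest.approx(1 / 5)

    def test_null_model_equals_nelson_aalen(self, stacked20):
        from lifelines import NelsonAalenFitter
        sub = stacked20.iloc[:5000]
        fit = fit_pc_cox(sub, NULL_SPEC)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(sub.residual_time, sub.event)
        na = naf.cumulative_hazard_.iloc[:, 0]
        mine = pd.Series(fit.baseline_cumhaz, index=fit.baseline_times)
        joined = na[na.index.isin(mine.index)]
        assert np.allclose(mine.reindex(joined.index), joined, atol=1e-10)

    def test_constant_hazard_cumulative_level(self, null_sim):
        _, sim = null_sim
        from screenrisk import build_stacked
        st_ = build_stacked(sim.cohort)
        fit = fit_pc_cox(st_)
        # true Lambda0(10) = 10 * lambda at the reference profile
        assert fit.cumhaz_at(10.0)[0] == pytest.approx(0.02183, rel=0.15)

    def test_monotone_right_continuous_from_zero(self, fit20):
        assert (np.diff(fit20.baseline_cumhaz) >= 0).all()
        assert fit20.cumhaz_at(0.0)[0] == 0.0

    def test_center_shift_leaves_predictions_invariant(self, stacked20):
        from screenrisk import predict_risk
        sub_w = stacked20.woman_id.unique()[:4000]
        sub = stacked20[stacked20.woman_id.isin(sub_w)]
        f1 = fit_pc_cox(sub, CovariateSpec(age_center=59.5))
        f2 = fit_pc_cox(sub, CovariateSpec(age_center=0.0))
        prof = sub.iloc[:50].rename(columns={"age_at_visit": "age"})
        r1 = predict_risk(f1, prof, [5.0, 10.0])
        r2 = predict_risk(f2, prof, [5.0, 10.0])
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-8)


def test_fit_serialization_roundtrip(tmp_path, fit20):
    path = tmp_path / "fit.json"
    fit20.to_json(path)
    back = ModelFit.from_json(path)
    pd.testing.assert_series_equal(back.beta, fit20.beta)
    assert np.allclose(back.robust_cov, fit20.robust_cov)
    assert np.allclose(back.baseline_cumhaz, fit20.baseline_cumhaz)
    assert back.ties == fit20.ties
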