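import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from pdprog.cohort import GeneratorConfig, generate_cohort
from pdprog.survival import (
    build_survival_records,
    fit_cox_frailty,
    kaplan_meier,
    km_survival_at,
    logrank_test,
    survival_curves_by_subgroup,
)


def _cohort_row(sid, t, duration, age, status, **kw):
    base = {
        "subject_id": sid, "site": 0, "sex": kw.get("sex", 0),
        "education_years": 16.0, "onset_age_years": age - duration,
        "apoe4": kw.get("apoe4", 0), "gba": kw.get("gba", 0), "mapt_h1": 0,
        "visit_time_years": t, "age_years": age,
        "disease_duration_years": duration, "ledd_mg": 500.0, "gds15": 5,
        "status": status,
    }
    from pdprog.cohort import TEST_COLUMNS

    for c in TEST_COLUMNS:
        base[c] = 10.0
    return base


def exp_records(seed, n=200, log_hr=0.7, rate=0.1, cens_mean=15.0, binary_p=0.5):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, binary_p, n)
    t = rng.exponential(1.0 / (rate * np.exp(log_hr * x)))
    c = rng.exponential(cens_mean, n)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "entry": 0.0,
        "time": np.minimum(t, c),
        "event": (t <= c).astype(int),
        "x": x,
    })


class TestBuildRecords:
    def test_onset_scale_delayed_entry_mapping(self):
        rows = [
            _cohort_row("a", 0.0, 5.0, 60.0, 0),
            _cohort_row("a", 2.0, 7.0, 62.0, 1),
            _cohort_row("a", 4.0, 9.0, 64.0, 2),
        ]
        recs = build_survival_records(pd.DataFrame(rows), "onset")
        r = recs.iloc[0]
        assert (r["entry"], r["time"], r["event"]) == (5.0, 9.0, 1)

    def test_censored_subject(self):
        rows = [
            _cohort_row("b", 0.0, 5.0, 60.0, 0),
            _cohort_row("b", 7.0, 12.0, 67.0, 1),
        ]
        recs = build_survival_records(pd.DataFrame(rows), "onset")
        r = recs.iloc[0]
        assert (r["entry"], r["time"], r["event"]) == (5.0, 12.0, 0)

    def test_months_scale_has_zero_entry(self):
        rows = [
            _cohort_row("a", 0.0, 5.0, 60.0, 0),
            _cohort_row("a", 2.0, 7.0, 62.0, 2),
            _cohort_row("b", 0.0, 3.0, 55.0, 0),
            _cohort_row("b", 1.0, 4.0, 56.0, 0),
        ]
        recs = build_survival_records(pd.DataFrame(rows), "months")
        assert (recs["entry"] == 0.0).all()
        assert recs.set_index("subject_id").loc["a", "time"] == 24.0

    def test_baseline_pdd_excluded_and_counted(self):
        rows = [
            _cohort_row("a", 0.0, 5.0, 60.0, 2),
            _cohort_row("b", 0.0, 3.0, 55.0, 0),
            _cohort_row("b", 2.0, 5.0, 57.0, 2),
        ]
        recs = build_survival_records(pd.DataFrame(rows), "onset")
        assert recs.attrs["n_excluded_baseline_pdd"] == 1
        assert list(recs["subject_id"]) == ["b"]

    def test_event_counts_agree_across_scales(self, cohort_default):
        counts = {
            s: int(build_survival_records(cohort_default, s)["event"].sum())
            for s in ("onset", "age", "months")
        }
        assert len(set(counts.values())) == 1, counts


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        recs = pd.DataFrame({
            "subject_id": list("abcd"), "entry": 0.0,
            "time": [1.0, 2.0, 3.0, 4.0], "event": 1,
        })
        km = kaplan_meier(recs)
        assert km_survival_at(km, 2.5) == 0.5

    def test_all_censored_flat_at_one(self):
        recs = pd.DataFrame({
            "subject_id": list("abc"), "entry": 0.0,
            "time": [1.0, 2.0, 3.0], "event": 0,
        })
        km = kaplan_meier(recs)
        assert km.empty or (km["survival"] == 1.0).all()
        assert km_survival_at(km, 10.0) == 1.0

    def test_mixed_censoring_hand_risk_table(self):
        # events at 1 (n=5), 3 (n=3, after censor at 2), censor 4, event 5 (n=1)
        recs = pd.DataFrame({
            "subject_id": list("abcde"), "entry": 0.0,
            "time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 0, 1, 0, 1],
        })
        km = kaplan_meier(recs)
        expect = {1.0: 4 / 5, 3.0: 4 / 5 * 2 / 3, 5.0: 4 / 5 * 2 / 3 * 0.0}
        for t, s in expect.items():
            assert abs(km_survival_at(km, t) - s) < 1e-12

    def test_matches_lifelines_with_delayed_entry(self):
        rng = np.random.default_rng(4)
        n = 150
        entry = np.minimum(rng.exponential(1.0, n), 3.0)
        t = entry + rng.exponential(5.0, n)
        c = entry + rng.exponential(8.0, n)
        recs = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "entry": entry,
            "time": np.minimum(t, c), "event": (t <= c).astype(int),
        })
        km = kaplan_meier(recs)
        kmf = KaplanMeierFitter().fit(recs["time"], recs["event"], entry=recs["entry"])
        for t_eval in [2.0, 4.0, 8.0]:
            theirs = float(kmf.survival_function_at_times(t_eval).iloc[0])
            assert abs(km_survival_at(km, t_eval) - theirs) < 1e-10

    def test_survival_monotone_in_unit_interval(self, cohort_default):
        recs = build_survival_records(cohort_default, "onset")
        km = kaplan_meier(recs)
        s = km["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        recs = pd.DataFrame({
            "subject_id": list("abcdefgh"), "entry": 0.0,
            "time": [1, 2, 3, 4] * 2, "event": 1,
            "g": [0] * 4 + [1] * 4,
        })
        stat, p = logrank_test(recs, "g")
        assert abs(stat) < 1e-12 and abs(p - 1.0) < 1e-12

    def test_toy_two_group_hand_computation(self):
        # A events at 1, 2; B events at 3, 4; no censoring
        recs = pd.DataFrame({
            "subject_id": list("abcd"), "entry": 0.0,
            "time": [1.0, 2.0, 3.0, 4.0], "event": 1,
            "g": ["A", "A", "B", "B"],
        })
        stat, p = logrank_test(recs, "g")
        # hand risk table: O_A=2, E_A=2/4+1/3, V=sum of hypergeometric terms
        e_a = 2 / 4 + 1 / 3
        v = (2 * 2 / 16) * (4 - 1) / (4 - 1) * 1  # t=1: d=1 n=4 nA=2 -> 1*(2/4)*(2/4)*(3/3)
        v = 0.25 + (1 * (1 / 3) * (2 / 3))  # t=2: n=3, nA=1
        expected_stat = (2 - e_a) ** 2 / v
        assert abs(stat - expected_stat) < 1e-10

    def test_time_shift_invariance(self):
        recs = exp_records(seed=5)
        s1, _ = logrank_test(recs, "x")
        shifted = recs.copy()
        shifted["time"] += 100.0
        shifted["entry"] += 100.0
        s2, _ = logrank_test(shifted, "x")
        assert abs(s1 - s2) < 1e-10

    def test_no_events_rejected(self):
        recs = exp_records(seed=6)
        recs["event"] = 0
        with pytest.raises(ValueError):
            logrank_test(recs, "x")

    def test_null_type_i_error(self):
        """Equal-rate exponential groups reject at ~5% (accept 2-8%)."""
        reps, rej = 300, 0
        for s in range(reps):
            recs = exp_records(seed=2000 + s, n=100, log_hr=0.0, cens_mean=20.0)
            _, p = logrank_test(recs, "x")
            rej += p < 0.05
        assert 0.02 * reps <= rej <= 0.08 * reps, rej


class TestCox:
    def test_reduces_to_lifelines_partial_likelihood(self):
        rng = np.random.default_rng(1)
        n = 250
        x1 = rng.binomial(1, 0.4, n)
        x2 = rng.normal(size=n)
        entry = rng.uniform(0, 1, n)
        t = entry + rng.exponential(1.0 / (0.1 * np.exp(0.7 * x1 - 0.3 * x2)))
        c = entry + rng.exponential(12.0, n)
        recs = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "entry": entry,
            "time": np.minimum(t, c), "event": (t <= c).astype(int),
            "x1": x1, "x2": x2,
        })
        fit = fit_cox_frailty(recs, ["x1", "x2"], frailty_var=0.0)
        cph = CoxPHFitter().fit(
            recs[["entry", "time", "event", "x1", "x2"]], "time", "event",
            entry_col="entry",
        )
        assert np.allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_log_hr_recovery_within_three_se(self):
        hits, reps = 0, 40
        for s in range(reps):
            recs = exp_records(seed=3000 + s, n=500)
            fit = fit_cox_frailty(recs, ["x"], frailty_var=0.0)
            hits += abs(fit.params["x"] - 0.7) <= 3.0 * fit.se["x"]
        assert hits >= 0.9 * reps, hits

    def test_duplicate_covariates_rejected(self):
        recs = exp_records(seed=7)
        recs["x2"] = recs["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cox_frailty(recs, ["x", "x2"])

    def test_no_event_level_flagged(self):
        recs = exp_records(seed=8, n=80)
        recs.loc[recs["x"] == 1, "event"] = 0
        with pytest.warns(UserWarning, match="monotone"):
            fit = fit_cox_frailty(recs, ["x"], frailty_var=0.0)
        assert fit.flags

    def test_frailty_shrinks_cluster_effects(self):
        """Clustered records with shared risk: frailty fit runs and the
        estimated frailty terms correlate with the cluster hazards."""
        rng = np.random.default_rng(9)
        n_cluster, per = 40, 5
        b = rng.normal(0, 0.8, n_cluster)
        rows = []
        for g in range(n_cluster):
            x = rng.binomial(1, 0.5, per)
            t = rng.exponential(1.0 / (0.2 * np.exp(0.5 * x + b[g])))
            for j in range(per):
                rows.append({"subject_id": f"c{g}", "entry": 0.0,
                             "time": min(t[j], 20.0), "event": int(t[j] <= 20.0),
                             "x": x[j]})
        recs = pd.DataFrame(rows)
        fit = fit_cox_frailty(recs, ["x"])
        assert fit.frailty_var > 0.05
        est = fit.frailty.loc[[f"c{g}" for g in range(n_cluster)]].to_numpy()
        assert np.corrcoef(est, b)[0, 1] > 0.3


class TestSubgroupCurves:
    def test_zero_coefficients_give_identical_curves(self):
        recs = exp_records(seed=10, n=120)
        fit = fit_cox_frailty(recs, ["x"], frailty_var=0.0)
        fit.params[:] = 0.0
        sub = pd.DataFrame({"label": ["a", "b"], "x": [0, 1]})
        curves = survival_curves_by_subgroup(fit, sub)
        a = curves[curves["group"] == "a"]["survival"].to_numpy()
        b = curves[curves["group"] == "b"]["survival"].to_numpy()
        assert np.allclose(a, b)
        km = kaplan_meier(recs)
        # Breslow exp(-cumhaz) tracks the product-limit curve closely
        assert np.max(np.abs(a - km["survival"].to_numpy())) < 0.02

    def test_positive_log_hr_orders_curves(self):
        recs = exp_records(seed=11, n=200)
        fit = fit_cox_frailty(recs, ["x"], frailty_var=0.0)
        sub = pd.DataFrame({"label": ["lo", "hi"], "x": [0, 1]})
        curves = survival_curves_by_subgroup(fit, sub)
        lo = curves[curves["group"] == "lo"]["survival"].to_numpy()
        hi = curves[curves["group"] == "hi"]["survival"].to_numpy()
        assert np.all(hi <= lo + 1e-12)

    def test_hand_computed_breslow_arithmetic(self):
        fit_like = fit_cox_frailty(exp_records(seed=12, n=50), ["x"], frailty_var=0.0)
        fit_like.params[:] = np.log(2.0)
        fit_like.center[:] = 0.0
        fit_like.baseline_hazard = pd.DataFrame({"time": [1.0, 2.0], "cumhaz": [0.1, 0.3]})
        sub = pd.DataFrame({"label": ["g"], "x": [1.0]})
        curves = survival_curves_by_subgroup(fit_like, sub)
        assert np.allclose(curves["survival"].to_numpy(),
                           [np.exp(-0.1 * 2.0), np.exp(-0.3 * 2.0)])

    def test_missing_pattern_covariate_rejected(self):
        fit = fit_cox_frailty(exp_records(seed=13), ["x"], frailty_var=0.0)
        with pytest.raises(ValueError, match="x"):
            survival_curves_by_subgroup(fit, pd.DataFrame({"label": ["a"], "y": [1]}))


def test_sex_gba_hazard_ordering_on_synthetic_cohort():
    """Male GBA carriers progress fastest when both multipliers exceed 1."""
    cfg = GeneratorConfig(n_subjects=800, seed=77, gba_rate=0.25,
                          single_visit_fraction=0.1)
    recs = build_survival_records(generate_cohort(cfg), "onset")
    groups = {}
    for (s, g), sub in recs.groupby(["sex", "gba"]):
        km = kaplan_meier(sub)
        groups[(s, g)] = km_survival_at(km, 15.0)
    assert groups[(1, 1)] == min(groups.values())
    assert groups[(0, 0)] == max(groups.values())
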