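"""Survival estimators and clinical association tests vs independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lincdiscover as ld
from lincdiscover.genotype import InputError
from lincdiscover.survival import (
    categorize_expression, collapse_stage, cox_fit, fisher_exact,
    km_estimate, kruskal_wallis, logrank_test, stagewise_summary,
    survival_time_event,
)


class TestCategorize:
    @pytest.mark.parametrize("value,initial,group", [
        (0.39, "<=1", "low"),
        (1.0, "<=1", "low"),          # boundary inclusive
        (4.28, ">1-5", "high"),
        (7.0, ">5-10", "high"),
        (83.0, ">10-83", "high"),
        (200.0, ">10-83", "high"),    # top category open-ended
    ])
    def test_categories(self, value, initial, group):
        assert categorize_expression(value) == (initial, group)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            categorize_expression(-0.1)


class TestExclusions:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=[
            "patient_id", "expression", "vital_status", "days_to_death",
            "days_to_last_followup", "age", "ajcc_stage", "t_stage"])

    def test_zero_followup_and_stage_na_dropped(self):
        recs = self._records([
            ("p1", 2.0, "alive", np.nan, 0.0, 50, "II", "T2"),
            ("p2", 2.0, "alive", np.nan, 100.0, 50, "NA", "T2"),
            ("p3", 2.0, "dead", 300.0, np.nan, 50, "II", "T2"),
        ])
        cohort, report = ld.apply_exclusions(recs)
        assert list(cohort["patient_id"]) == ["p3"]
        assert report["n_excluded_zero_followup"] == 1
        assert report["n_excluded_stage_na"] == 1


def _km_oracle(times, events):
    """Longhand product-limit loop used as the independent reference."""
    out = []
    s = 1.0
    for t in sorted(set(times[events])):
        n = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1 - d / n
        out.append((t, s))
    return out


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        curves = km_estimate([5, 6, 7], [False] * 3)
        assert curves["all"].survival_at(100) == 1.0

    def test_all_events_closed_form(self):
        curves = km_estimate([1, 2, 3], [True] * 3)
        np.testing.assert_allclose(curves["all"].table["survival"],
                                   [2 / 3, 1 / 3, 0.0])

    def test_matches_longhand_oracle_on_random_data(self, rng):
        for _ in range(5):
            times = rng.integers(1, 30, size=40).astype(float)
            events = rng.random(40) < 0.6
            curve = km_estimate(times, events)["all"]
            for (t, s), (_, row) in zip(_km_oracle(times, events),
                                        curve.table.iterrows()):
                assert row["time"] == t
                assert row["survival"] == pytest.approx(s, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(100, size=80)
        events = rng.random(80) < 0.7
        curve = km_estimate(times, events)["all"]
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in curve.table.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-10)


def _logrank_oracle(times, events, g1):
    """Independent tabulation of O-E and hypergeometric variance."""
    o_e = v = 0.0
    for t in sorted(set(times[events])):
        at = times >= t
        n, n1 = at.sum(), (at & g1).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & g1).sum()
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * n1 * (n - n1) * (n - d) / (n ** 2 * (n - 1))
    return o_e ** 2 / v


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        events = np.array([1, 1, 0, 1] * 2, dtype=bool)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_dataset_matches_independent_tabulation(self):
        times = np.array([3, 5, 7, 2, 4, 6, 8, 9], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(
            _logrank_oracle(times, events, groups == "a"), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        times = rng.exponential(50, size=100)
        events = rng.random(100) < 0.7
        groups = rng.random(100) < 0.5
        chi2, p = logrank_test(times, events, groups)
        ref = ll_logrank(times[groups], times[~groups],
                         events[groups], events[~groups])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_group_relabeling_invariance(self, rng):
        times = rng.exponential(50, size=60)
        events = rng.random(60) < 0.6
        groups = np.where(rng.random(60) < 0.5, "x", "y")
        chi2a, pa = logrank_test(times, events, groups)
        flipped = np.where(groups == "x", "y", "x")
        chi2b, pb = logrank_test(times, events, flipped)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_planted_hazard_detected_with_power(self):
        hits = 0
        for seed in range(40):
            sim = ld.simulate_survival_cohort(700, 0.45, 2.5, 1.0, 0.5,
                                              seed=seed)
            t, e = survival_time_event(sim.records)
            g = sim.records["expression"] > 1.0
            hits += logrank_test(t, e, g)[1] < 0.05
        assert hits / 40 >= 0.9


class TestCox:
    def test_score_test_equals_logrank_without_ties(self, rng):
        times = rng.exponential(100, size=120)  # continuous: no ties
        events = rng.random(120) < 0.8
        group = (rng.random(120) < 0.5).astype(float)
        fit = cox_fit(times, events, pd.DataFrame({"g": group}))
        chi2, _ = logrank_test(times, events, group > 0.5)
        assert fit.score_test_chi2 == pytest.approx(chi2, abs=1e-6)

    def test_matches_lifelines_coefficients(self, rng):
        from lifelines import CoxPHFitter
        sim = ld.simulate_survival_cohort(400, 0.4, 2.0, 1.02, 0.4, seed=3)
        t, e = survival_time_event(sim.records)
        X = pd.DataFrame({
            "high": (sim.records["expression"] > 1).astype(float),
            "age": sim.records["age"].to_numpy(),
        })
        fit = cox_fit(t, e, X)
        df = X.copy()
        df["T"] = t
        df["E"] = e
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, ref.params_[["high", "age"]],
                                   atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_[["high", "age"]],
                                   atol=1e-5)

    def test_efron_ties_match_lifelines(self, rng):
        from lifelines import CoxPHFitter
        times = rng.integers(1, 15, size=150).astype(float)  # heavy ties
        events = rng.random(150) < 0.7
        X = pd.DataFrame({"x": rng.normal(size=150)})
        fit = cox_fit(times, events, X, ties="efron")
        df = X.copy()
        df["T"] = times
        df["E"] = events
        ref = CoxPHFitter().fit(df, "T", "E")  # lifelines default is Efron
        assert fit.coef["x"] == pytest.approx(ref.params_["x"], abs=1e-5)

    def test_null_covariate_centered_at_zero(self):
        betas = []
        for seed in range(60):
            sim = ld.simulate_survival_cohort(150, 0.5, 1.0, 1.0, 0.3,
                                              seed=seed)
            t, e = survival_time_event(sim.records)
            X = pd.DataFrame({
                "high": (sim.records["expression"] > 1).astype(float)})
            betas.append(cox_fit(t, e, X).coef["high"])
        assert abs(np.mean(betas)) < 0.05

    def test_too_few_events_rejected(self):
        with pytest.raises(InputError):
            cox_fit([1, 2, 3], [True, False, False],
                    pd.DataFrame({"x": [0.0, 1.0, 0.0]}))


def _kw_brute_force_p(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    h_obs = _kw_h(values, labels)
    uniq, counts = np.unique(labels, return_counts=True)
    hits = total = 0
    for perm in set(itertools.permutations(labels)):
        h = _kw_h(values, np.asarray(perm))
        total += 1
        if h >= h_obs - 1e-9:
            hits += 1
    return hits / total


def _kw_h(values, labels):
    ranks = sps.rankdata(values)
    n = len(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(values, return_counts=True)
    c = 1 - np.sum(t ** 3 - t) / (n ** 3 - n)
    return h / c if c > 0 else 0.0


class TestKruskalWallis:
    def test_all_equal_values(self):
        h, p = kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_two_group_exact_matches_brute_force(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = ["a", "a", "a", "b", "b", "b"]
        h, p = kruskal_wallis(values, labels)
        assert h == pytest.approx(_kw_h(np.array(values, float),
                                        np.array(labels)))
        assert p == pytest.approx(_kw_brute_force_p(values, labels))

    def test_three_group_exact_matches_brute_force(self, rng):
        values = rng.integers(0, 5, size=9).tolist()
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        _, p = kruskal_wallis(values, labels)
        assert p == pytest.approx(_kw_brute_force_p(values, labels))

    def test_large_sample_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, size=30) for m in (0.0, 0.3, 0.8)]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 30)
        h, p = kruskal_wallis(values, labels)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_planted_stage_shift_detected(self):
        sim = ld.simulate_survival_cohort(600, 0.45, 1.0, 1.0, 0.3, seed=21)
        out = stagewise_summary(sim.records)
        assert out["ajcc"]["kw_p"] < 0.05


class TestFisherExact:
    def test_perfect_independence(self):
        p, odds = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        """((10,0),(0,10)): only 2 of C(20,10) tables are as extreme."""
        p, _ = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(20):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0:
                continue
            p, odds = fisher_exact(table)
            ref_odds, ref_p = sps.fisher_exact(table)
            assert p == pytest.approx(ref_p, abs=1e-10)
            if np.isfinite(odds):
                assert odds == pytest.approx(ref_odds)

    def test_proportional_rows_give_p_one(self):
        p, _ = fisher_exact([[2, 4], [3, 6]])
        assert p == pytest.approx(1.0)

    def test_odds_ratio_invariant_under_transposition(self):
        _, o1 = fisher_exact([[8, 2], [3, 7]])
        _, o2 = fisher_exact([[8, 3], [2, 7]])
        assert o1 == pytest.approx(o2)

    def test_non_integer_rejected(self):
        with pytest.raises(InputError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestStagewise:
    def test_sublabels_collapse_per_grouping(self):
        assert collapse_stage("Stage IIA") == "II"
        assert collapse_stage("IIIC") == "III"
        assert collapse_stage("T1c", kind="t") == "T1"
        assert collapse_stage("T4d", kind="t") == "T4"

    def test_planted_monotone_stage_means(self):
        sim = ld.simulate_survival_cohort(3000, 0.45, 1.0, 1.0, 0.3, seed=2)
        out = stagewise_summary(sim.records)
        means = out["ajcc"]["table"].set_index("stage")["mean"]
        assert means["I"] < means["II"] < means["IV"]

    def test_quartiles_follow_linear_interpolation_convention(self, rng):
        vals = rng.uniform(0, 10, size=37)
        recs = pd.DataFrame({
            "expression": vals, "ajcc_stage": ["II"] * 37,
            "t_stage": ["T2"] * 37,
        })
        out = stagewise_summary(recs)
        row = out["ajcc"]["table"].iloc[0]
        assert row["q1"] == pytest.approx(np.percentile(vals, 25))
        assert row["q3"] == pytest.approx(np.percentile(vals, 75))

    def test_single_stage_cohort_has_no_test(self):
        recs = pd.DataFrame({
            "expression": [1.0, 2.0], "ajcc_stage": ["II", "II"],
            "t_stage": ["T2", "T2"],
        })
        out = stagewise_summary(recs)
        assert np.isnan(out["ajcc"]["kw_p"])


class TestAnalyzeSurvival:
    def test_merged_group_km_equals_pooled_computation(self, rng):
        """KM of relabeled single group equals KM of the pooled data."""
        times = rng.exponential(80, size=60)
        events = rng.random(60) < 0.6
        merged = km_estimate(times, events)["all"]
        relabeled = km_estimate(times, events, ["g"] * 60)["g"]
        pd.testing.assert_frame_equal(merged.table, relabeled.table)

    def test_full_analysis_recovers_planted_hazard_direction(self):
        sim = ld.simulate_survival_cohort(700, 0.45, 2.5, 1.03, 0.6, seed=4,
                                          frac_zero_followup=0.01,
                                          frac_stage_na=0.01)
        out = ld.analyze_survival(sim.records)
        assert out["exclusions"]["n_excluded"] == sim.truth["n_excluded"]
        assert out["logrank"]["p"] < 0.05
        assert out["cox"].coef["high_expression"] > 0
        assert out["cox"].wald_p["high_expression"] < 0.05
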