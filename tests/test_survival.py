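"""Cox regression, AIC ranking, ROC cut-offs, KM curves, visit comparison."""


import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from lungqct.records import records_to_frame
from lungqct.survival import (
    compare_visits,
    fit_cox,
    holm_adjust,
    km_by_cutoff,
    rank_by_aic,
    roc_cutoff,
    spearman_matrix,
    summarize_cohort,
)
from lungqct.synthetic import CohortSpec, generate_cohort


def _df(times, events, **covs):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(times))],
        "followup_days": times, "deceased": events, **covs,
    })


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

class TestCox:
    def test_coefficient_matches_brute_force_partial_likelihood(self):
        # 4 subjects, event times 1..4, covariate (1,0,1,0): the partial
        # likelihood can be written down term by term and maximized directly
        # (an alternating pattern keeps the maximizer finite)
        df = _df([1, 2, 3, 4], [1, 1, 1, 1], x=[1.0, 0.0, 1.0, 0.0])

        def neg_log_pl(beta):
            # risk sets: {1,2,3,4}, {2,3,4}, {3,4}, {4}
            e = np.exp(beta)
            return -(np.log(e / (2 * e + 2)) + np.log(1 / (e + 2)) + np.log(e / (e + 1)))

        brute = optimize.minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded",
                                         options={"xatol": 1e-10})
        fit = fit_cox(df, ["x"])
        assert fit.table.loc["x", "coefficient"] == pytest.approx(brute.x, abs=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(-neg_log_pl(brute.x), abs=1e-9)

    def test_scale_equivariance(self, cohort42):
        df = records_to_frame(cohort42)
        fit1 = fit_cox(df, ["skewness"])
        df2 = df.assign(skewness=2.0 * df["skewness"])
        fit2 = fit_cox(df2, ["skewness"])
        assert fit2.table.loc["skewness", "coefficient"] == pytest.approx(
            fit1.table.loc["skewness", "coefficient"] / 2.0, rel=1e-6)
        assert fit2.log_partial_likelihood == pytest.approx(
            fit1.log_partial_likelihood, abs=1e-8)

    def test_aic_identity_and_ci_brackets_hr(self, cohort42, cohort500):
        for records, covs in ((cohort42, ["skewness"]),
                              (cohort500, ["skewness", "fvc_pct_pred", "age_years"])):
            fit = fit_cox(records, covs)
            assert fit.aic == pytest.approx(
                2 * len(covs) - 2 * fit.log_partial_likelihood, abs=1e-9)
            t = fit.table
            assert (np.exp(t["coefficient"]) == pytest.approx(t["hazard_ratio"])).all() \
                or np.allclose(np.exp(t["coefficient"]), t["hazard_ratio"])
            assert ((t["ci95_low"] <= t["hazard_ratio"])
                    & (t["hazard_ratio"] <= t["ci95_high"])).all()

    def test_null_covariate_ci_coverage(self):
        """A covariate with true log-HR 0: the 95% CI should cover HR=1 in
        at least 90% of seeded replicates."""
        covered = 0
        n_rep = 200
        for r in range(n_rep):
            rng = np.random.default_rng(3000 + r)
            n = 120
            noise = rng.normal(size=n)
            t = rng.exponential(1000.0, size=n)
            c = rng.uniform(0, 2500.0, size=n)
            df = _df(np.minimum(t, c), (t <= c).astype(int), x=noise)
            fit = fit_cox(df, ["x"])
            lo, hi = fit.table.loc["x", ["ci95_low", "ci95_high"]]
            covered += lo <= 1.0 <= hi
        assert covered / n_rep >= 0.90

    def test_zero_events_and_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(_df([1, 2, 3], [0, 0, 0], x=[1.0, 2.0, 3.0]), ["x"])
        with pytest.raises(ValueError, match="constant covariate: 'x'"):
            fit_cox(_df([1, 2, 3], [1, 1, 0], x=[2.0, 2.0, 2.0]), ["x"])


class TestAicRanking:
    def test_noise_covariate_usually_loses(self):
        """Adding a pure-noise covariate to a real model should raise AIC
        in the clear majority of replicates."""
        wins = 0
        n_rep = 40
        for r in range(n_rep):
            recs = generate_cohort(CohortSpec(seed=4000 + r, n=150))
            df = records_to_frame(recs)
            df["noise"] = np.random.default_rng(9000 + r).normal(size=len(df))
            small = fit_cox(df, ["skewness"])
            big = fit_cox(df, ["skewness", "noise"])
            wins += small.aic < big.aic
        assert wins / n_rep >= 0.70

    def test_singleton_ordering_and_identity(self, cohort42):
        fit = fit_cox(cohort42, ["skewness"])
        table = rank_by_aic([fit])
        assert len(table) == 1
        assert table.loc[0, "aic"] == pytest.approx(
            2 * table.loc[0, "k"] - 2 * table.loc[0, "log_partial_likelihood"])

    def test_ascending_order_with_name_tiebreak(self, cohort42):
        fits = [fit_cox(cohort42, [c]) for c in ("skewness", "kurtosis", "mld")]
        table = rank_by_aic(fits)
        assert list(table["aic"]) == sorted(table["aic"])

    def test_differing_cohorts_rejected(self, cohort42):
        other = generate_cohort(CohortSpec(seed=77, n=42))
        with pytest.raises(ValueError, match="differing cohorts"):
            rank_by_aic([fit_cox(cohort42, ["skewness"]), fit_cox(other, ["skewness"])])


# ---------------------------------------------------------------------------
# ROC cut-offs
# ---------------------------------------------------------------------------

def brute_force_youden(x, y, direction):
    """Independent exhaustive scan over observed thresholds."""
    dead, alive = x[y == 1], x[y == 0]
    best = None
    for t in np.unique(x):
        if direction == "le":
            sens = np.count_nonzero(dead <= t) / dead.size
            spec = np.count_nonzero(alive > t) / alive.size
        else:
            sens = np.count_nonzero(dead >= t) / dead.size
            spec = np.count_nonzero(alive < t) / alive.size
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best:
            best = key
    return -best[2], best[0]


class TestRocCutoff:
    def test_perfect_separation(self):
        df = _df([1] * 6, [1, 1, 1, 0, 0, 0], x=[1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        cut = roc_cutoff(df, "x", direction="auto")
        assert cut.auc == pytest.approx(1.0)
        assert cut.sensitivity == 100.0 and cut.specificity == 100.0
        assert cut.direction == "le" and cut.threshold == 3.0

    def test_null_variable_auc_near_half(self):
        rng = np.random.default_rng(8)
        n1, n0 = 100, 400
        df = _df([1] * 500, [1] * n1 + [0] * n0, x=rng.normal(size=500))
        cut = roc_cutoff(df, "x", direction="auto")
        se = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
        assert abs(cut.auc - 0.5) <= 3 * se

    @pytest.mark.parametrize("seed", range(30))
    def test_threshold_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        x = np.round(rng.normal(size=n), 2)  # rounding forces ties
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        df = _df([1] * n, y, x=x)
        for direction in ("le", "ge"):
            cut = roc_cutoff(df, "x", direction=direction)
            t_ref, j_ref = brute_force_youden(x, y, direction)
            assert cut.threshold == t_ref
            assert cut.youden_j == pytest.approx(j_ref, abs=1e-12)

    def test_fixed_direction_conventions(self, cohort42):
        assert roc_cutoff(cohort42, "skewness").direction == "le"
        assert roc_cutoff(cohort42, "mld").direction == "ge"

    def test_single_class_rejected(self):
        df = _df([1, 2], [1, 1], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_cutoff(df, "x")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_two_groups_all_events_step_to_zero(self):
        df = _df([1] * 5 + [2] * 5, [1] * 10, x=[0.0] * 5 + [1.0] * 5)
        strat = km_by_cutoff(df, "x", 0.5, "le")
        assert strat.predicted_death.survival[-1] == pytest.approx(0.0)
        assert strat.predicted_survival.survival[-1] == pytest.approx(0.0)
        assert strat.predicted_death.times[-1] == 1.0
        assert strat.predicted_survival.times[-1] == 2.0
        assert strat.logrank_p < 0.05

    def test_product_limit_matches_hand_computation(self):
        # 6 subjects, events at 1, 2, 4, 6; censored at 3 and 5:
        # S(1)=5/6, S(2)=5/6*4/5=2/3, S(4)=2/3*2/3=4/9, S(6)=0
        df = _df([1, 2, 3, 4, 5, 6, 100], [1, 1, 0, 1, 0, 1, 1],
                 x=[0, 0, 0, 0, 0, 0, 10])
        strat = km_by_cutoff(df, "x", 0.5, "le")
        hand = {1.0: 5 / 6, 2.0: 2 / 3, 4.0: 4 / 9, 6.0: 0.0}
        merged = dict(zip(strat.predicted_death.times, strat.predicted_death.survival))
        for t, s in hand.items():
            assert merged[t] == pytest.approx(s, abs=1e-12)

    def test_single_stratum_no_censoring_equals_empirical_survival(self):
        times = [3, 1, 4, 1, 5]
        df = _df(times + [9], [1] * 5 + [1], x=[0.0] * 5 + [1.0])
        curve = km_by_cutoff(df, "x", 0.5, "le").predicted_death
        t_sorted = np.sort(times)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t_sorted > t))

    def test_logrank_matches_hand_2x2_construction(self):
        df = _df([1, 2, 3, 4, 5, 6, 7, 8], [1, 1, 0, 1, 1, 1, 0, 1],
                 x=[0, 0, 0, 0, 1, 1, 1, 1])
        strat = km_by_cutoff(df, "x", 0.5, "le")

        # hand-written log-rank: one 2x2 table per distinct event time
        t = df["followup_days"].to_numpy(float)
        e = df["deceased"].to_numpy(int)
        g = (df["x"] <= 0.5).to_numpy()
        obs_minus_exp, var = 0.0, 0.0
        for tj in np.unique(t[e == 1]):
            at_risk = t >= tj
            n = at_risk.sum()
            n1 = (at_risk & g).sum()
            d = ((t == tj) & (e == 1)).sum()
            d1 = ((t == tj) & (e == 1) & g).sum()
            obs_minus_exp += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2 = obs_minus_exp**2 / var
        assert strat.logrank_statistic == pytest.approx(chi2, abs=1e-9)

    def test_all_censored_is_an_error(self):
        df = _df([1, 2, 3, 4], [0, 0, 0, 0], x=[0, 0, 1, 1])
        with pytest.raises(ValueError, match="log-rank test undefined"):
            km_by_cutoff(df, "x", 0.5, "le")

    def test_empty_stratum_named(self):
        df = _df([1, 2], [1, 1], x=[1.0, 2.0])
        with pytest.raises(ValueError, match="predicted-death stratum"):
            km_by_cutoff(df, "x", 0.5, "le")
        with pytest.raises(ValueError, match="predicted-survival stratum"):
            km_by_cutoff(df, "x", 0.5, "ge")


# ---------------------------------------------------------------------------
# visit comparison and Holm
# ---------------------------------------------------------------------------

class TestCompareVisits:
    def test_interval_difference_is_median_shift(self):
        # three pairs whose medians are 1.26 at baseline and 0.94 at follow-up
        df = pd.DataFrame({
            "patient_id": list("abc"), "followup_days": [1] * 3, "deceased": [0] * 3,
            "kurtosis": [0.41, 1.26, 2.26], "fu_kurtosis": [0.01, 0.94, 1.53],
        })
        out = compare_visits(df, variables=("kurtosis",))
        assert out.loc[0, "interval_difference"] == pytest.approx(0.94 - 1.26)
        assert out.loc[0, "baseline_median"] == pytest.approx(1.26)

    def test_identical_visits_give_zero_difference_and_p_one(self):
        df = pd.DataFrame({
            "patient_id": list("abcd"), "followup_days": [1] * 4, "deceased": [0] * 4,
            "kurtosis": [1.0, 1.0, 1.0, 1.0], "fu_kurtosis": [1.0, 1.0, 1.0, 1.0],
            "mld": [-800.0, -790, -780, -770], "fu_mld": [-800.0, -790, -780, -770],
        })
        out = compare_visits(df, variables=("kurtosis", "mld"))
        assert (out["interval_difference"] == 0).all()
        assert np.allclose(out["p_holm"], 1.0)

    def test_holm_adjustment_matches_hand_rule(self):
        # step-down: sorted p * (m - rank + 1), monotonicity enforced
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({
            "patient_id": ["a", "b"], "followup_days": [1, 1], "deceased": [0, 0],
            "kurtosis": [1.0, 2.0], "fu_kurtosis": [0.9, np.nan],
        })
        with pytest.raises(ValueError, match="paired records"):
            compare_visits(df, variables=("kurtosis",))

    def test_paired_option_uses_signed_rank(self, cohort42):
        df = records_to_frame(cohort42)
        unpaired = compare_visits(df)
        paired = compare_visits(df, paired=True)
        assert set(unpaired["variable"]) == set(paired["variable"])
        assert not np.allclose(unpaired["p_raw"], paired["p_raw"])


# ---------------------------------------------------------------------------
# Spearman and cohort summary
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        df = pd.DataFrame({
            "patient_id": list("abcde"), "followup_days": [1] * 5, "deceased": [0] * 5,
            "a": x, "b": np.exp(x), "c": -x,
        })
        sp = spearman_matrix(df, ["a", "b", "c"])
        assert sp.rho.loc["a", "b"] == pytest.approx(1.0)
        assert sp.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(sp.rho), 1.0)
        assert np.allclose(sp.rho, sp.rho.T)

    def test_generated_indexes_are_rank_correlated(self, cohort500):
        sp = spearman_matrix(cohort500)
        assert sp.rho.loc["kurtosis", "skewness"] > 0
        assert sp.rho.loc["mld", "haa_pct"] > 0
        assert sp.rho.loc["kurtosis", "mld"] < 0

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame({
            "patient_id": list("abcd"), "followup_days": [1] * 4, "deceased": [0] * 4,
            "a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0],
        })
        with pytest.warns(RuntimeWarning, match="constant"):
            sp = spearman_matrix(df, ["a", "b"])
        assert np.isnan(sp.rho.loc["a", "b"])
        assert sp.rho.loc["b", "b"] == 1.0


class TestSummary:
    def test_deceased_percentage_from_counts(self):
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(42)],
            "followup_days": np.arange(42) + 1.0,
            "deceased": [1] * 10 + [0] * 32,
        })
        out = summarize_cohort(df)
        row = out[(out["variable"] == "deceased") & (out["level"] == "1")].iloc[0]
        assert row["count"] == 10
        assert round(row["pct"], 2) == 23.81

    def test_single_record_sd_missing(self):
        df = pd.DataFrame({
            "patient_id": ["a"], "followup_days": [100.0], "deceased": [0],
            "skewness": [1.3],
        })
        out = summarize_cohort(df)
        row = out[out["variable"] == "skewness"].iloc[0]
        assert np.isnan(row["sd"]) and row["median"] == 1.3

    def test_generator_means_within_three_se(self, cohort500):
        from lungqct.synthetic import DEFAULT_MARGINALS

        out = summarize_cohort(cohort500)
        for var in ("kurtosis", "skewness", "mld"):
            mean, sd, _ = DEFAULT_MARGINALS[var]
            row = out[out["variable"] == var].iloc[0]
            assert abs(row["mean"] - mean) <= 3 * sd / np.sqrt(row["n"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort(pd.DataFrame(columns=["patient_id"]))
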