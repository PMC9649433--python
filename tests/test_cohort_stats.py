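import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from snowmatch.cohort_stats import (
    DegenerateLocus,
    cox_regression,
    cox_score_test,
    cross_locus_frame,
    cross_locus_table,
    logistic_univariable,
    normalize,
    pool_ktc,
    pool_pregnancy,
    rank_test,
    spearman,
    stepwise_aic,
)


def pc_case(case_id, child, mother, scores, csa):
    return {"case_id": case_id, "child": child, "mother": mother,
            "scores": scores, "csa": csa}


SCORES0 = {L: {"snowflake": 3, "all_eps": 2, "abv_eps": 1, "pirche_DRB1": 5}
           for L in "ABC"}


class TestPoolPregnancy:
    def test_matched_locus_dropped(self):
        case = pc_case(
            "c1",
            child={"A": ("A*01:01", "A*02:01"), "B": ("B*01:01", "B*02:01"),
                   "C": ("C*01:01", "C*02:01")},
            mother={"A": ("A*01:01", "A*02:01"), "B": ("B*01:01", "B*03:01"),
                    "C": ("C*03:01", "C*04:01")},
            scores=SCORES0, csa={L: True for L in "ABC"},
        )
        df = pool_pregnancy([case])
        assert set(df["locus"]) == {"B", "C"}

    def test_homozygous_shared_dropped(self):
        case = pc_case(
            "c1",
            child={"A": ("A*01:01", "A*01:01"), "B": ("B*01:01", "B*02:01"),
                   "C": ("C*01:01", "C*02:01")},
            mother={"A": ("A*01:01", "A*02:01"), "B": ("B*03:01", "B*04:01"),
                    "C": ("C*03:01", "C*04:01")},
            scores=SCORES0, csa={L: False for L in "ABC"},
        )
        df = pool_pregnancy([case])
        assert set(df["locus"]) == {"B", "C"}

    def test_fully_mismatched_three_records(self):
        case = pc_case(
            "c1",
            child={"A": ("A*01:01", "A*02:01"), "B": ("B*01:01", "B*02:01"),
                   "C": ("C*01:01", "C*02:01")},
            mother={"A": ("A*03:01", "A*04:01"), "B": ("B*03:01", "B*04:01"),
                    "C": ("C*03:01", "C*04:01")},
            scores=SCORES0, csa={L: False for L in "ABC"},
        )
        assert len(pool_pregnancy([case])) == 3


def ktc_case(case_id, scores, dsa, follow_up=5.0):
    return {"case_id": case_id, "scores": scores, "dsa": dsa,
            "follow_up": {L: follow_up for L in "ABC"}}


class TestPoolKtc:
    def test_all_zero_scores_excluded(self):
        scores = {L: {"snowflake": 0, "all_eps": 0, "abv_eps": 0, "pirche_DRB1": 0}
                  for L in "ABC"}
        scores["B"] = {"snowflake": 1, "all_eps": 0, "abv_eps": 0, "pirche_DRB1": 0}
        df = pool_ktc([ktc_case("k1", scores, {L: False for L in "ABC"})])
        # zero-everything loci dropped; nonzero snowflake alone retained
        assert list(df["locus"]) == ["B"]

    def test_negative_follow_up_rejected(self):
        with pytest.raises(ValueError):
            pool_ktc([ktc_case("k1", SCORES0, {L: False for L in "ABC"},
                               follow_up=-1.0)])


class TestNormalize:
    def frame(self):
        rng = np.random.default_rng(0)
        rows = []
        for L in "ABC":
            for i in range(30):
                rows.append({"case_id": i, "locus": L,
                             "snowflake": int(rng.integers(0, 20)),
                             "all_eps": int(rng.integers(0, 10)),
                             "abv_eps": int(rng.integers(0, 5)),
                             "pirche_DRB1": int(rng.integers(0, 40)),
                             "outcome": bool(rng.random() < 0.3)})
        return pd.DataFrame(rows)

    def test_z_columns_standardized_per_locus(self):
        out = normalize(self.frame())
        for L, grp in out.groupby("locus"):
            for col in ("z_snowflake", "z_all_eps", "z_abv_eps"):
                assert abs(grp[col].mean()) < 1e-9
                assert abs(grp[col].std(ddof=1) - 1.0) < 1e-9

    def test_closed_form_sample_sd(self):
        # (1,2,3) standardized with the sample (n-1) sd gives (-1, 0, 1)
        df = pd.DataFrame({"locus": ["A"] * 3, "snowflake": [1, 2, 3],
                           "all_eps": [1, 2, 3], "abv_eps": [1, 2, 3],
                           "pirche_DRB1": [0, 1, 2]})
        out = normalize(df)
        assert np.allclose(out["z_snowflake"], [-1.0, 0.0, 1.0])

    def test_log1p_pirche(self):
        out = normalize(self.frame())
        assert np.allclose(out["log_pirche_DRB1"], np.log1p(out["pirche_DRB1"]))
        assert (out.loc[out["pirche_DRB1"] == 0, "log_pirche_DRB1"] == 0).all()

    def test_degenerate_locus_raises(self):
        df = self.frame()
        df.loc[df["locus"] == "B", "snowflake"] = 4
        with pytest.raises(DegenerateLocus, match="B"):
            normalize(df)


class TestRankTest:
    def test_identical_groups(self):
        assert rank_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        # all 20 orderings enumerable: U is extreme, two-sided p = 2/20
        assert rank_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_matches_exhaustive_enumeration(self):
        # independent permutation oracle on a tie-free sample
        x, y = [0.3, 1.7, 2.2], [1.1, 2.9, 3.4, 4.0]
        combined = x + y
        u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        n1 = len(x)
        us = []
        for idx in itertools.combinations(range(len(combined)), n1):
            g0 = [combined[i] for i in idx]
            g1 = [combined[i] for i in range(len(combined)) if i not in idx]
            us.append(sum(1 for a in g0 for b in g1 if a > b))
        us = np.array(us)
        mu = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert rank_test(x, y) == pytest.approx(p_exact)

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=60)
        ps = [rank_test(base, base + shift) for shift in (0.2, 0.6, 1.2)]
        assert ps[0] > ps[1] > ps[2]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        a, b = rng.exponential(size=15), rng.exponential(size=12) + 0.3
        assert rank_test(a, b) == pytest.approx(rank_test(np.log(a), np.log(b)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        # d = (0, 1, -1, 0): rho = 1 - 6*2/(4*15) = 0.8
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 10, 30)
        y = rng.uniform(1, 10, 30)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.log(x), y**3)
        assert rho1 == pytest.approx(rho2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestLogistic:
    def test_two_by_two_cross_product(self):
        # 10/40 events among exposed vs 5/45 among unexposed:
        # OR = (10*45)/(40*5) = 2.25
        rows = (
            [{"x": 1.0, "outcome": True}] * 10 + [{"x": 1.0, "outcome": False}] * 40
            + [{"x": 0.0, "outcome": True}] * 5 + [{"x": 0.0, "outcome": False}] * 45
        )
        res = logistic_univariable(pd.DataFrame(rows), "x")
        assert res.estimates["x"] == pytest.approx(2.25, abs=1e-6)
        assert res.ci_low["x"] < 2.25 < res.ci_high["x"]

    def test_null_predictor_covers_one(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"x": rng.normal(size=4000),
                           "outcome": rng.random(4000) < 0.3})
        res = logistic_univariable(df, "x")
        assert res.ci_low["x"] < 1.0 < res.ci_high["x"]
        assert abs(np.log(res.estimates["x"])) < 0.2

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "outcome": [True, True]})
        with pytest.raises(ValueError):
            logistic_univariable(df, "x")

    def test_separation_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "outcome": np.r_[np.zeros(20), np.ones(20)].astype(bool)})
        res = logistic_univariable(df, "x")
        assert not res.converged


class TestStepwise:
    def test_noise_reduced_and_aic_bounded(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame({"noise": rng.normal(size=600),
                           "outcome": rng.random(600) < 0.25})
        res = stepwise_aic(df, ["noise"])
        full = logistic_univariable(df, "noise")
        assert res.aic <= full.aic + 1e-9
        assert res.terms == []  # pure noise dropped at this draw

    def test_true_predictor_retained(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=600)
        noise = rng.normal(size=600)
        p = 1 / (1 + np.exp(-(-1.2 + np.log(1.6) * x)))
        df = pd.DataFrame({"x": x, "noise": noise,
                           "outcome": rng.random(600) < p})
        res = stepwise_aic(df, ["x", "noise"])
        assert "x" in res.terms

    def test_requires_candidates(self):
        with pytest.raises(ValueError):
            stepwise_aic(pd.DataFrame({"outcome": [True, False]}), [])


class TestCox:
    def two_group_data(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        return pd.DataFrame({"follow_up": t, "outcome": True, "x": x})

    def test_score_test_matches_logrank(self):
        # no censoring, distinct times: the partial-likelihood score test at
        # beta=0 is the log-rank test
        df = self.two_group_data()
        chi2, p = cox_score_test(df["follow_up"], df["outcome"], df["x"])
        lr = logrank_test(
            df.loc[df.x == 0, "follow_up"], df.loc[df.x == 1, "follow_up"]
        )
        assert chi2 == pytest.approx(lr.test_statistic, abs=1e-6)
        assert p == pytest.approx(lr.p_value, abs=1e-6)

    def test_clear_separation_hr_positive(self):
        res = cox_regression(self.two_group_data(), ["x"])
        assert res.estimates["x"] > 1.0
        assert res.p_values["x"] < 0.01

    def test_constant_covariate_rejected(self):
        df = self.two_group_data()
        df["x"] = 1.0
        with pytest.raises(ValueError):
            cox_regression(df, ["x"])

    def test_zero_events_rejected(self):
        df = self.two_group_data()
        df["outcome"] = False
        with pytest.raises(ValueError):
            cox_regression(df, ["x"])

    def test_parameter_recovery(self):
        # exponential survival, true log-HR 0.5, 30% independent censoring
        rng = np.random.default_rng(40)
        errs = []
        for _ in range(50):
            x = rng.normal(size=600)
            t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
            c = rng.exponential(1.0 / (0.1 * 0.3 / 0.7))
            df = pd.DataFrame({"follow_up": np.minimum(t, c),
                               "outcome": t <= c, "x": x})
            res = cox_regression(df, ["x"])
            errs.append(np.log(res.estimates["x"]) - 0.5)
        assert abs(np.mean(errs)) < 0.15


@pytest.fixture(scope="module")
def frames(pool):
    from snowmatch.synthetic_cohorts import SimulationConfig, simulate_pregnancy
    out = {}
    for coupling in (0.0, 0.8):
        cfg = SimulationConfig(seed=0, n_cases=900, cross_locus_coupling=coupling)
        cases = simulate_pregnancy(pool, cfg, seed=77)
        out[coupling] = cross_locus_frame(cases)
    return out


class TestCrossLocus:
    def test_subset_fully_mismatched(self, pool):
        from snowmatch.synthetic_cohorts import SimulationConfig, simulate_pregnancy
        cases = simulate_pregnancy(pool, SimulationConfig(seed=0, n_cases=200), seed=5)
        frame = cross_locus_frame(cases)
        kept = set(frame["case_id"])
        for case in cases:
            informative_all = all(
                not set(case["child"][L]) <= set(case["mother"][L]) for L in "ABC"
            )
            assert (case["case_id"] in kept) == informative_all

    def test_null_conditional_off_locus_or_near_one(self, frames):
        # without coupling, off-locus effects conditional on the own-locus
        # score stay near 1 (marginal effects pick up haplotype linkage)
        import statsmodels.api as sm
        frame = frames[0.0]
        log_ors = []
        for tgt in "ABC":
            offs = [f"z_snowflake_{s}" for s in "ABC" if s != tgt]
            X = sm.add_constant(frame[[f"z_snowflake_{tgt}"] + offs].astype(float))
            fit = sm.GLM(frame[f"csa_{tgt}"].astype(float), X,
                         family=sm.families.Binomial()).fit()
            log_ors.extend(float(fit.params[o]) for o in offs)
        assert abs(np.mean(log_ors)) < 0.15

    def test_coupled_off_locus_detectable(self, frames):
        table = cross_locus_table(frames[0.8])
        significant = 0
        for tgt in "ABC":
            for pred, res in table[tgt]["univariable"].items():
                if pred.startswith("z_snowflake") and not pred.endswith(tgt):
                    if res.estimates[pred] > 1.0 and res.p_values[pred] < 0.05:
                        significant += 1
        assert significant >= 3

    def test_stepwise_present_per_target(self, frames):
        table = cross_locus_table(frames[0.0])
        for tgt in "ABC":
            assert table[tgt]["stepwise"].aic > 0
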