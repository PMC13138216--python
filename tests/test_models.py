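"""Multinomial risk models, constrained LRTs, persistence ORs, descriptives."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from traumameta._glm import equality_mapping, fit_logistic_ml, fit_multinomial_ml
from traumameta.models import (
    constrained_lrt,
    describe_groups,
    fit_multinomial,
    fit_persistence_logistic,
    pool_lrt_d2,
)
from conftest import make_persistence_frame


def simulate_multinomial(rng, n, beta):
    """beta has shape (p, K-1); column 0 of X is the intercept."""
    p = beta.shape[0]
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    eta = np.hstack([np.zeros((n, 1)), X @ beta])
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    y = (rng.random(n)[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)
    return X, y


class TestMultinomialFitter:
    def test_intercept_only_recovers_sample_frequencies(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 500)
        X = np.ones((500, 1))
        fit = fit_multinomial_ml(X, y, n_categories=3)
        beta = fit.params
        p = np.exp([0.0, beta[0], beta[1]])
        p /= p.sum()
        freqs = np.bincount(y) / 500
        assert np.allclose(p, freqs, atol=1e-8)

    def test_loglik_matches_direct_optimizer_oracle(self):
        rng = np.random.default_rng(1)
        X, y = simulate_multinomial(rng, 30, np.array([[0.2, -0.3], [0.5, 0.1], [-0.2, 0.4]]))

        def nll(b):
            eta = np.hstack([np.zeros((30, 1)), X @ b.reshape(3, 2, order="F")])
            lse = np.log(np.exp(eta).sum(axis=1))
            return -(eta[np.arange(30), y] - lse).sum()

        oracle = minimize(nll, np.zeros(6), method="Nelder-Mead",
                          options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        fit = fit_multinomial_ml(X, y, n_categories=3)
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-6)

    def test_matches_statsmodels_mnlogit(self):
        rng = np.random.default_rng(2)
        X, y = simulate_multinomial(rng, 400, np.array([[0.2, -0.3], [0.5, 0.1], [-0.2, 0.4]]))
        fit = fit_multinomial_ml(X, y, n_categories=3)
        ref = sm.MNLogit(y, X).fit(disp=0)
        assert np.abs(fit.params.reshape(3, 2, order="F") - ref.params).max() < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_two_categories_reduce_to_binary_logistic(self):
        rng = np.random.default_rng(3)
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ [0.2, 0.7, -0.4])))).astype(int)
        multi = fit_multinomial_ml(X, y, n_categories=2)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.abs(multi.params - ref.params).max() < 1e-6

    def test_binary_alias(self):
        rng = np.random.default_rng(4)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.4).astype(int)
        a = fit_logistic_ml(X, y)
        b = fit_multinomial_ml(X, y, n_categories=2)
        assert np.allclose(a.params, b.params)


class TestConstrainedLRT:
    def test_statistic_nonnegative_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            X, y = simulate_multinomial(
                rng, 150, rng.normal(0, 0.4, size=(3, 2))
            )
            fu = fit_multinomial_ml(X, y, n_categories=3)
            M = equality_mapping(3, 2, [1])
            fc = fit_multinomial_ml(X, y, n_categories=3, mapping=M)
            assert 2 * (fu.loglik - fc.loglik) >= -1e-8

    def test_constrained_fit_enforces_equality(self):
        rng = np.random.default_rng(6)
        X, y = simulate_multinomial(rng, 500, np.array([[0.1, 0.2], [0.8, 0.3], [0.0, 0.0]]))
        M = equality_mapping(3, 2, [1])
        fc = fit_multinomial_ml(X, y, n_categories=3, mapping=M)
        beta = (M @ fc.params).reshape(3, 2, order="F")
        assert beta[1, 0] == pytest.approx(beta[1, 1])

    def test_invariant_to_rescaling_other_covariates(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "study_id": "s1",
                "age": rng.normal(38, 10, n),
                "female": rng.random(n) < 0.5,
                "single": rng.random(n) < 0.5,
                "below_secondary": rng.random(n) < 0.2,
                "prior_trauma": rng.choice(["none", "non-interpersonal", "interpersonal"], n),
                "index_trauma": rng.choice(["MVA", "other_accident", "assault"], n),
                "ptsd_trajectory": rng.choice(["Never", "Acute", "Persistent"], n,
                                               p=[0.6, 0.25, 0.15]),
            }
        )
        r1 = constrained_lrt(df, "ptsd", "female", study_dummies=False)
        df2 = df.copy()
        df2["age"] = df2["age"] * 10 + 3  # affine rescale of another covariate
        r2 = constrained_lrt(df2, "ptsd", "female", study_dummies=False)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-5)

    def test_power_against_unequal_effects(self):
        """beta_acute = 0 vs beta_persistent = ln 2 should be detected more
        often than not at n = 4000."""
        rejections = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            beta = np.array([[-0.8, -1.2], [0.0, np.log(2)], [0.3, 0.3]])
            X, y = simulate_multinomial(rng, 4000, beta)
            fu = fit_multinomial_ml(X, y, n_categories=3)
            M = equality_mapping(3, 2, [1])
            fc = fit_multinomial_ml(X, y, n_categories=3, mapping=M)
            stat = 2 * (fu.loglik - fc.loglik)
            from scipy.stats import chi2

            rejections += chi2.sf(stat, 1) < 0.05
        assert rejections / reps > 0.5

    def test_d2_pooling_single_and_multiple(self):
        stat, p = pool_lrt_d2([3.84], df=1)
        assert p == pytest.approx(0.05, abs=0.001)
        stat_m, p_m = pool_lrt_d2([2.0, 3.0, 4.0], df=1)
        assert stat_m >= 0 and 0 <= p_m <= 1


class TestPersistenceModels:
    def test_null_coefficient_gives_unit_or_at_any_increment(self):
        rng = np.random.default_rng(8)
        df, _ = make_persistence_frame(rng, 3000, beta_sev=0.0)
        out = fit_persistence_logistic([df], "ptsd", model=1, study_dummies=False)
        row = out[out["predictor"] == "w1_dep_severity"].iloc[0]
        assert row["increment"] == 5.0
        assert row["or_low"] < 1.0 < row["or_high"]

    def test_scaled_or_arithmetic(self):
        # a log-odds of 0.0314 per point is an OR of exp(5 * 0.0314) = 1.17
        assert np.exp(5 * 0.0314) == pytest.approx(1.17, abs=0.005)
        rng = np.random.default_rng(9)
        df, _ = make_persistence_frame(rng, 4000, beta_sev=0.0314)
        out = fit_persistence_logistic([df], "ptsd", model=1, study_dummies=False)
        row = out[out["predictor"] == "w1_dep_severity"].iloc[0]
        assert row["or"] == pytest.approx(np.exp(5 * row["log_or_per_unit"]))

    def test_per15_point_ptsd_or_recovery(self):
        """Generative per-15-point OR of 1.15 should be covered by the CI in
        at least 90% of replicates."""
        hits = 0
        reps = 40
        beta = np.log(1.15) / 15
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            df, _ = make_persistence_frame(
                rng, 2500, beta_sev=beta, sev_col="w1_ptsd_severity", sev_sd=20
            )
            out = fit_persistence_logistic([df], "mdd", model=1, study_dummies=False)
            row = out[out["predictor"] == "w1_ptsd_severity"].iloc[0]
            hits += row["or_low"] <= 1.15 <= row["or_high"]
        assert hits >= 0.9 * reps

    def test_model_extras_by_specification(self):
        rng = np.random.default_rng(10)
        df, _ = make_persistence_frame(rng, 1500, beta_sev=0.02)
        m3 = fit_persistence_logistic([df], "ptsd", model=3, study_dummies=False)
        preds = set(m3["predictor"])
        assert {"w1_dep_severity", "w1_ptsd_B", "w1_ptsd_C", "w1_ptsd_D"} <= preds
        assert "w1_ptsd_severity" not in preds
        with pytest.raises(ValueError):
            fit_persistence_logistic([df], "ptsd", model=4)


def table3_like_fixture():
    """Participant-level frame reproducing printed group-count margins."""
    rows = []

    def add(group, n, female, assault, other, mva):
        for i in range(n):
            rows.append(
                {
                    "ptsd_trajectory": group,
                    "female": i < female,
                    "single": False,
                    "below_secondary": False,
                    "prior_trauma": "none",
                    "index_trauma": (
                        "assault" if i < assault
                        else "other_accident" if i < assault + other
                        else "MVA" if i < assault + other + mva
                        else np.nan
                    ),
                    "age": 38.0,
                }
            )

    add("Never", 1363, female=424, assault=66, other=338, mva=951)
    add("Acute", 267, female=136, assault=29, other=23, mva=214)
    add("Persistent", 138, female=77, assault=20, other=7, mva=110)
    add("Unclassifiable-missing", 803, female=283, assault=67, other=149, mva=586)
    return pd.DataFrame(rows)


class TestDescriptives:
    def test_reproduces_percentages_from_printed_counts(self):
        df = table3_like_fixture()
        desc = describe_groups(df, "ptsd")
        fem = desc[(desc["variable"] == "female") & (desc["level"] == "yes")]
        by_group = fem.set_index("group")["pct"]
        assert by_group["Acute"] == pytest.approx(50.9, abs=0.05)
        assert by_group["Persistent"] == pytest.approx(55.8, abs=0.05)
        asl = desc[(desc["variable"] == "index_trauma") & (desc["level"] == "assault")]
        asl = asl.set_index("group")
        # non-missing denominator: 110 + 7 + 20 = 137 in the persistent group
        assert asl.loc["Persistent", "denominator"] == 137
        assert asl.loc["Persistent", "pct"] == pytest.approx(14.6, abs=0.05)
        assert asl.loc["Acute", "pct"] == pytest.approx(10.9, abs=0.05)

    def test_flat_contingency_table_gives_zero_chi2(self):
        from scipy.stats import chi2_contingency

        stat = chi2_contingency(np.array([[10, 10], [10, 10]]))[0]
        assert stat == 0.0

    def test_empty_group_raises(self):
        df = table3_like_fixture()
        df = df[df["ptsd_trajectory"] != "Acute"]
        with pytest.raises(ValueError, match="empty"):
            describe_groups(df, "ptsd")
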