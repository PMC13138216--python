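"""Chained-equations imputation and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from traumameta.mice import (
    ImputationSpec,
    chain_autocorrelation,
    fit_continuous_mixed,
    impute_binary_probit,
    impute_continuous_mixed,
    rubin_pool,
    run_mice,
    select_predictors,
)


def make_long_table(rng, n=300, miss_rate=0.3, study_var_ratio=1.0):
    """Two-wave table with participant random intercept and study effects."""
    pid = np.repeat(np.arange(n), 2)
    wave = np.tile([1, 2], n)
    study = np.repeat(np.where(np.arange(n) % 2 == 0, "A", "B"), 2)
    u = np.repeat(rng.normal(0, 1, n), 2)
    x = rng.normal(0, 1, 2 * n)
    sd = np.where(study == "A", 1.0, np.sqrt(study_var_ratio))
    y = 1.0 + 0.8 * x + 0.5 * (study == "B") + u + rng.normal(0, sd)
    d = (rng.random(2 * n) < 1 / (1 + np.exp(-(0.8 * x)))).astype(float)
    tab = pd.DataFrame(
        {"participant_id": pid, "study_id": study, "wave": wave, "x": x, "y": y, "d": d}
    )
    miss = (wave == 2) & (rng.random(2 * n) < miss_rate)
    tab.loc[miss, ["y", "d"]] = np.nan
    return tab, y, d


class TestRubinPooling:
    def test_textbook_arithmetic(self):
        p = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert p.estimate == 2.0
        assert p.within_var == 1.0
        assert p.between_var == 1.0
        assert p.total_var == pytest.approx(7.0 / 3.0)
        assert p.total_var >= p.within_var

    def test_identical_estimates_degenerate_to_within_variance(self):
        p = rubin_pool([1.5] * 5, [0.4] * 5)
        assert p.between_var == 0.0 and p.total_var == 0.4

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rubin_pool([1.0], [1.0])
        with pytest.raises(ValueError):
            rubin_pool([1.0, 2.0], [1.0, 0.0])

    def test_mcar_coverage_of_complete_data_mean(self):
        """Pooled CIs should cover the complete-data mean at near-nominal
        rate under MCAR deletion."""
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            tab, y_full, _ = make_long_table(rng, n=120, miss_rate=0.3)
            truth = y_full.mean()
            ests, vars_ = [], []
            for k in range(8):
                filled = impute_continuous_mixed(
                    tab, "y", ["x", "wave"], seed=rep * 100 + k
                )
                ests.append(filled.mean())
                vars_.append(filled.var(ddof=1) / len(filled))
            p = rubin_pool(ests, vars_)
            hits += p.ci_low <= truth <= p.ci_high
        assert hits >= 90


class TestPredictorScreen:
    @pytest.fixture()
    def screening_table(self):
        rng = np.random.default_rng(5)
        n = 400
        t = rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "target": t,
                "strong": 0.8 * t + 0.6 * rng.normal(0, 1, n),
                "medium": 0.3 * t + rng.normal(0, 1, n),
                "weak": 0.02 * t + rng.normal(0, 1, n),
                "noise": rng.normal(0, 1, n),
            }
        )

    def test_threshold_zero_selects_everything(self, screening_table):
        got = select_predictors(screening_table, "target", threshold=0.0)
        assert set(got) == {"strong", "medium", "weak", "noise"}

    def test_only_variables_above_threshold_selected(self, screening_table):
        got = select_predictors(screening_table, "target", threshold=0.10)
        assert "strong" in got and "medium" in got
        assert "weak" not in got
        assert got[0] == "strong"  # ordered by correlation strength

    def test_target_excluded_from_own_predictors(self, screening_table):
        got = select_predictors(screening_table, "target", threshold=0.0)
        assert "target" not in got

    def test_always_columns_appended(self, screening_table):
        screening_table["study_B"] = 0.0
        got = select_predictors(
            screening_table, "target", threshold=0.10, always=("study_B",)
        )
        assert got[-1] == "study_B"

    def test_constant_target_rejected(self, screening_table):
        screening_table["flat"] = 1.0
        with pytest.raises(ValueError):
            select_predictors(screening_table, "flat")


class TestConditionalModels:
    def test_no_missing_returns_input_unchanged(self):
        rng = np.random.default_rng(0)
        tab, _, _ = make_long_table(rng, miss_rate=0.0)
        out = impute_continuous_mixed(tab, "y", ["x"], seed=1)
        assert np.array_equal(out, tab["y"].to_numpy())
        out_b = impute_binary_probit(tab, "d", ["x"], seed=1)
        assert np.array_equal(out_b, tab["d"].to_numpy())

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(1)
        tab, _, _ = make_long_table(rng)
        obs = tab["y"].notna()
        out = impute_continuous_mixed(tab, "y", ["x", "wave"], seed=2)
        assert np.allclose(out[obs], tab.loc[obs, "y"])

    def test_study_residual_variances_ordered_concordantly(self):
        """True 4:1 study residual-variance ratio should be recovered in
        direction in the vast majority of replicates."""
        wins = 0
        for rep in range(40):
            rng = np.random.default_rng(rep)
            tab, _, _ = make_long_table(rng, n=250, miss_rate=0.0, study_var_ratio=4.0)
            X = np.column_stack([np.ones(len(tab)), tab["x"], tab["study_id"] == "B"])
            fit = fit_continuous_mixed(
                X.astype(float), tab["y"].to_numpy(),
                tab["participant_id"].to_numpy(), tab["study_id"].to_numpy(),
            )
            wins += fit.sigma2_by_study["B"] > fit.sigma2_by_study["A"]
        assert wins >= 36  # >= 90%

    def test_probit_imputation_tracks_predictor(self):
        rng = np.random.default_rng(3)
        tab, _, _ = make_long_table(rng, n=600, miss_rate=0.4)
        out = impute_binary_probit(tab, "d", ["x"], seed=4)
        miss = tab["d"].isna().to_numpy()
        x_m = tab.loc[miss, "x"].to_numpy()
        d_m = out[miss]
        deciles = pd.qcut(x_m, 5, labels=False)
        rates = pd.Series(d_m).groupby(deciles).mean()
        rho = np.corrcoef(np.arange(5), rates)[0, 1]
        assert rho > 0

    def test_single_class_target_rejected(self):
        rng = np.random.default_rng(4)
        tab, _, _ = make_long_table(rng)
        tab["d"] = np.where(tab["d"].isna(), np.nan, 1.0)
        with pytest.raises(Exception, match="class"):
            impute_binary_probit(tab, "d", ["x"], seed=5)


class TestChainedCycles:
    @pytest.fixture()
    def spec(self):
        return ImputationSpec(
            m=4, cycles=4, variables={"y": "continuous", "d": "binary"}, seed=99
        )

    def test_fully_observed_table_yields_identical_copies(self, spec):
        rng = np.random.default_rng(6)
        tab, _, _ = make_long_table(rng, miss_rate=0.0)
        out = run_mice(tab, spec)
        assert out.m == 4
        for ds in out.datasets:
            assert ds[["y", "d"]].equals(tab[["y", "d"]])

    def test_same_spec_and_seed_reproduce_identically(self, spec):
        rng = np.random.default_rng(7)
        tab, _, _ = make_long_table(rng)
        a = run_mice(tab, spec)
        b = run_mice(tab, spec)
        assert all(x.equals(y) for x, y in zip(a.datasets, b.datasets))

    def test_no_missing_cells_remain_and_observed_shared(self, spec):
        rng = np.random.default_rng(8)
        tab, _, _ = make_long_table(rng)
        out = run_mice(tab, spec)
        obs = tab["y"].notna()
        for ds in out.datasets:
            assert not ds[["y", "d"]].isna().any().any()
            assert np.allclose(ds.loc[obs, "y"], tab.loc[obs, "y"])

    def test_chain_means_mix_quickly(self):
        rng = np.random.default_rng(9)
        tab, _, _ = make_long_table(rng, n=400)
        spec = ImputationSpec(
            m=3, cycles=10, variables={"y": "continuous", "d": "binary"}, seed=17
        )
        out = run_mice(tab, spec)
        ac = chain_autocorrelation(out.metadata["chain_means"]["y"], burn_in=2)
        assert abs(ac) < 0.5

    def test_categorical_variable_reassembled(self):
        rng = np.random.default_rng(10)
        tab, _, _ = make_long_table(rng, miss_rate=0.0)
        cat = rng.choice(["lo", "mid", "hi"], size=len(tab))
        tab["grp"] = cat
        tab.loc[rng.random(len(tab)) < 0.2, "grp"] = np.nan
        spec = ImputationSpec(m=2, cycles=2, variables={"grp": "categorical"}, seed=3)
        out = run_mice(tab, spec)
        for ds in out.datasets:
            assert ds["grp"].notna().all()
            assert set(ds["grp"].unique()) <= {"lo", "mid", "hi"}
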