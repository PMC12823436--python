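import numpy as np
import pandas as pd
import pytest

from metbmikit.metbmi import (MetBMIRegressor, balanced_strata_sample, fit_metbmi,
                              predict_metbmi, residualize_and_classify,
                              select_bmi_metabolites, split_train_test,
                              who_bmi_class)


def _cohort_with_strata(sizes, seed=0):
    """Cohort with exact per-stratum sizes: (f/n, f/ov, f/ob, m/n, m/ov, m/ob)."""
    rng = np.random.default_rng(seed)
    ranges = [(18.5, 24.9), (25.0, 29.9), (30.0, 40.0)] * 2
    sexes = [0, 0, 0, 1, 1, 1]
    rows = []
    for size, (lo, hi), sex in zip(sizes, ranges, sexes):
        for _ in range(size):
            rows.append({"age": rng.uniform(50, 65), "sex": sex,
                         "BMI": rng.uniform(lo, hi)})
    df = pd.DataFrame(rows, index=[f"S{i:05d}" for i in range(len(rows))])
    return df.sample(frac=1, random_state=1)   # shuffle rows


class TestPrefilter:
    def test_metabolite_equal_to_bmi_retained_first(self, rng):
        bmi = rng.uniform(19, 40, 200)
        met = pd.DataFrame({"self": bmi, "noise": rng.normal(size=200)})
        out = select_bmi_metabolites(met, bmi)
        assert out["metabolite"].iloc[0] == "self"
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_metabolite_excluded(self):
        excluded = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            bmi = rng.uniform(19, 40, 1400)
            met = pd.DataFrame({"sig": bmi + rng.normal(0, 5, 1400),
                                "null": rng.normal(size=1400)})
            out = select_bmi_metabolites(met, bmi)
            excluded += "null" not in set(out["metabolite"])
        assert excluded >= 49

    def test_planted_informative_set_recalled(self, default_cohort):
        layers, cohort, truth = default_cohort
        out = select_bmi_metabolites(layers["metabolome"].to_frame(), cohort["BMI"])
        recall = len(set(out["metabolite"]) & set(truth.informative_metabolites)) / 267
        assert recall >= 0.95

    def test_empty_result_advises(self, rng):
        met = pd.DataFrame({"a": rng.normal(size=100)})
        with pytest.raises(ValueError, match="relaxing"):
            select_bmi_metabolites(met, rng.uniform(19, 40, 100))


class TestBalancedSampling:
    def test_published_worked_example_774(self):
        # smallest stratum = 129 men with normal-weight BMI -> pool 6 x 129
        cohort = _cohort_with_strata([200, 300, 160, 129, 310, 150])
        pool = balanced_strata_sample(cohort, seed=0)
        assert pool.sampled_per_stratum == 129
        assert len(pool.pool_ids) == 774

    def test_equal_strata_give_six_s(self):
        pool = balanced_strata_sample(_cohort_with_strata([40] * 6), seed=0)
        assert len(pool.pool_ids) == 240

    def test_minimum_rule_by_hand(self):
        pool = balanced_strata_sample(
            _cohort_with_strata([10, 20, 30, 40, 50, 60]), seed=0)
        assert len(pool.pool_ids) == 60

    def test_underweight_routed_outside_strata(self):
        cohort = _cohort_with_strata([20] * 6)
        extra = pd.DataFrame({"age": [55.0], "sex": [0], "BMI": [18.3]},
                             index=["UNDER"])
        pool = balanced_strata_sample(pd.concat([cohort, extra]), seed=0)
        assert pool.outside_strata_ids == ["UNDER"]
        assert "UNDER" not in pool.pool_ids

    def test_empty_stratum_reported(self):
        cohort = _cohort_with_strata([10, 10, 0, 10, 10, 10])
        with pytest.raises(ValueError, match="female/obesity"):
            balanced_strata_sample(cohort, seed=0)


class TestSplit:
    def test_774_pool_splits_580_194(self):
        cohort = _cohort_with_strata([200, 300, 160, 129, 310, 150])
        pool = balanced_strata_sample(cohort, seed=0)
        train, test, extended = split_train_test(pool, cohort, seed=0)
        assert abs(len(train) - 0.75 * 774) <= 3
        assert len(train) + len(test) == 774
        assert set(train).isdisjoint(test)
        assert set(extended) >= set(test)
        assert len(extended) == len(cohort) - len(train)

    def test_seeded_reproducibility(self):
        cohort = _cohort_with_strata([30] * 6)
        pool = balanced_strata_sample(cohort, seed=5)
        a = split_train_test(pool, cohort, seed=7)
        b = split_train_test(pool, cohort, seed=7)
        assert a == b


class TestMetBMIRegressor:
    def test_noiseless_linear_bmi_nearly_exact(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 10)),
                         columns=[f"m{j}" for j in range(10)])
        y = X.to_numpy() @ rng.normal(size=10) + 27
        est = MetBMIRegressor(seed=0).fit(X.iloc[:200], y[:200])
        pred = est.predict(X.iloc[200:])
        r2 = 1 - ((pred - y[200:]) ** 2).sum() / ((y[200:] - y[200:].mean()) ** 2).sum()
        assert r2 >= 0.99

    def test_permuted_labels_give_null_test_r2(self):
        r2s = []
        for s in range(20):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(260, 20)))
            y = rng.permutation(X.iloc[:, 0].to_numpy() + rng.normal(size=260))
            est = MetBMIRegressor(seed=s, grid_length=30).fit(X.iloc[:200], y[:200])
            pred = est.predict(X.iloc[200:])
            r2s.append(1 - ((pred - y[200:]) ** 2).sum()
                       / ((y[200:] - y[200:].mean()) ** 2).sum())
        assert np.median(r2s) <= 0.05

    def test_training_predictions_match_fitted_values(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        y = X.iloc[:, 0].to_numpy() + rng.normal(size=100)
        est = MetBMIRegressor(seed=0, k_cv=5).fit(X, y)
        np.testing.assert_allclose(est.predict(X), est._fit.predict(X.to_numpy()),
                                   atol=1e-9)

    def test_duplicated_row_predicts_identically(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)))
        y = X.iloc[:, 0].to_numpy() * 2 + 27
        est = MetBMIRegressor(seed=0, k_cv=5).fit(X, y)
        row = X.iloc[[3]]
        assert est.predict(row)[0] == est.predict(pd.concat([row, row]))[1]

    def test_all_mean_profile_predicts_training_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 6)))
        y = X.iloc[:, 0].to_numpy() + 27 + rng.normal(size=100)
        est = MetBMIRegressor(seed=0, k_cv=5).fit(X, y)
        mean_profile = X.mean().to_frame().T
        assert est.predict(mean_profile)[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_non_finite_feature_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        X.loc[X.index[5], "b"] = np.inf
        with pytest.raises(ValueError, match="b"):
            MetBMIRegressor().fit(X, rng.normal(size=60))

    def test_missing_metabolite_at_predict_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        est = MetBMIRegressor(k_cv=5).fit(X, X["a"].to_numpy() + 27)
        with pytest.raises(ValueError, match="c"):
            est.predict(X[["a", "b"]])

    def test_sklearn_contract(self):
        est = MetBMIRegressor(penalty="lasso", k_cv=3)
        params = est.get_params()
        assert params["penalty"] == "lasso"
        est.set_params(penalty="ridge")
        assert est.get_params()["penalty"] == "ridge"


class TestFitPredictPipeline:
    def test_planted_r2_regime(self, default_cohort):
        layers, cohort, truth = default_cohort     # planted R^2 = 0.4
        met = layers["metabolome"].to_frame()
        pre = select_bmi_metabolites(met, cohort["BMI"])
        pool = balanced_strata_sample(cohort, seed=1)
        train, test, ext = split_train_test(pool, cohort, seed=1)
        model = fit_metbmi(met, cohort, pre["metabolite"].tolist(), train, test, seed=1)
        assert 0.33 <= model.test_r2 <= 0.47
        assert set(model.coefficients) == set(model.prefilter_ids) | {"(intercept)"}
        preds = predict_metbmi(model, met)
        assert len(preds) == len(cohort)


class TestResidualClassification:
    def _inputs(self, rng, n=400):
        cohort = _cohort_with_strata([n // 6] * 6, seed=3)
        metbmi = (0.6 * cohort["BMI"] + 0.02 * cohort["age"]
                  + rng.normal(0, 1.8, len(cohort)) + 10)
        return pd.Series(metbmi, index=cohort.index), cohort

    def test_residuals_orthogonal_to_covariates(self, rng):
        metbmi, cohort = self._inputs(rng)
        cls = residualize_and_classify(metbmi, cohort)
        for v in cls.residual_covariate_corr.values():
            assert abs(v) < 1e-8

    def test_partition_and_threshold_overrides(self, rng):
        metbmi, cohort = self._inputs(rng)
        cls = residualize_and_classify(metbmi, cohort)
        assert cls.table["group"].notna().all()
        assert sum(cls.group_sizes.values()) == len(cohort)
        high = cls.table[cls.table["residual"] > 2.5]
        assert (high["group"] == "HmetBMI").all()
        low = cls.table[cls.table["residual"] < -2.5]
        assert (low["group"] == "LmetBMI").all()

    def test_tail_overrides_who_class(self):
        cohort = pd.DataFrame({"age": np.random.default_rng(1).uniform(50, 65, 40),
                               "sex": [0, 1] * 20,
                               "BMI": np.linspace(20, 35, 40)},
                              index=[f"S{i}" for i in range(40)])
        base = pd.Series(np.zeros(40), index=cohort.index)
        base.iloc[7] = -3.0     # strong negative residual
        cls = residualize_and_classify(base + 25, cohort)
        resid = cls.table["residual"]
        assert (cls.table.loc[resid < -2.5, "group"] == "LmetBMI").all()

    def test_boundary_and_tail_rule_cases(self):
        from metbmikit.metbmi import classify_residuals
        groups = classify_residuals([-3.0, 0.0, 2.5, 2.500001, -2.5],
                                    [31.0, 22.0, 27.0, 27.0, 22.0])
        # residual -3.0 at BMI 31 overrides the obesity class
        assert groups[0] == "LmetBMI"
        assert groups[1] == "normal weight"
        # exactly +2.5 stays in its WHO class (strict inequality) ...
        assert groups[2] == "overweight"
        # ... while anything beyond is a tail group
        assert groups[3] == "HmetBMI"
        assert groups[4] == "normal weight"

    def test_who_classes(self):
        np.testing.assert_array_equal(
            who_bmi_class([18.3, 22.0, 27.0, 31.0]),
            ["normal weight", "normal weight", "overweight", "obesity"])

    def test_rank_deficient_design_fails(self, rng):
        cohort = _cohort_with_strata([10] * 6)
        cohort["sex"] = 0   # constant -> rank deficient
        metbmi = pd.Series(rng.normal(27, 2, len(cohort)), index=cohort.index)
        with pytest.raises(ValueError, match="rank"):
            residualize_and_classify(metbmi, cohort)
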