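"""Heuristic-method model selection and validation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from terpentox import qsar, synthetic
from terpentox.qsar import (
    ScreeningConfig,
    evaluate_external,
    exhaustive_search,
    fit_mlr,
    flag_outliers,
    heuristic_search,
    loo_q2,
    max_descriptors,
    prescreen,
    split_train_test,
)


def _random_problem(rng, n=20, p=6, signal=2):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"D{j + 1}" for j in range(p)])
    y = X.iloc[:, :signal] @ np.arange(1, signal + 1) + rng.normal(0, 0.5, n)
    return X, pd.Series(np.asarray(y))


class TestPrescreen:
    def test_constant_and_missing_tagged(self, rng):
        X, y = _random_problem(rng)
        X["CONST"] = 3.14
        X["MISS"] = X["D1"].to_numpy()
        X.loc[X.index[4], "MISS"] = np.nan
        report = prescreen(X, y)
        assert report.rules["CONST"] == "constant"
        assert report.rules["MISS"] == "missing"
        assert report.check_partition(X.columns)

    def test_duplicate_column_one_survives(self, rng):
        X, y = _random_problem(rng)
        X["D1_copy"] = X["D1"].to_numpy()
        report = prescreen(X, y)
        assert ("D1" in report.surviving) != ("D1_copy" in report.surviving)
        dropped = "D1_copy" if "D1" in report.surviving else "D1"
        assert report.rules[dropped].startswith("collinear(")

    def test_pathology_matrix_matches_ground_truth(self):
        X, y, expected = synthetic.gen_prescreen_case(seed=3)
        report = prescreen(X, y)
        for name, rule in expected.items():
            assert report.rules.get(name, "").startswith(rule), (name, report.rules.get(name))
        assert not (set(expected) & set(report.surviving))

    def test_low_t_reachable_when_f_rule_relaxed(self):
        X, y, _ = synthetic.gen_prescreen_case(seed=3)
        report = prescreen(X, y, ScreeningConfig(f_min=0.0))
        assert report.rules["ORTHO1"] == "low_t"

    def test_too_few_rows(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            prescreen(X, [0.0, 1.0])


class TestFitMlr:
    def test_exact_line(self):
        x = np.arange(6, dtype=float)
        model = fit_mlr(x[:, None], 1 + 2 * x, names=["x"])
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.coefs[0] == pytest.approx(2.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0)
        assert model.s2 == pytest.approx(0.0, abs=1e-18)

    def test_against_statsmodels(self, rng):
        """Coefficients, SEs, t, r2, F match the independent OLS oracle."""
        X, y = _random_problem(rng, n=15, p=3, signal=3)
        model = fit_mlr(X, y)
        ols = sm.OLS(np.asarray(y), sm.add_constant(X.to_numpy())).fit()
        assert model.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert np.allclose(model.coefs, ols.params[1:], atol=1e-10)
        assert np.allclose(model.tstats, ols.tvalues[1:], atol=1e-8)
        assert model.r2 == pytest.approx(ols.rsquared, abs=1e-12)
        assert model.F == pytest.approx(ols.fvalue, abs=1e-8)
        assert model.s2 == pytest.approx(ols.mse_resid, abs=1e-12)

    def test_f_equals_t_squared_univariate(self, rng):
        X, y = _random_problem(rng, n=12, p=1, signal=1)
        model = fit_mlr(X, y)
        assert model.F == pytest.approx(model.tstats[0] ** 2, rel=1e-10)

    def test_saturated_design_rejected(self):
        with pytest.raises(ValueError):
            fit_mlr(np.eye(3)[:, :2], [1.0, 2.0, 3.0])

    def test_collinear_rejected(self):
        x = np.arange(8, dtype=float)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_mlr(X, x)


class TestLooQ2:
    def test_noiseless_is_one(self):
        x = np.arange(10, dtype=float)
        assert loo_q2(x[:, None], 3 - x) == pytest.approx(1.0)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError, match="SST"):
            loo_q2(np.arange(8.0)[:, None], np.ones(8))

    def test_matches_literal_refit_oracle(self, rng):
        """Hat-matrix PRESS equals n explicit refits to 1e-10."""
        for _ in range(10):
            n, p = int(rng.integers(8, 25)), int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = X @ rng.normal(size=p) + rng.normal(0, 0.8, n)
            press = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                A = np.column_stack([np.ones(n - 1), X[mask]])
                beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
                pred = beta[0] + X[i] @ beta[1:]
                press += (y[i] - pred) ** 2
            sst = ((y - y.mean()) ** 2).sum()
            assert loo_q2(X, y) == pytest.approx(1 - press / sst, abs=1e-10)

    def test_insufficient_rows(self):
        with pytest.raises(ValueError):
            loo_q2(np.arange(3.0)[:, None], np.arange(3.0) ** 2)


class TestMaxDescriptors:
    @pytest.mark.parametrize("n,cap,expected", [(22, 4, 4), (8, 4, 2), (100, 4, 4),
                                                (19, 4, 4), (15, 4, 3), (5, 4, 1)])
    def test_ratio_rule(self, n, cap, expected):
        assert max_descriptors(n, cap) == expected

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            max_descriptors(4)


class TestSearch:
    def test_heuristic_equals_exhaustive_generous_beam(self, rng):
        for _ in range(10):
            X, y = _random_problem(rng, n=18, p=8, signal=3)
            ex = exhaustive_search(X, y, max_desc=3, compute_q2=False)
            he = heuristic_search(X, y, max_desc=3, beam_width=200, compute_q2=False)
            assert set(he.models[0].names) == set(ex.models[0].names)
            assert he.models[0].r2 == pytest.approx(ex.models[0].r2, abs=1e-12)

    def test_exhaustive_dominates_heuristic(self, rng):
        X, y = _random_problem(rng, n=18, p=10, signal=3)
        ex = exhaustive_search(X, y, max_desc=3, compute_q2=False)
        he = heuristic_search(X, y, max_desc=3, beam_width=2, compute_q2=False)
        assert ex.models[0].r2 >= he.models[0].r2 - 1e-12

    def test_exhaustive_counts_subsets(self, rng):
        X, y = _random_problem(rng, n=20, p=10, signal=2)
        res = exhaustive_search(X, y, max_desc=3, compute_q2=False)
        assert res.settings["n_subsets"] == 120

    def test_exhaustive_limit(self, rng):
        X, y = _random_problem(rng, n=20, p=10, signal=2)
        with pytest.raises(ValueError, match="heuristic_search"):
            exhaustive_search(X, y, max_desc=3, limit=100)

    def test_single_descriptor_reduction(self, rng):
        X, y = _random_problem(rng, n=20, p=6, signal=2)
        res = heuristic_search(X, y, max_desc=1, compute_q2=False)
        best_by_corr = max(
            X.columns, key=lambda c: abs(np.corrcoef(X[c], y)[0, 1])
        )
        assert res.models[0].names == (best_by_corr,)

    def test_planted_model_recovered_low_noise(self):
        cfg = synthetic.SynthConfig(n_compounds=25, p_descriptors=30, noise_sd=0.1,
                                    rho=0.0, n_constant=0, n_missing=0,
                                    n_duplicate=0, seed=7)
        X, truth = synthetic.gen_descriptor_matrix(cfg)
        y = synthetic.gen_activity(X, truth.beta, cfg.noise_sd, seed=8,
                                   intercept=truth.intercept)
        res = heuristic_search(X.values, y, max_desc=4, beam_width=50)
        assert set(res.models[0].names) == set(truth.active)
        assert res.models[0].q2 is not None and res.models[0].q2 > 0.9

    def test_ranking_monotone(self, rng):
        X, y = _random_problem(rng, n=18, p=8, signal=3)
        res = heuristic_search(X, y, max_desc=3, beam_width=20, compute_q2=False)
        r2s = [m.r2 for m in res.models]
        assert r2s == sorted(r2s, reverse=True)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            heuristic_search(pd.DataFrame(index=range(5)), np.zeros(5), max_desc=1)


class TestOutliers:
    def test_clean_data_none(self):
        x = np.arange(12, dtype=float)
        model = fit_mlr(x[:, None], 2 * x + 1, names=["x"])
        assert flag_outliers(model, x[:, None], 2 * x + 1) == []

    def test_planted_outlier_found(self, rng):
        X, y = _random_problem(rng, n=20, p=2, signal=2)
        y = y.copy()
        y.iloc[7] += 10 * 0.5  # displace by 10 residual sd
        model = fit_mlr(X, y)
        assert flag_outliers(model, X, y) == [7]

    def test_refit_without_outlier_improves_r2(self, rng):
        X, y = _random_problem(rng, n=20, p=2, signal=2)
        y.iloc[3] += 6.0
        model = fit_mlr(X, y)
        out = flag_outliers(model, X, y)
        assert out
        keep = [i for i in range(len(y)) if i not in out]
        refit = fit_mlr(X.iloc[keep], y.iloc[keep])
        assert refit.r2 >= model.r2


class TestExternalValidation:
    def test_perfect_predictions(self, rng):
        X, y = _random_problem(rng, n=12, p=2, signal=2)
        model = fit_mlr(X, y)
        assert evaluate_external(model, X, model.predict(X)) == pytest.approx(1.0)

    def test_shift_convention_contrast(self, rng):
        """A constant shift keeps Pearson r2 at 1 but lowers predictive R2."""
        X, y = _random_problem(rng, n=12, p=2, signal=2)
        model = fit_mlr(X, y)
        shifted = pd.Series(model.predict(X) + 5.0)
        assert evaluate_external(model, X, shifted) == pytest.approx(1.0)
        assert evaluate_external(model, X, shifted, method="predictive") < 1.0

    def test_small_test_set_rejected(self, rng):
        X, y = _random_problem(rng, n=12, p=2, signal=2)
        model = fit_mlr(X, y)
        with pytest.raises(ValueError):
            evaluate_external(model, X.iloc[:2], y.iloc[:2])


class TestSplit:
    def test_27_to_22_5(self, rng):
        ids = [f"c{i}" for i in range(27)]
        y = pd.Series(rng.normal(size=27), index=ids)
        train, test = split_train_test(ids, y, n_test=5, seed=1)
        assert len(train) == 22 and len(test) == 5
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_test_set_spans_activity_range(self, rng):
        ids = [f"c{i}" for i in range(27)]
        y = pd.Series(np.linspace(0, 100, 27), index=ids)
        train, test = split_train_test(ids, y, n_test=5, seed=3)
        span = y.loc[test].max() - y.loc[test].min()
        assert span >= 0.6 * (y.max() - y.min())

    def test_deterministic(self, rng):
        ids = [f"c{i}" for i in range(27)]
        y = pd.Series(rng.normal(size=27), index=ids)
        assert split_train_test(ids, y, seed=9) == split_train_test(ids, y, seed=9)

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_train_test(list("abcdefg"), np.arange(7.0), n_test=5)
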