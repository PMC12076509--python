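"""Unseen-substituent splitting, LASSO/RF fitting, bootstrap evaluation."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from porphgeom.ml_analysis import (
    InfeasibleSplitError,
    SplitSpec,
    bootstrap_evaluate,
    coefficient_table,
    fit_lasso_cv,
    fit_rf,
    split_unseen_substituent,
    verify_unseen,
)


def _toy_sets(n, n_ids, rng, per=2):
    ids = [f"sub{k}" for k in range(n_ids)]
    return [frozenset(rng.choice(ids, size=per, replace=False))
            for _ in range(n)]


class TestSplit:
    def test_sizes_and_predicate_on_toy_set(self, rng):
        sets = _toy_sets(20, 12, rng)
        tr, te = split_unseen_substituent(sets, SplitSpec(0.2, seed=5))
        assert len(tr) + len(te) == 20 and len(te) == 4
        assert verify_unseen(sets, tr, te)          # exhaustive check
        # brute-force: every test structure has an identity never in train
        train_ids = set().union(*(sets[i] for i in tr))
        for i in te:
            assert sets[i] - train_ids

    def test_deterministic_for_fixed_seed(self, rng):
        sets = _toy_sets(40, 30, rng)
        s1 = split_unseen_substituent(sets, SplitSpec(0.1, seed=9))
        s2 = split_unseen_substituent(sets, SplitSpec(0.1, seed=9))
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_shared_substituent_everywhere_is_infeasible(self):
        sets = [frozenset({"common"})] * 30
        with pytest.raises(InfeasibleSplitError):
            split_unseen_substituent(sets, SplitSpec(0.1, seed=0))

    def test_population_split_has_ninety_ten_shape(self, small_population):
        data = small_population
        tr, te = split_unseen_substituent(data.substituent_sets,
                                          SplitSpec(0.1, seed=2))
        assert len(te) == round(0.1 * len(data.structures))
        assert verify_unseen(data.substituent_sets, tr, te)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.5)


class TestLasso:
    def test_constant_target_shrinks_to_intercept(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = np.full(60, 3.25)
        model = fit_lasso_cv(X, y, seed=0)
        assert np.abs(model.coef).max() < 1e-8
        assert model.intercept == pytest.approx(3.25, abs=1e-8)

    def test_planted_signs_recovered_vs_ols_oracle(self, rng):
        n = 400
        X = rng.normal(0, 1, (n, 4))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + rng.normal(0, 0.05, n)
        model = fit_lasso_cv(X, y, seed=3)
        # independent oracle: ordinary least squares on the same draw
        Z = (X - X.mean(0)) / X.std(0)
        ols = np.linalg.lstsq(np.column_stack([Z, np.ones(n)]), y,
                              rcond=None)[0][:4]
        assert model.coef[0] > 0 and model.coef[1] < 0
        assert np.abs(model.coef[2:]).max() < 0.02
        assert np.abs(model.coef[:2] - ols[:2]).max() < 0.05

    def test_duplicated_feature_splits_the_weight(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 0.05, n)
        X_single = np.column_stack([x, rng.normal(0, 1, n)])
        X_dup = np.column_stack([x, x, rng.normal(0, 1, n)])
        y = 1.5 * x + noise
        single = fit_lasso_cv(X_single, y, seed=1)
        dup = fit_lasso_cv(X_dup, y, seed=1)
        # L1 path property: duplicated columns share the single-column weight
        assert dup.coef[0] + dup.coef[1] == pytest.approx(single.coef[0],
                                                          abs=0.05)

    def test_constant_column_dropped_with_zero_coef(self, rng):
        X = np.column_stack([rng.normal(0, 1, 80), np.full(80, 7.0)])
        y = X[:, 0] * 1.2
        model = fit_lasso_cv(X, y, seed=0)
        assert model.coef[1] == 0.0

    def test_standardization_invariance_under_rescaling(self, rng):
        X = rng.normal(0, 1, (150, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.1, 150)
        base = fit_lasso_cv(X, y, seed=4)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        scaled = fit_lasso_cv(X2, y, seed=4)
        assert np.abs(base.coef - scaled.coef).max() < 1e-8


class TestRandomForest:
    def test_pure_noise_importances_are_near_uniform(self, rng):
        X = rng.normal(0, 1, (120, 4))
        y = rng.normal(0, 1, 120)
        rf = fit_rf(X, y, seed=0, n_estimators=100)
        assert rf.importances.max() < 2.0 * rf.importances.mean()

    def test_planted_feature_ranks_first(self, rng):
        X = rng.normal(0, 1, (200, 4))
        y = np.sin(X[:, 2]) * 3.0 + rng.normal(0, 0.1, 200)
        rf = fit_rf(X, y, seed=0, n_estimators=100)
        assert int(np.argmax(rf.importances)) == 2

    def test_same_seed_identical_predictions(self, rng):
        X = rng.normal(0, 1, (100, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 100)
        p1 = fit_rf(X, y, seed=7, n_estimators=50).predict(X)
        p2 = fit_rf(X, y, seed=7, n_estimators=50).predict(X)
        assert np.array_equal(p1, p2)

    def test_rf_and_lasso_agree_on_single_signal(self, rng):
        X = rng.normal(0, 1, (250, 4))
        y = 2.0 * X[:, 1] + rng.normal(0, 0.1, 250)
        rf = fit_rf(X, y, seed=0, n_estimators=100)
        lasso = fit_lasso_cv(X, y, seed=0)
        assert int(np.argmax(rf.importances)) == \
            int(np.argmax(np.abs(lasso.coef))) == 1


def _dataset(rng, n=160, sigma=0.0):
    X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
    y = X.to_numpy() @ np.array([1.0, -0.7, 0.0]) + rng.normal(0, sigma, n)
    Y = pd.DataFrame({"t": y})
    ids = [f"s{k}" for k in range(20)]
    sets = [frozenset(rng.choice(ids, size=2, replace=False))
            for _ in range(n)]
    return X, Y, sets


class TestBootstrap:
    def test_noiseless_linear_data_has_zero_mae(self, rng):
        X, Y, sets = _dataset(rng, sigma=0.0)
        rep = bootstrap_evaluate(X, Y, sets, "cone_angles", n_boot=4,
                                 seed=0, rf_estimators=20)
        assert rep.mae["t"]["mean"] < 5e-3
        assert rep.mae["t"]["ci_high"] - rep.mae["t"]["ci_low"] < 5e-3

    def test_gaussian_noise_gives_analytic_mae(self, rng):
        # MAE of a N(0, sigma) residual is sigma * sqrt(2/pi)
        sigma = 0.4
        X, Y, sets = _dataset(rng, n=500, sigma=sigma)
        rep = bootstrap_evaluate(X, Y, sets, "cone_angles", n_boot=6,
                                 seed=1, rf_estimators=20)
        expected = sigma * np.sqrt(2 / np.pi)
        assert rep.mae["t"]["mean"] == pytest.approx(expected, rel=0.25)

    def test_report_metadata(self, rng):
        X, Y, sets = _dataset(rng, n=100)
        rep = bootstrap_evaluate(X, Y, sets, "distances", n_boot=3, ci=0.95,
                                 seed=2, rf_estimators=10)
        assert rep.n_boot == 3 and rep.ci == 0.95
        assert rep.bootstrap_mode == "resplit"
        assert rep.split_sizes[0] + rep.split_sizes[1] == 100

    def test_row_resampling_mode(self, rng):
        X, Y, sets = _dataset(rng, n=100)
        rep = bootstrap_evaluate(X, Y, sets, "cone_angles", n_boot=3,
                                 seed=2, mode="rows", rf_estimators=10)
        assert rep.bootstrap_mode == "rows"
        assert rep.mae["t"]["mean"] >= 0


class TestCoefficientTable:
    def _report(self, rng, targets):
        X = pd.DataFrame(rng.normal(0, 1, (80, 5)),
                         columns=[f"f{j}" for j in range(5)])
        Y = pd.DataFrame({t: rng.normal(0, 1, 80) for t in targets})
        ids = [f"s{k}" for k in range(15)]
        sets = [frozenset(rng.choice(ids, size=2, replace=False))
                for _ in range(80)]
        return bootstrap_evaluate(X, Y, sets, "cone_angles", n_boot=2,
                                  seed=0, rf_estimators=10)

    def test_cardinality_three_targets_five_features_two_variants(self, rng):
        targets = ("total_oop", "abs_sad", "abs_ruf")
        rep1 = self._report(rng, targets)
        rep2 = self._report(rng, targets)
        rep2.variant = "distances"
        table = coefficient_table([rep1, rep2])
        assert len(table) == 3 * 5 * 2

    def test_homa_rows_excluded_by_default(self, rng):
        rep = self._report(rng, ("abs_sad", "homa_inner"))
        assert "homa_inner" not in set(coefficient_table([rep])["target"])
        with_homa = coefficient_table([rep], include_homa=True)
        assert "homa_inner" in set(with_homa["target"])
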