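"""Interpretable models on the five-feature steric representations.

LASSO (L1-regularized linear regression, regularization chosen by five-fold
cross-validation on MAE) provides signed, comparable coefficients on
standardized features; a random forest provides a nonlinear cross-check with
permutation importances.  Evaluation follows an unseen-substituent protocol:
every test structure carries at least one substituent identity absent from
the training set, so reported errors reflect generalization to new
substituents rather than interpolation.  All headline metrics are means over
bootstrap replicates (independent re-splits by default) with percentile
confidence intervals.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec", "ModelReport", "InfeasibleSplitError",
    "split_unseen_substituent", "fit_lasso_cv", "fit_rf",
    "bootstrap_evaluate", "coefficient_table",
]


class InfeasibleSplitError(RuntimeError):
    """No test set satisfying the unseen-substituent constraint exists."""


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.1
    seed: int = 0
    unseen_substituent: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test fraction must be in (0, 1)")


def verify_unseen(substituent_sets: list[frozenset[str]],
                  train_idx: np.ndarray, test_idx: np.ndarray) -> bool:
    """Exhaustive check of the protocol predicate: every test structure has
    at least one substituent identity absent from all training structures."""
    train_ids: set[str] = set()
    for i in train_idx:
        train_ids |= substituent_sets[i]
    return all(bool(substituent_sets[i] - train_ids) for i in test_idx)


def split_unseen_substituent(substituent_sets: list[frozenset[str]],
                             spec: SplitSpec,
                             max_restarts: int = 300
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Train/test partition under the unseen-substituent constraint.

    Substituent identities are moved to the test side as whole carrier
    groups (every structure containing a chosen identity goes to test), so
    chosen identities never appear in training.  A randomized greedy over
    identity groups, restarted with derived seeds, searches for a partition
    of exactly the requested size; determinism follows from the seed.
    """
    n = len(substituent_sets)
    n_test = max(1, round(spec.test_fraction * n))
    if not spec.unseen_substituent:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(n)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    carriers: dict[str, frozenset[int]] = {}
    for i, ids in enumerate(substituent_sets):
        for s in ids:
            carriers.setdefault(s, set())  # type: ignore[arg-type]
    carriers = {s: frozenset(i for i, ids in enumerate(substituent_sets)
                             if s in ids) for s in carriers}
    usable = {s: c for s, c in carriers.items() if len(c) <= n_test}
    if not usable:
        raise InfeasibleSplitError(
            "every substituent identity occurs in more structures than the "
            "test set can hold")
    rng = np.random.default_rng(spec.seed)
    best: set[int] = set()
    for _ in range(max_restarts):
        order = list(usable)
        rng.shuffle(order)
        test: set[int] = set()
        for s in order:
            grp = usable[s]
            if len(test | grp) <= n_test:
                test |= grp
            if len(test) == n_test:
                break
        if len(test) > len(best):
            best = test
        if len(best) == n_test:
            break
    if not best:
        raise InfeasibleSplitError(
            "could not assemble any test set from whole substituent-identity "
            "groups")
    if len(best) < n_test:
        logger.warning("unseen-substituent constraint limits the test set to "
                       "%d structures (requested %d)", len(best), n_test)
    test_idx = np.array(sorted(best))
    train_idx = np.array(sorted(set(range(n)) - best))
    if not verify_unseen(substituent_sets, train_idx, test_idx):
        raise InfeasibleSplitError("constructed split violates the "
                                   "unseen-substituent predicate")
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    """LASSO fit on standardized features (coefficients on that scale)."""

    coef: np.ndarray
    intercept: float
    alpha: float
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_std: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return Z @ self.coef + self.intercept


def fit_lasso_cv(X: np.ndarray, y: np.ndarray,
                 feature_names: tuple[str, ...] | None = None,
                 folds: int = 5, seed: int = 0,
                 n_alphas: int = 50) -> LassoModel:
    """LASSO with the regularization strength chosen by k-fold CV on MAE.

    Features are z-scored on training statistics; constant columns are
    dropped (zero coefficient) with a warning.  The alpha grid is
    logarithmic with its upper bound at the smallest alpha that zeroes all
    coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ValueError("need at least as many rows as folds")
    names = feature_names or tuple(f"x{j}" for j in range(p))
    mean, std = X.mean(axis=0), X.std(axis=0)
    const = std < 1e-12
    if np.any(const):
        logger.warning("dropping constant feature column(s): %s",
                       [names[j] for j in np.where(const)[0]])
    std_safe = np.where(const, 1.0, std)
    Z = (X - mean) / std_safe
    Z[:, const] = 0.0
    alpha_max = float(np.max(np.abs(Z.T @ (y - y.mean())))) / n
    alpha_max = max(alpha_max, 1e-8)
    alphas = np.geomspace(alpha_max, alpha_max * 1e-4, n_alphas)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = list(kf.split(Z))
    cv_mae = np.zeros(n_alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, alpha in enumerate(alphas):
            errs = []
            for tr, te in fold_idx:
                model = Lasso(alpha=alpha, max_iter=50000)
                model.fit(Z[tr], y[tr])
                errs.append(np.mean(np.abs(y[te] - model.predict(Z[te]))))
            cv_mae[a] = np.mean(errs)
        best = alphas[int(np.argmin(cv_mae))]
        final = Lasso(alpha=best, max_iter=100000)
        final.fit(Z, y)
    return LassoModel(coef=final.coef_.copy(), intercept=float(final.intercept_),
                      alpha=float(best), feature_names=tuple(names),
                      x_mean=mean, x_std=std_safe)


@dataclass
class RFModel:
    model: RandomForestRegressor
    importances: np.ndarray
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def fit_rf(X: np.ndarray, y: np.ndarray,
           feature_names: tuple[str, ...] | None = None,
           seed: int = 0, n_estimators: int = 200) -> RFModel:
    """Random forest with permutation importances (deterministic per seed)."""
    X = np.asarray(X, dtype=float)
    names = feature_names or tuple(f"x{j}" for j in range(X.shape[1]))
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=10, random_state=seed)
    return RFModel(model=rf, importances=imp.importances_mean,
                   feature_names=tuple(names))


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Bootstrap summary: per-target MAE and per-feature coefficients."""

    variant: str
    n_boot: int
    ci: float
    mae: dict[str, dict[str, float]]            # target -> mean/lo/hi
    lasso_coef: dict[str, dict[str, dict[str, float]]]  # target -> feat -> stats
    rf_importance: dict[str, dict[str, float]]  # target -> feat -> mean
    alphas: dict[str, list[float]] = field(default_factory=dict)
    split_sizes: tuple[int, int] = (0, 0)
    bootstrap_mode: str = "resplit"


def _ci_bounds(vals: np.ndarray, ci: float) -> tuple[float, float]:
    lo = float(np.percentile(vals, 100 * (1 - ci) / 2))
    hi = float(np.percentile(vals, 100 * (1 + ci) / 2))
    return lo, hi


def bootstrap_evaluate(X: pd.DataFrame, Y: pd.DataFrame,
                       substituent_sets: list[frozenset[str]],
                       variant: str, targets: tuple[str, ...] | None = None,
                       n_boot: int = 10, ci: float = 0.95, seed: int = 0,
                       test_fraction: float = 0.1,
                       mode: str = "resplit",
                       rf_estimators: int = 200) -> ModelReport:
    """Repeat split -> fit -> test-MAE over bootstrap replicates.

    ``mode='resplit'`` (default) redraws the unseen-substituent split with a
    derived seed per replicate; ``mode='rows'`` keeps one split and
    resamples training rows with replacement.
    """
    targets = tuple(targets or Y.columns)
    feature_names = tuple(X.columns)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_boot)
    mae_runs: dict[str, list[float]] = {t: [] for t in targets}
    coef_runs: dict[str, list[np.ndarray]] = {t: [] for t in targets}
    imp_runs: dict[str, list[np.ndarray]] = {t: [] for t in targets}
    alphas: dict[str, list[float]] = {t: [] for t in targets}
    base_split = None
    if mode == "rows":
        base_split = split_unseen_substituent(
            substituent_sets, SplitSpec(test_fraction, int(rep_seeds[0])))
    sizes = (0, 0)
    for b in range(n_boot):
        s = int(rep_seeds[b])
        if mode == "resplit":
            tr, te = split_unseen_substituent(
                substituent_sets, SplitSpec(test_fraction, s))
        else:
            tr0, te = base_split
            tr = np.random.default_rng(s).choice(tr0, size=len(tr0),
                                                 replace=True)
        sizes = (len(tr), len(te))
        for t in targets:
            y = Y[t].to_numpy(dtype=float)
            lasso = fit_lasso_cv(Xv[tr], y[tr], feature_names, seed=s)
            rf = fit_rf(Xv[tr], y[tr], feature_names, seed=s,
                        n_estimators=rf_estimators)
            mae_runs[t].append(float(np.mean(np.abs(
                y[te] - lasso.predict(Xv[te])))))
            coef_runs[t].append(lasso.coef)
            imp_runs[t].append(rf.importances)
            alphas[t].append(lasso.alpha)
    mae = {}
    lasso_coef = {}
    rf_imp = {}
    for t in targets:
        vals = np.array(mae_runs[t])
        lo, hi = _ci_bounds(vals, ci)
        mae[t] = {"mean": float(vals.mean()), "ci_low": lo, "ci_high": hi}
        C = np.array(coef_runs[t])
        lasso_coef[t] = {}
        for j, f in enumerate(feature_names):
            lo, hi = _ci_bounds(C[:, j], ci)
            lasso_coef[t][f] = {"mean": float(C[:, j].mean()),
                                "ci_low": lo, "ci_high": hi,
                                "sign_agreement": float(np.mean(
                                    np.sign(C[:, j]) ==
                                    np.sign(np.median(C[:, j]))))}
        I = np.array(imp_runs[t])
        rf_imp[t] = {f: float(I[:, j].mean())
                     for j, f in enumerate(feature_names)}
    return ModelReport(variant=variant, n_boot=n_boot, ci=ci, mae=mae,
                       lasso_coef=lasso_coef, rf_importance=rf_imp,
                       alphas=alphas, split_sizes=sizes, bootstrap_mode=mode)


def coefficient_table(reports: list[ModelReport],
                      include_homa: bool = False) -> pd.DataFrame:
    """Long-format coefficient table for heatmap-style interpretation.

    HOMA targets are excluded by default: their predictive error is too
    high for the coefficients to carry interpretable weight.
    """
    rows = []
    for rep in reports:
        for target, feats in rep.lasso_coef.items():
            if not include_homa and target.startswith("homa"):
                continue
            for feat, stats in feats.items():
                rows.append({
                    "target": target, "feature": feat,
                    "representation": rep.variant,
                    "coefficient": stats["mean"],
                    "ci_low": stats["ci_low"], "ci_high": stats["ci_high"],
                })
    return pd.DataFrame(rows, columns=["target", "feature", "representation",
                                       "coefficient", "ci_low", "ci_high"])
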