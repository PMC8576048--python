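"""Ridge outcome prediction under nested leave-one-out cross-validation.

The prediction target is the fractional motor improvement
``(UPDRS_pre - UPDRS_post) / UPDRS_pre``. For each network's edge features
the model is ridge regression minimizing

    J(theta) = MSE(y, X theta + b) + alpha * 1/2 * sum_i theta_i^2

with an unpenalized intercept ``b``. The minimizer is computed in closed
form (normal equations on centered, optionally standardized features), so
results are independent of any iterative solver's ``max_iter``; the grid
value is still tracked for protocol fidelity.

Validation is a nested loop: the outer loop leaves one subject out; within
each outer training set, feature screening (forest OOB importance) and an
inner 5-fold grid search over ``(alpha, max_iter)`` run on the N-1 training
subjects only, and the held-out subject receives exactly one prediction that
never touches their outcome or connectivity. Performance is the Pearson
correlation (two-sided t-transform p) between the N held-out predictions and
the true rates; R^2 is reported as that correlation squared (out-of-sample),
with the mean training-fold coefficient of determination kept as a secondary
diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .atlas import Edge, Network
from .connectome import FeatureMatrix
from .selection import ForestConfig, fit_forest, oob_importance, select_features
from .simulate import SubjectRecord

__all__ = [
    "RidgeConfig",
    "RidgeModel",
    "PredictionResult",
    "improvement_rate",
    "fit_ridge",
    "ridge_predict",
    "inner_grid_search",
    "nested_loocv",
    "evaluate",
    "pearson_p_from_r",
]

logger = logging.getLogger(__name__)


def _default_alpha_grid() -> tuple[float, ...]:
    return tuple(float(a) for a in np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class RidgeConfig:
    alpha_grid: tuple[float, ...] = None  # type: ignore[assignment]
    max_iter_grid: tuple[int, ...] = (1000, 5000, 10000)
    inner_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_grid is None:
            object.__setattr__(self, "alpha_grid", _default_alpha_grid())
        if not self.alpha_grid or not self.max_iter_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(a <= 0 for a in self.alpha_grid):
            raise ValueError("ridge penalties must be positive")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class RidgeModel:
    coef: np.ndarray
    intercept: float
    alpha: float
    max_iter: int | None
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    train_r2: float


@dataclass
class PredictionResult:
    network: Network | None
    subject_ids: tuple[str, ...]
    true_rate: np.ndarray
    predicted_rate: np.ndarray
    fold_alpha: np.ndarray
    fold_max_iter: np.ndarray
    n_selected: np.ndarray
    pearson_r: float
    pearson_p: float
    r_squared: float
    train_r_squared: float  # secondary, in-sample diagnostic (mean over folds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": list(self.subject_ids),
            "true_rate": self.true_rate,
            "predicted_rate": self.predicted_rate,
            "fold_alpha": self.fold_alpha,
            "fold_max_iter": self.fold_max_iter,
            "n_selected_features": self.n_selected,
        })

    def summary(self) -> dict:
        return {
            "network": self.network,
            "n_subjects": len(self.subject_ids),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "r_squared": self.r_squared,
            "train_r_squared": self.train_r_squared,
        }


def improvement_rate(pre: float, post: float) -> float:
    """Fractional motor improvement (pre - post) / pre."""
    if pre <= 0:
        raise ValueError(f"pre-surgery score must be > 0, got {pre}")
    if post < 0:
        raise ValueError(f"post-surgery score must be >= 0, got {post}")
    return (pre - post) / pre


def fit_ridge(
    X,
    y,
    alpha: float,
    max_iter: int | None = None,
    standardize: bool = True,
) -> RidgeModel:
    """Closed-form minimizer of MSE + alpha/2 * ||theta||^2, intercept free.

    On centered features the normal equations read
    ``(Xc' Xc + N alpha / 2 * I) theta = Xc' yc`` (the N/2 factor converts the
    mean-squared-error loss to the sum-of-squares form). With
    ``standardize=True`` the penalty applies to coefficients of unit-variance
    features, computed from the training data only. An empty feature set
    degrades to an intercept-only model predicting the training mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 training subjects")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    d = X.shape[1]
    y_mean = float(np.mean(y))
    if d == 0:
        warnings.warn("empty feature set: falling back to intercept-only ridge")
        logger.warning("fit_ridge: empty feature set, intercept-only fallback")
        return RidgeModel(
            coef=np.empty(0), intercept=y_mean, alpha=alpha, max_iter=max_iter,
            feature_mean=np.empty(0), feature_scale=np.empty(0), train_r2=0.0,
        )
    if X.shape[0] != n:
        raise ValueError("X and y lengths differ")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(d)
    Xs = (X - mean) / scale
    yc = y - y_mean
    if alpha == 0:
        # OLS limit: centering can make X'X singular, use least squares
        theta = np.linalg.lstsq(Xs, yc, rcond=None)[0]
    else:
        A = Xs.T @ Xs + (n * alpha / 2.0) * np.eye(d)
        theta = np.linalg.solve(A, Xs.T @ yc)
    pred = Xs @ theta + y_mean
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    train_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RidgeModel(
        coef=theta, intercept=y_mean, alpha=alpha, max_iter=max_iter,
        feature_mean=mean, feature_scale=scale, train_r2=train_r2,
    )


def ridge_predict(model: RidgeModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.coef.size == 0:
        return np.full(X.shape[0], model.intercept)
    Xs = (X - model.feature_mean) / model.feature_scale
    return Xs @ model.coef + model.intercept


def inner_grid_search(
    X, y, config: RidgeConfig
) -> tuple[float, int]:
    """Pick (alpha, max_iter) minimizing seeded 5-fold CV mean squared error.

    Ties break toward larger alpha (stronger regularization), then smaller
    max_iter. The closed-form solver makes CV error independent of max_iter,
    so the tie rule always resolves that axis to the smallest grid value.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    folds = config.inner_folds
    if n < folds:
        warnings.warn(f"only {n} subjects: reducing inner folds from {folds} to {n}")
        folds = n
    kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed % (2**31))
    splits = list(kf.split(np.arange(n)))
    mse_by_alpha: dict[float, float] = {}
    for alpha in config.alpha_grid:
        errs = []
        for tr, te in splits:
            model = fit_ridge(X[tr], y[tr], alpha, standardize=config.standardize)
            errs.append(np.mean((ridge_predict(model, X[te]) - y[te]) ** 2))
        mse_by_alpha[alpha] = float(np.mean(errs))
    best: tuple[float, int] | None = None
    best_mse = np.inf
    for alpha in config.alpha_grid:
        for max_iter in config.max_iter_grid:
            mse = mse_by_alpha[alpha]
            if (
                mse < best_mse
                or (mse == best_mse and best is not None and (
                    alpha > best[0] or (alpha == best[0] and max_iter < best[1])
                ))
            ):
                best_mse = mse
                best = (alpha, max_iter)
    assert best is not None
    return best


def _derived_seed(base: int, *salt: int) -> int:
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0] % (2**31))


def nested_loocv(
    features: FeatureMatrix,
    subjects: Sequence[SubjectRecord],
    forest_config: ForestConfig,
    ridge_config: RidgeConfig,
    selection_scope: Literal["per_fold", "global"] = "per_fold",
    preselected: Sequence[Edge] | None = None,
) -> PredictionResult:
    """Outer leave-one-subject-out loop around screening + ridge.

    ``selection_scope="per_fold"`` reruns the forest screening inside every
    outer training set (no information from the held-out subject is used at
    any stage). ``"global"`` screens once on the full cohort before the outer
    loop — the deliberately leaky variant used for inter-group analyses.
    ``preselected`` skips screening entirely and fixes the edge set.
    """
    ids = list(features.subjects)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in feature matrix")
    by_id = {s.subject_id: s for s in subjects}
    if len(by_id) != len(subjects):
        raise ValueError("duplicate subject_id in subject records")
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ValueError(f"subjects missing from records: {missing}")
    n = len(ids)
    if n < 10:
        raise ValueError(f"nested LOOCV needs at least 10 subjects, got {n}")
    X = features.values
    y = np.array([by_id[i].improvement_rate for i in ids], dtype=float)
    edge_index = features.edge_index
    edge_pos = {e: k for k, e in enumerate(edge_index)}

    fixed_cols: list[int] | None = None
    if preselected is not None:
        fixed_cols = [edge_pos[e] for e in preselected]
    elif selection_scope == "global":
        model = fit_forest(X, y, forest_config)
        table = oob_importance(model, X, y, edges=edge_index, network=features.network)
        fixed_cols = select_features(table)
    elif selection_scope != "per_fold":
        raise ValueError(f"unknown selection_scope {selection_scope!r}")

    preds = np.empty(n)
    fold_alpha = np.empty(n)
    fold_iter = np.empty(n, dtype=int)
    n_selected = np.empty(n, dtype=int)
    train_r2s = np.empty(n)
    for i in range(n):
        tr = np.r_[0:i, i + 1:n]
        Xtr, ytr = X[tr], y[tr]
        if fixed_cols is not None:
            cols = fixed_cols
        else:
            fc = replace(forest_config, seed=_derived_seed(forest_config.seed, 11, i))
            model = fit_forest(Xtr, ytr, fc)
            table = oob_importance(model, Xtr, ytr, edges=edge_index,
                                   network=features.network)
            cols = select_features(table)
        n_selected[i] = len(cols)
        if not cols:
            logger.warning("fold %d: empty selection, intercept-only fallback", i)
            rm = fit_ridge(np.empty((n - 1, 0)), ytr, alpha=ridge_config.alpha_grid[0],
                           standardize=ridge_config.standardize)
            fold_alpha[i] = np.nan
            fold_iter[i] = -1
        else:
            rc = replace(ridge_config, seed=_derived_seed(ridge_config.seed, 13, i))
            alpha, max_iter = inner_grid_search(Xtr[:, cols], ytr, rc)
            rm = fit_ridge(Xtr[:, cols], ytr, alpha, max_iter=max_iter,
                           standardize=ridge_config.standardize)
            fold_alpha[i] = alpha
            fold_iter[i] = max_iter
        train_r2s[i] = rm.train_r2
        preds[i] = float(ridge_predict(rm, X[i:i + 1, cols] if cols else
                                       np.empty((1, 0)))[0])
    r, p, r2 = evaluate(preds, y)
    return PredictionResult(
        network=features.network,
        subject_ids=tuple(ids),
        true_rate=y,
        predicted_rate=preds,
        fold_alpha=fold_alpha,
        fold_max_iter=fold_iter,
        n_selected=n_selected,
        pearson_r=r,
        pearson_p=p,
        r_squared=r2,
        train_r_squared=float(np.mean(train_r2s)),
    )


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t-transform with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def evaluate(pred, true) -> tuple[float, float, float]:
    """Pearson r (two-sided t-transform p) and its square for pred vs truth."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size != true.size or pred.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(pred, true).statistic)
    p = pearson_p_from_r(r, pred.size)
    return r, p, r * r
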