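"""Laplacian-kernel ridge regression surrogate for adsorption enthalpies.

The model regresses CO2 adsorption enthalpy (kcal/mol) on flattened
persistence-image descriptors of the HOST structure (no guest) using the
Laplacian kernel K(x, y) = exp(-gamma * ||x - y||_1).  Dual coefficients
solve (K + alpha I) c = y.  Hyperparameters are chosen by k-fold
cross-validated grid search with the one-standard-error rule: among settings
whose mean test R^2 is within one standard error of the best, prefer the
most regularized (largest alpha, then smallest gamma).

Descriptors enter the kernel unscaled: persistence images share a common
intensity scale by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve as _sym_solve
from sklearn.metrics.pairwise import laplacian_kernel as _sk_laplacian
from sklearn.metrics.pairwise import manhattan_distances

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "SurrogateModel",
    "RegressionMetrics",
    "FoldMetrics",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_GAMMA_GRID",
    "laplacian_kernel",
    "fit",
    "metrics",
    "cross_validate",
    "grid_search_one_se",
    "save_model",
    "load_model",
]

#: Default hyperparameter grids: log-spaced, bracketing the regularization
#: and bandwidth region a ~6000-pixel PI descriptor typically selects.
DEFAULT_ALPHA_GRID = np.logspace(-3, 1, 25)
DEFAULT_GAMMA_GRID = np.logspace(-4, 0, 25)


@dataclass(frozen=True)
class Hyperparams:
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be strictly positive")


def laplacian_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """K_ij = exp(-gamma * ||x_i - y_j||_1); values in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("descriptor lengths differ")
    return _sk_laplacian(X, Y, gamma=gamma)


@dataclass
class SurrogateModel:
    """Trained KRR surrogate: training set, dual coefficients, settings."""

    X_train: np.ndarray
    y_train: np.ndarray
    dual_coef: np.ndarray
    hyperparams: Hyperparams
    config_hash: str

    def __post_init__(self) -> None:
        if len(self.dual_coef) != len(self.X_train):
            raise ValueError("one dual coefficient per training row required")
        if not self.config_hash:
            raise ValueError("config hash must be nonempty")

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = laplacian_kernel(np.atleast_2d(X), self.X_train, self.hyperparams.gamma)
        return K @ self.dual_coef


def _solve_dual(K: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    A = K + alpha * np.eye(len(K))
    try:
        return _sym_solve(A, y, assume_a="pos")
    except np.linalg.LinAlgError:
        logger.warning("kernel system not positive definite; adding 1e-10 jitter")
        return _sym_solve(A + 1e-10 * np.eye(len(K)), y, assume_a="sym")


def fit(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Hyperparams,
    config_hash: str = "unversioned",
) -> SurrogateModel:
    """Solve (K + alpha I) c = y and return the fitted surrogate."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y row counts differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    K = laplacian_kernel(X, X, hyperparams.gamma)
    coef = _solve_dual(K, y, hyperparams.alpha)
    return SurrogateModel(X, y, coef, hyperparams, config_hash)


@dataclass(frozen=True)
class RegressionMetrics:
    r2: float
    rmse: float
    mae: float
    r2_defined: bool = True


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """R^2 = 1 - SSres/SStot, RMSE, MAE.

    A zero-variance truth vector leaves R^2 undefined; the result is flagged
    (``r2_defined=False``, R^2 reported as NaN) rather than silently NaN-ing
    downstream averages.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        return RegressionMetrics(float("nan"), rmse, mae, r2_defined=False)
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return RegressionMetrics(r2, rmse, mae)


@dataclass
class FoldMetrics:
    """Per-fold and aggregated train/test metrics of a k-fold CV run."""

    train: list[RegressionMetrics]
    test: list[RegressionMetrics]

    @property
    def k(self) -> int:
        return len(self.test)

    def _agg(self, vals: Sequence[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=0))

    @property
    def mean_train_r2(self) -> float:
        return self._agg([m.r2 for m in self.train])[0]

    @property
    def mean_test_r2(self) -> float:
        return self._agg([m.r2 for m in self.test])[0]

    @property
    def sd_test_r2(self) -> float:
        return self._agg([m.r2 for m in self.test])[1]

    @property
    def mean_test_rmse(self) -> float:
        return self._agg([m.rmse for m in self.test])[0]

    @property
    def sd_test_rmse(self) -> float:
        return self._agg([m.rmse for m in self.test])[1]

    @property
    def mean_test_mae(self) -> float:
        return self._agg([m.mae for m in self.test])[0]

    @property
    def sd_test_mae(self) -> float:
        return self._agg([m.mae for m in self.test])[1]


def _folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then k near-equal contiguous slices."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def _cv_from_kernel(
    K: np.ndarray, y: np.ndarray, folds: Sequence[np.ndarray], alpha: float
) -> FoldMetrics:
    train_m: list[RegressionMetrics] = []
    test_m: list[RegressionMetrics] = []
    n = len(y)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        K_tt = K[np.ix_(train_idx, train_idx)]
        coef = _solve_dual(K_tt, y[train_idx], alpha)
        pred_train = K_tt @ coef
        pred_test = K[np.ix_(test_idx, train_idx)] @ coef
        train_m.append(metrics(y[train_idx], pred_train))
        test_m.append(metrics(y[test_idx], pred_test))
    return FoldMetrics(train_m, test_m)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Hyperparams,
    k: int = 3,
    seed: int = 0,
) -> FoldMetrics:
    """Shuffled k-fold CV: fit on k-1 folds, score both partitions."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) < k:
        raise ValueError("fewer rows than folds")
    K = laplacian_kernel(X, X, hyperparams.gamma)
    return _cv_from_kernel(K, y, _folds(len(y), k, seed), hyperparams.alpha)


def grid_search_one_se(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 3,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """CV grid search with the one-standard-error selection rule.

    The pairwise L1 distance matrix is computed once and re-exponentiated
    per gamma.  Returns the selected Hyperparams and the full score table
    (one row per grid point) for audit.
    """
    alpha_grid = list(alpha_grid)
    gamma_grid = list(gamma_grid)
    if not alpha_grid or not gamma_grid:
        raise ValueError("grids must be nonempty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    D = manhattan_distances(X)
    folds = _folds(len(y), k, seed)
    rows = []
    for gamma in gamma_grid:
        K = np.exp(-gamma * D)
        for alpha in alpha_grid:
            fm = _cv_from_kernel(K, y, folds, alpha)
            rows.append(
                {
                    "alpha": alpha,
                    "gamma": gamma,
                    "mean_train_r2": fm.mean_train_r2,
                    "mean_test_r2": fm.mean_test_r2,
                    "sd_test_r2": fm.sd_test_r2,
                    "mean_test_rmse": fm.mean_test_rmse,
                    "mean_test_mae": fm.mean_test_mae,
                }
            )
    table = pd.DataFrame(rows)
    best_idx = int(table["mean_test_r2"].idxmax())
    best = table.loc[best_idx]
    se = best["sd_test_r2"] / np.sqrt(k)
    eligible = table[table["mean_test_r2"] >= best["mean_test_r2"] - se]
    # most regularized within one SE: largest alpha, then smallest gamma
    chosen = eligible.sort_values(
        ["alpha", "gamma"], ascending=[False, True]
    ).iloc[0]
    return Hyperparams(float(chosen["alpha"]), float(chosen["gamma"])), table


def save_model(model: SurrogateModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "arrays.npz",
        X_train=model.X_train,
        y_train=model.y_train,
        dual_coef=model.dual_coef,
    )
    (directory / "model.json").write_text(
        json.dumps(
            {
                "alpha": model.hyperparams.alpha,
                "gamma": model.hyperparams.gamma,
                "config_hash": model.config_hash,
            },
            indent=2,
        ),
        encoding="utf-8",
    )


def load_model(directory: str | Path) -> SurrogateModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    arrays = np.load(directory / "arrays.npz")
    return SurrogateModel(
        X_train=arrays["X_train"],
        y_train=arrays["y_train"],
        dual_coef=arrays["dual_coef"],
        hyperparams=Hyperparams(meta["alpha"], meta["gamma"]),
        config_hash=meta["config_hash"],
    )
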