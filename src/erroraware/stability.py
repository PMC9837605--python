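"""Lasso regression with cross-validated penalty and bootstrap stability.

Links the questionnaire subscales to an outcome (error awareness rate or
cluster activity) with L1-penalised least squares,

    (1 / 2n) * ||y - X b||^2 + lambda * ||b||_1,

all variables standardised to z-scores beforehand. The penalty is chosen
by 10-fold cross-validation (minimum held-out squared error); robustness
of the variable selection is assessed by refitting the whole CV-lasso on
bootstrap resamples and reporting the percentage of resamples in which
each predictor's coefficient is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "standardize_z",
    "lambda_max",
    "default_lambda_grid",
    "LassoFit",
    "fit_lasso",
    "kkt_violation",
    "CVResult",
    "cv_select_lambda",
    "StabilityResult",
    "bootstrap_stability",
    "drop_missing_rows",
]

KKT_TOL = 1e-6


def standardize_z(a: np.ndarray, ddof: int = 1):
    """Z-score columns (or a vector); returns (z, mean, sd).

    The standard deviation uses the n-1 denominator. Constant columns
    are rejected by name (index) since their z-score is undefined.
    """
    a = np.asarray(a, dtype=float)
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=ddof)
    bad = np.atleast_1d(sd <= 0)
    if bad.any():
        cols = np.flatnonzero(bad)
        raise ValueError(f"constant column(s) cannot be standardized: {cols.tolist()}")
    return (a - mean) / sd, mean, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every lasso coefficient is zero:
    max_j |x_j' y| / n (for centred data)."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    return float(np.abs(Xc.T @ yc).max() / n)


def default_lambda_grid(
    lmax: float, n_points: int = 100, ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to ratio*lambda_max."""
    return np.geomspace(lmax, lmax * ratio, n_points)


@dataclass
class LassoFit:
    lam: float
    coef: np.ndarray
    intercept: float
    objective: float
    kkt_max_violation: float


def _objective(X, y, coef, intercept, lam) -> float:
    n = len(y)
    r = y - X @ coef - intercept
    return float((r @ r) / (2 * n) + lam * np.abs(coef).sum())


def kkt_violation(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, lam: float
) -> float:
    """Maximum violation of the lasso stationarity conditions.

    At the optimum, |x_j'(y - Xb - b0)| / n <= lambda for b_j = 0 and
    = lambda * sign(b_j) otherwise; returns the worst absolute deviation.
    """
    n = len(y)
    g = X.T @ (y - X @ coef - intercept) / n
    active = coef != 0
    v_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0)
    v_active = np.abs(g[active] - lam * np.sign(coef[active]))
    parts = np.concatenate([v_inactive, v_active])
    return float(parts.max()) if len(parts) else 0.0


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> LassoFit:
    """Solve the lasso at one penalty and verify the KKT conditions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite (drop missing rows first)")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        ols = LinearRegression().fit(X, y)
        coef, intercept = ols.coef_, float(ols.intercept_)
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
        model.fit(X, y)
        coef, intercept = model.coef_, float(model.intercept_)
    viol = kkt_violation(X, y, coef, intercept, lam)
    scale = max(lam, 1.0)
    if viol > KKT_TOL * max(scale, np.abs(coef).max() + 1):
        raise RuntimeError(f"lasso solution violates KKT conditions ({viol:.3g})")
    return LassoFit(
        lam=float(lam),
        coef=coef.copy(),
        intercept=intercept,
        objective=_objective(X, y, coef, intercept, lam),
        kkt_max_violation=viol,
    )


@dataclass
class CVResult:
    lambda_opt: float
    grid: np.ndarray
    cv_mse: np.ndarray
    fold_ids: np.ndarray
    fit: LassoFit


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> CVResult:
    """Choose the penalty by K-fold cross-validation.

    The fold assignment is seeded and returned. The grid defaults to 100
    log-spaced points from lambda_max down by a factor of 1e-3; the
    penalty minimising the mean held-out squared error wins, and the
    returned fit is on the full sample at that penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} observations, got {n}")
    if grid is None:
        grid = default_lambda_grid(lambda_max(X, y))
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ids = np.empty(n, dtype=int)
    sse = np.zeros(len(grid))
    for k, (tr, va) in enumerate(kf.split(X)):
        fold_ids[va] = k
        mx, my = X[tr].mean(axis=0), y[tr].mean()
        _, coefs, _ = lasso_path(X[tr] - mx, y[tr] - my, alphas=grid, tol=1e-5)
        pred = (X[va] - mx) @ coefs + my  # (n_va, n_alphas)
        sse += ((y[va][:, None] - pred) ** 2).sum(axis=0)
    cv_mse = sse / n
    lam = float(grid[np.argmin(cv_mse)])
    return CVResult(
        lambda_opt=lam,
        grid=grid,
        cv_mse=cv_mse,
        fold_ids=fold_ids,
        fit=fit_lasso(X, y, lam),
    )


@dataclass
class StabilityResult:
    predictors: list[str]
    coef: np.ndarray
    pct_nonzero: np.ndarray
    lambda_opt: float
    n_boot: int
    n_used: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "lasso_coeff": self.coef,
                "pct_nonzero": self.pct_nonzero,
            }
        )


def drop_missing_rows(
    X: pd.DataFrame | np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Complete-case filter; returns (X, y, predictor names, n_dropped)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(Xa).all(axis=1) & np.isfinite(y)
    return Xa[ok], y[ok], names, int((~ok).sum())


def bootstrap_stability(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_boot: int = 500,
    n_folds: int = 10,
    seed: int = 0,
    refit_lambda: bool = True,
) -> StabilityResult:
    """Bootstrap stability selection around the CV-lasso.

    Rows with missing values are omitted first. Variables (and the
    outcome) are standardised; the point coefficients come from the
    full-sample fit at the CV-optimal penalty. Each bootstrap resample
    (with replacement, original size) re-runs the whole CV-lasso
    (``refit_lambda=True``, the default) or refits at the frozen
    full-sample penalty; ``pct_nonzero`` is the percentage of resamples
    with a nonzero coefficient per predictor.
    """
    Xc, yc, names, n_dropped = drop_missing_rows(X, y)
    n = len(yc)
    Xz, *_ = standardize_z(Xc)
    yz, *_ = standardize_z(yc)

    full = cv_select_lambda(Xz, yz, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(seed)
    nonzero = np.zeros(Xz.shape[1])
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xz[idx], yz[idx]
        if refit_lambda:
            try:
                res = cv_select_lambda(Xb, yb, n_folds=n_folds, seed=seed + b + 1)
                coef = res.fit.coef
            except ValueError:  # degenerate resample (e.g. constant column)
                continue
        else:
            coef = fit_lasso(Xb, yb, full.lambda_opt).coef
        nonzero += coef != 0
    return StabilityResult(
        predictors=names,
        coef=full.fit.coef,
        pct_nonzero=100.0 * nonzero / n_boot,
        lambda_opt=full.lambda_opt,
        n_boot=n_boot,
        n_used=n,
        n_dropped=n_dropped,
    )
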