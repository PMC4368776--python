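"""Penalised and ordinary least-squares fitting.

The lasso objective follows the convention

    L(b0, b) = sum_i (y_i - b0 - x_i . b)^2 + lambda * sum_j |b_j|

with an unpenalised intercept and no 1/(2n) factor, so lambda values are
directly comparable across implementations of the same formula.  Features
are standardised internally (zero mean, unit population variance) before
the penalty is applied — penalising raw-scale mixed features (binary
mutation vs. continuous expression) would make one lambda meaningless
across feature classes — and coefficients are reported on the original
scale.

The solver is scikit-learn coordinate descent; its objective is ours
divided by 2n, so ``alpha = lambda / (2 n)`` maps one onto the other
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


@dataclass
class LassoFit:
    intercept: float
    coefs: np.ndarray            # over the candidate columns, original scale
    lam: float
    active: list[int]            # positions (within the candidate set) of nonzero coefs


@dataclass
class OLSFit:
    intercept: float
    coefs: np.ndarray
    standard_errors: np.ndarray  # per coefficient (intercept excluded)
    intercept_se: float
    residual_variance: float     # RSS / df
    df: int                      # n - |M| - 1
    cov_params: np.ndarray       # (k+1)x(k+1), intercept first
    exact_fit: bool = False      # RSS at rounding level: SEs are meaningless

    def predict(self, X_sub: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X_sub, dtype=float) @ self.coefs


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns by population (ddof=0) std; constant columns get scale 1."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, mean, std


def lambda_max(X_sub: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the lasso solution is all-zero.

    From the KKT conditions at beta = 0: lambda_max = 2 max_j |x_j . (y - ybar)|
    on standardised columns.
    """
    X = np.asarray(X_sub, dtype=float)
    Xs, _, _ = _standardize(X)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    return float(2.0 * np.max(np.abs(Xs.T @ yc))) if X.shape[1] else 0.0


def lasso_fit(X_sub: np.ndarray, y: np.ndarray, lam: float) -> LassoFit:
    """Minimise the penalised RSS at a fixed penalty ``lam``."""
    X = np.atleast_2d(np.asarray(X_sub, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if k == 0:
        raise ValueError("candidate set is empty")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    Xs, mean, std = _standardize(X)
    if lam == 0.0:
        beta_s, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), Xs]), y, rcond=None)
        b0_s, beta_s = beta_s[0], beta_s[1:]
    else:
        model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, tol=1e-10, max_iter=200_000)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Xs, y)
            except ConvergenceWarning as w:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"lasso failed to converge at lambda={lam} (n={n}, k={k}): {w}"
                ) from w
        b0_s, beta_s = float(model.intercept_), model.coef_
    coefs = beta_s / std
    intercept = float(b0_s - np.sum(beta_s * mean / std))
    active = [int(j) for j in np.flatnonzero(coefs)]
    return LassoFit(intercept=intercept, coefs=coefs, lam=float(lam), active=active)


def select_lambda(
    X_sub: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    decades: float = 3.0,
) -> float:
    """Pick lambda by k-fold CV over a log grid below lambda_max.

    The grid is ``n_lambdas`` log-spaced values spanning ``decades`` decades
    down from lambda_max; the winner minimises mean out-of-fold squared
    error, with ties going to the larger (sparser) lambda.  Columns are
    standardised once on the full candidate matrix (only the scaling, not
    the fit, is shared across folds).  Deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(X_sub, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"n={n} < n_folds={n_folds}")
    lmax = max(lambda_max(X, y), 1e-12)
    grid = np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambdas)
    Xs, _, _ = _standardize(X)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=grid / (2.0 * n), cv=kf, fit_intercept=True, tol=1e-8, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    # alphas are evaluated in descending order, so exact ties resolve to
    # the larger (sparser) lambda
    return float(model.alpha_ * 2.0 * n)


def cv_lasso(X_sub: np.ndarray, y: np.ndarray, seed: int = 0, n_folds: int = 10) -> LassoFit:
    """CV-select lambda, then fit at it (the inner selector of the ISIS loop)."""
    lam = select_lambda(X_sub, y, n_folds=n_folds, seed=seed)
    return lasso_fit(X_sub, y, lam)


def ols_fit(X_sub: np.ndarray, y: np.ndarray) -> OLSFit:
    """Exact least squares with intercept, SEs from sigma^2 (X'X)^-1."""
    X = np.atleast_2d(np.asarray(X_sub, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > |M| + 1 (n={n}, |M|={k})")
    D = np.column_stack([np.ones(n), X])
    # pivoted QR exposes which columns are linearly dependent
    _, R, piv = sla.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, k + 1) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < k + 1:
        dep = sorted(int(j) - 1 for j in piv[rank:] if j > 0)
        j = dep[0]
        # name the prior column it is most correlated with
        others = [c for c in range(k) if c != j]
        xc = X - X.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.linalg.norm(xc[:, j]) * np.linalg.norm(xc[:, others], axis=0)
            corr = np.abs(xc[:, others].T @ xc[:, j]) / np.where(denom > 0, denom, 1.0)
        partner = others[int(np.argmax(corr))] if others else j
        raise ValueError(
            f"design is rank deficient: column {j} is collinear with column {partner}"
        )
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = n - k - 1
    rss = float(resid @ resid)
    s2 = rss / df
    xtx_inv = sla.inv(D.T @ D)
    cov = s2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    return OLSFit(
        intercept=float(beta[0]),
        coefs=beta[1:],
        standard_errors=se[1:],
        intercept_se=float(se[0]),
        residual_variance=s2,
        df=df,
        cov_params=cov,
        exact_fit=bool(rss <= (1e-12 * max(1.0, float(np.linalg.norm(y)))) ** 2),
    )


def residuals(fit: OLSFit, X_sub: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r = y - yhat; sums to zero and is orthogonal to every fitted column."""
    return np.asarray(y, dtype=float) - fit.predict(X_sub)
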