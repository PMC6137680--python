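"""Penalized linear regression machinery shared by both association analyses.

Implements the glmnet-style contract: features standardized to population
unit variance, a log-spaced lambda path anchored at the smallest penalty
that zeroes every coefficient, elastic-net fits of

    (1/2n) * sum(y - b0 - X b)^2 + lam * (a * ||b||_1 + (1-a)/2 * ||b||_2^2)

with mixing parameter ``a`` (1 = LASSO), and cross-validated lambda
selection by minimum mean held-out squared error. Coordinate descent is
delegated to scikit-learn, whose objective is exactly the one above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

NONZERO_TOL = 1e-10  # coefficients below this (standardized scale) count as zero


class PathError(ValueError):
    """The lambda-path formula is undefined (pure ridge, alpha = 0)."""


class InsufficientDataError(ValueError):
    """Too few usable cell lines to fit a drug model."""


@dataclass
class RegressionConfig:
    """Shared knobs for the penalized fits.

    alpha is the elastic-net mixing parameter (1 = LASSO, 0.5 = the
    balanced penalty used for transporter-only models); n_lambda the path
    length; lambda_min_ratio defaults to 0.01 when n_samples < n_features
    and 1e-4 otherwise.
    """

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    n_folds: int = 5
    n_repeats: int = 100
    seed: int = 0
    standardize: bool = True
    lambda_rule: str = "min"  # "min" or "1se"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.lambda_min_ratio is not None and not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class FitResult:
    lambda_: float
    intercept: float
    coefficients: np.ndarray  # one entry per input feature, zeros included
    training_mse: float


@dataclass
class CVSelection:
    lambda_: float
    path: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to population sd 1.

    Zero-variance columns pass through as all-zero and are flagged.
    Returns (X_std, means, sds, zero_variance_mask); sds holds 1.0 for
    flagged columns so the transform stays invertible elsewhere.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (n denominator)
    zero_var = sds == 0
    safe = np.where(zero_var, 1.0, sds)
    X_std = (X - means) / safe
    return X_std, means, safe, zero_var


def apply_standardization(
    X: np.ndarray, means: np.ndarray, sds: np.ndarray, zero_var: np.ndarray
) -> np.ndarray:
    """Map new rows onto a previously learned standardization."""
    X_std = (np.asarray(X, dtype=float) - means) / sds
    X_std[:, zero_var] = 0.0
    return X_std


def default_lambda_min_ratio(n_samples: int, n_features: int) -> float:
    return 0.01 if n_samples < n_features else 1e-4


def lambda_path(
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Descending log-spaced penalty path.

    lambda_max = max_j |x_j . (y - mean(y))| / (n * alpha) is the smallest
    penalty at which every coefficient is exactly zero.
    """
    if alpha <= 0:
        raise PathError("the lambda path is undefined for alpha = 0 (pure ridge)")
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X_std.T @ resid)) / (n * alpha))
    if lam_max <= 0:
        lam_max = 1e-3  # degenerate flat response; any tiny path works
    if lambda_min_ratio is None:
        lambda_min_ratio = default_lambda_min_ratio(*X_std.shape)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)


def fit_enet(
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int = 50_000,
    tol: float = 1e-8,
) -> FitResult:
    """Minimize the elastic-net objective at one penalty value.

    lam = 0 reduces to ordinary least squares (solved directly).
    Deterministic given its inputs.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0:
        Xc = np.column_stack([np.ones(len(y)), X_std])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        intercept, coef = float(beta[0]), beta[1:]
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # l1_ratio=0 triggers an advisory warning
            model.fit(X_std, y)
        intercept, coef = float(model.intercept_), np.asarray(model.coef_, dtype=float)
    resid = y - intercept - X_std @ coef
    return FitResult(float(lam), intercept, coef, float(np.mean(resid**2)))


def fit_enet_path(
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 2_000,
) -> tuple[np.ndarray, float]:
    """Coefficients along a descending lambda path (warm-started).

    Returns (coefs with shape n_features x n_lambda, intercept). The
    design is centered internally so the intercept is exact. The default
    tolerance matches the coordinate-descent default; tighten it when
    path coefficients are compared pointwise against cold restarts.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    col_means = X_std.mean(axis=0)
    Xc = X_std - col_means
    y_mean = y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            Xc,
            y - y_mean,
            l1_ratio=alpha,
            alphas=lambdas,
            max_iter=max_iter,
            tol=tol,
            precompute=np.asfortranarray(Xc.T @ Xc),
        )
    # enet_path returns coefficients for alphas sorted descending, which is
    # the order lambda_path already produces
    intercept = float(y_mean)  # valid for prediction via (x - col_means) @ coef
    return coefs, intercept


def kfold_split(
    n: int, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition; fold sizes differ by at most one."""
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    splits = []
    for i in range(n_folds):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(n_folds) if j != i]))
        splits.append((train, test))
    return splits


def cv_select_lambda(
    X_std: np.ndarray,
    y: np.ndarray,
    cfg: RegressionConfig,
    inner_folds: int = 5,
    seed: int | None = None,
) -> CVSelection:
    """Pick lambda by inner cross-validation on a training partition.

    The path is computed on the partition itself; each inner fold refits
    the whole path and scores held-out squared error. The minimum-MSE rule
    is the default; ties and the optional 1-se rule resolve toward the
    larger (sparser) lambda.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    path = lambda_path(X_std, y, cfg.alpha, cfg.n_lambda, cfg.lambda_min_ratio)
    seed = cfg.seed if seed is None else seed
    splits = kfold_split(len(y), min(inner_folds, len(y)), seed)
    errors = np.empty((len(splits), len(path)))
    for i, (tr, te) in enumerate(splits):
        # fold scoring tolerates a looser path fit: the deep-tail models it
        # loosens are grossly overfit and never win the MSE comparison
        coefs, intercept = fit_enet_path(X_std[tr], y[tr], cfg.alpha, path, tol=1e-3, max_iter=500)
        col_means = X_std[tr].mean(axis=0)
        preds = (X_std[te] - col_means) @ coefs + intercept  # n_test x n_lambda
        errors[i] = ((preds - y[te][:, None]) ** 2).mean(axis=0)
    mean_mse = errors.mean(axis=0)
    se_mse = errors.std(axis=0, ddof=1) / np.sqrt(len(splits))
    if cfg.lambda_rule == "1se":
        best = int(np.argmin(mean_mse))
        bar = mean_mse[best] + se_mse[best]
        idx = int(np.flatnonzero(mean_mse <= bar)[0])  # first = largest lambda
    else:
        idx = int(np.argmin(mean_mse))  # first minimum = larger lambda on ties
    return CVSelection(float(path[idx]), path, mean_mse, se_mse)
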