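"""Genome-wide LASSO predictor ranking by lambda-path appearance frequency.

For each resampled training partition the full lambda path is fitted and
each feature scored by how many of the path's penalty values give it a
nonzero coefficient; features are ranked per fit (midranks on ties) and
the ranks averaged over all repeats x folds. The top predictor's direction
(sensitivity vs resistance) comes from the sign of its coefficient in a
full-data fit at the cross-validated penalty, with response oriented
higher = more resistant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .regression import (
    NONZERO_TOL,
    InsufficientDataError,
    RegressionConfig,
    cv_select_lambda,
    fit_enet,
    fit_enet_path,
    kfold_split,
    lambda_path,
    standardize,
)

logger = logging.getLogger(__name__)

MIN_CELL_LINES = 20


def path_frequency(
    X_train: np.ndarray, y_train: np.ndarray, cfg: RegressionConfig
) -> np.ndarray:
    """Per-feature count of nonzero coefficients along the lambda path.

    The path is recomputed on the training partition; counts range over
    0..n_lambda.
    """
    X_std, _, _, _ = standardize(X_train) if cfg.standardize else (
        np.asarray(X_train, float),
        None,
        None,
        None,
    )
    path = lambda_path(X_std, np.asarray(y_train, float), cfg.alpha, cfg.n_lambda, cfg.lambda_min_ratio)
    coefs, _ = fit_enet_path(X_std, np.asarray(y_train, float), cfg.alpha, path)
    return (np.abs(coefs) > NONZERO_TOL).sum(axis=1)


def rank_within_fit(freq: np.ndarray) -> np.ndarray:
    """Descending-frequency ranks with midranks on ties (best rank = 1)."""
    return rankdata(-np.asarray(freq, dtype=float), method="average")


def run_lasso_ranking(
    X: pd.DataFrame, y: pd.Series, cfg: RegressionConfig
) -> pd.DataFrame:
    """Average path-frequency ranks over n_repeats x n_folds partitions.

    Returns a per-feature table with average_rank, mean_path_frequency and
    final_rank (1 = best; ties broken by larger mean path frequency, then
    alphabetically). Zero-variance features are excluded from fitting and
    pinned to the worst ranks. Drugs with fewer than 20 usable lines are
    rejected.
    """
    y = y.dropna()
    X = X.loc[y.index]
    if len(y) < MIN_CELL_LINES:
        raise InsufficientDataError(f"only {len(y)} usable cell lines (need >= {MIN_CELL_LINES})")

    variances = X.to_numpy(dtype=float).std(axis=0)
    active = variances > 0
    excluded = list(X.columns[~active])
    if excluded:
        logger.info("excluding %d zero-variance features", len(excluded))
    Xa = X.loc[:, active]
    features = list(Xa.columns)
    n_feat = len(features)
    if n_feat == 0:
        raise InsufficientDataError("no features with nonzero variance")

    Xmat = Xa.to_numpy(dtype=float)
    yvec = y.to_numpy(dtype=float)
    rank_sum = np.zeros(n_feat)
    freq_sum = np.zeros(n_feat)
    n_fits = 0
    for r in range(cfg.n_repeats):
        for train, _ in kfold_split(len(yvec), cfg.n_folds, cfg.seed + r):
            freq = path_frequency(Xmat[train], yvec[train], cfg)
            rank_sum += rank_within_fit(freq)
            freq_sum += freq
            n_fits += 1

    table = pd.DataFrame(
        {
            "feature": features,
            "average_rank": rank_sum / n_fits,
            "mean_path_frequency": freq_sum / n_fits,
        }
    )
    table = table.sort_values(
        ["average_rank", "mean_path_frequency", "feature"], ascending=[True, False, True]
    ).reset_index(drop=True)
    table["final_rank"] = np.arange(1, len(table) + 1)

    if excluded:
        worst = pd.DataFrame(
            {
                "feature": sorted(excluded),
                "average_rank": float(n_feat + len(excluded)),
                "mean_path_frequency": 0.0,
            }
        )
        worst["final_rank"] = np.arange(len(table) + 1, len(table) + len(worst) + 1)
        table = pd.concat([table, worst], ignore_index=True)
    return table


def top_predictor(
    table: pd.DataFrame, X: pd.DataFrame, y: pd.Series, cfg: RegressionConfig
) -> tuple[str, str]:
    """The final_rank-1 feature and its association direction.

    Direction comes from the feature's coefficient sign in a full-data fit
    at the cross-validation-selected penalty: positive = resistance,
    negative = sensitivity (AUC oriented higher = more resistant); an
    exactly-zero coefficient yields "undetermined".
    """
    top = str(table.loc[table["final_rank"] == 1, "feature"].iloc[0])
    y = y.dropna()
    X = X.loc[y.index]
    X_std, _, _, _ = standardize(X.to_numpy(dtype=float))
    yvec = y.to_numpy(dtype=float)
    sel = cv_select_lambda(X_std, yvec, cfg, seed=cfg.seed)
    fit = fit_enet(X_std, yvec, cfg.alpha, sel.lambda_)
    coef = fit.coefficients[list(X.columns).index(top)]
    if coef > NONZERO_TOL:
        return top, "resistance"
    if coef < -NONZERO_TOL:
        return top, "sensitivity"
    logger.info("top predictor %s has zero coefficient at the selected lambda", top)
    return top, "undetermined"
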