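"""Transporter-only elastic-net stability selection with concordance index.

Per drug, many cross-validated elastic-net models are fitted (repeats x
folds); each run selects its penalty by inner cross-validation, predicts
the held-out lines and scores a concordance index, and contributes
coefficients normalized to the run's absolute-maximum weight. Features
are aggregated by appearance frequency and average normalized weight;
positive weights mark resistance associations, negative sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OmicsBundle
from .regression import (
    NONZERO_TOL,
    InsufficientDataError,
    RegressionConfig,
    apply_standardization,
    cv_select_lambda,
    fit_enet,
    kfold_split,
    standardize,
)

logger = logging.getLogger(__name__)

MIN_CELL_LINES = 20
FEATURE_MODES = ("expression", "genomics", "combined")


@dataclass
class ModelRun:
    """One cross-validation fit of one drug model."""

    repeat: int
    fold: int
    lambda_: float
    coefficients: np.ndarray
    normalized_weights: np.ndarray  # coefficients / max|coefficient|; all-zero stays zero
    test_ci: float  # NaN when the held-out responses are all tied


def concordance_index(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Fraction of comparable pairs ordered concordantly (0.5 = random).

    Over all pairs with distinct observed values: concordant pairs earn 1,
    predicted ties 0.5, discordant 0. Returns NaN when every observed
    value is tied (no comparable pair).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or len(predicted) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    dp = predicted[:, None] - predicted[None, :]
    do = observed[:, None] - observed[None, :]
    upper = np.triu(np.ones(len(predicted), dtype=bool), k=1)
    comparable = upper & (do != 0)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        return float("nan")
    concordant = ((dp * do) > 0) & comparable
    pred_tied = (dp == 0) & comparable
    credit = concordant.sum() + 0.5 * pred_tied.sum()
    return float(credit / n_pairs)


def feature_set(bundle: OmicsBundle, mode: str) -> pd.DataFrame:
    """Transporter-restricted feature matrix for model fitting.

    expression: transporter expression columns; genomics: amp/del/var
    columns for transporter genes; combined: both, concatenated.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    transporter_genes = {
        g for g in bundle.expression.columns if bundle.class_of(g) in ("SLC", "ABC")
    }
    parts = []
    if mode in ("expression", "combined"):
        cols = [g for g in bundle.expression.columns if g in transporter_genes]
        parts.append(bundle.expression[cols])
    if mode in ("genomics", "combined"):
        cols = [f for f in bundle.alterations.columns if f[3:] in transporter_genes]
        parts.append(bundle.alterations[cols].astype(float))
    X = pd.concat(parts, axis=1)
    if X.shape[1] == 0:
        raise ValueError("no transporter features available in the requested mode")
    return X


def run_enet_models(
    X: pd.DataFrame, y: pd.Series, cfg: RegressionConfig
) -> tuple[list[ModelRun], list[str]]:
    """Fit n_repeats x n_folds cross-validated elastic-net models for a drug.

    Each run standardizes its training partition, selects lambda by an
    independent inner 5-fold CV (seed = master + 1000*repeat + fold, so
    every run is independently reproducible), fits, and scores the
    concordance index on the held-out lines. Returns the runs and the
    feature-name order the coefficient vectors follow.
    """
    y = y.dropna()
    X = X.loc[y.index]
    if len(y) < MIN_CELL_LINES:
        raise InsufficientDataError(f"only {len(y)} usable cell lines (need >= {MIN_CELL_LINES})")
    features = list(X.columns)
    Xmat = X.to_numpy(dtype=float)
    yvec = y.to_numpy(dtype=float)
    runs: list[ModelRun] = []
    for r in range(cfg.n_repeats):
        for f, (train, test) in enumerate(kfold_split(len(yvec), cfg.n_folds, cfg.seed + r)):
            run_seed = cfg.seed + 1000 * r + f
            X_std, means, sds, zero_var = standardize(Xmat[train])
            sel = cv_select_lambda(X_std, yvec[train], cfg, seed=run_seed)
            fit = fit_enet(X_std, yvec[train], cfg.alpha, sel.lambda_)
            X_test = apply_standardization(Xmat[test], means, sds, zero_var)
            pred = X_test @ fit.coefficients + fit.intercept
            ci = concordance_index(pred, yvec[test])
            if np.isnan(ci):
                logger.warning("repeat %d fold %d: held-out responses all tied", r, f)
            max_abs = np.max(np.abs(fit.coefficients))
            weights = fit.coefficients / max_abs if max_abs > 0 else np.zeros_like(fit.coefficients)
            runs.append(ModelRun(r, f, sel.lambda_, fit.coefficients, weights, ci))
    return runs, features


def aggregate_associations(runs: list[ModelRun], features: list[str]) -> pd.DataFrame:
    """Frequency / average-weight aggregation over all runs.

    frequency = share of runs with a nonzero coefficient; mean_weight
    averages normalized weights over all runs (zeros included); direction
    is resistance for positive mean weight, sensitivity for negative.
    Never-selected features carry no rank.
    """
    coefs = np.vstack([r.coefficients for r in runs])
    weights = np.vstack([r.normalized_weights for r in runs])
    freq = (np.abs(coefs) > NONZERO_TOL).mean(axis=0)
    mean_w = weights.mean(axis=0)
    table = pd.DataFrame(
        {
            "feature": features,
            "frequency": freq,
            "mean_weight": mean_w,
            "direction": np.where(mean_w > 0, "resistance", "sensitivity"),
        }
    )
    ranked = table[table["frequency"] > 0].copy()
    ranked["abs_weight"] = ranked["mean_weight"].abs()
    ranked = ranked.sort_values(
        ["frequency", "abs_weight", "feature"], ascending=[False, False, True]
    )
    table["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index, dtype="float"
    )
    return table.sort_values(["rank", "feature"], na_position="last").reset_index(drop=True)


def summarize_runs(drug: str, runs: list[ModelRun]) -> dict:
    """Per-drug concordance summary across all runs (NaN CIs dropped)."""
    cis = np.array([r.test_ci for r in runs], dtype=float)
    cis = cis[~np.isnan(cis)]
    return {
        "drug": drug,
        "mean_ci": float(cis.mean()) if len(cis) else float("nan"),
        "median_ci": float(np.median(cis)) if len(cis) else float("nan"),
        "n_runs": len(runs),
    }


def select_drugs(
    summaries: pd.DataFrame, threshold: float = 0.65, stat: str = "mean"
) -> pd.DataFrame:
    """Drugs whose aggregate CI strictly exceeds the threshold.

    ``stat`` chooses the aggregate: "mean" (the averaging convention) or
    "median" (the distribution-plot convention); both columns are kept in
    the output so the choice stays visible.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    col = f"{stat}_ci"
    out = summaries.copy()
    out["selected"] = out[col] > threshold
    return out[out["selected"]].reset_index(drop=True)
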