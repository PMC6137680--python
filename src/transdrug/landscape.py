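"""Transporter expression landscape across a cell-line panel.

Expressed calls at an RMA cutoff, per-line and per-gene prevalence,
common/specific/intermediate prevalence classes, per-gene median vs
maximum summaries with the tissue attaining the maximum, and per-gene
tissue Z-scores of tissue-average expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.5  # RMA units; values >= cutoff count as expressed
REFERENCE_PANEL_SIZE = 1000
DEFAULT_COMMON_MIN = 900  # expressed in at least this many lines -> common
DEFAULT_SPECIFIC_MAX = 100  # expressed in fewer than this many lines -> specific


@dataclass
class LandscapeSummary:
    per_line_expressed: pd.Series
    per_gene_lines: pd.Series
    gene_class_sets: dict[str, set[str]]
    gene_stats: pd.DataFrame
    tissue_z: pd.DataFrame


def call_expressed(expression: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Boolean expressed mask; the cutoff is inclusive (value >= cutoff)."""
    return expression >= cutoff


def prevalence(bool_matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(transporters expressed per line, lines expressing each gene)."""
    per_line = bool_matrix.sum(axis=1).astype(int)
    per_gene = bool_matrix.sum(axis=0).astype(int)
    return per_line, per_gene


def classify_prevalence(
    per_gene_lines: pd.Series,
    n_lines: int,
    common_min: int = DEFAULT_COMMON_MIN,
    specific_max: int = DEFAULT_SPECIFIC_MAX,
) -> dict[str, set[str]]:
    """Partition genes into common / specific / intermediate prevalence sets.

    The reference thresholds (>= 900 and < 100 of a ~1000-line panel) are
    rescaled proportionally when the panel size differs, so the classes
    keep their meaning on smaller synthetic panels.
    """
    if specific_max > common_min:
        raise ValueError("specific_max must be <= common_min")
    if n_lines != REFERENCE_PANEL_SIZE:
        scale = n_lines / REFERENCE_PANEL_SIZE
        common_min = common_min * scale
        specific_max = specific_max * scale
    common = {g for g, n in per_gene_lines.items() if n >= common_min}
    specific = {g for g, n in per_gene_lines.items() if n < specific_max}
    intermediate = set(per_gene_lines.index) - common - specific
    return {"common": common, "specific": specific, "intermediate": intermediate}


def median_max(expression: pd.DataFrame, tissue: pd.Series) -> pd.DataFrame:
    """Per gene: median and maximum expression, and the tissue of the line
    attaining the maximum (first occurrence on ties)."""
    med = expression.median(axis=0)
    mx = expression.max(axis=0)
    argmax_line = expression.idxmax(axis=0)  # first occurrence on ties
    argmax_tissue = argmax_line.map(tissue)
    return pd.DataFrame(
        {
            "median_expression": med,
            "max_expression": mx,
            "argmax_tissue": argmax_tissue,
        }
    ).rename_axis("gene")


def tissue_zscores(expression: pd.DataFrame, tissue: pd.Series) -> pd.DataFrame:
    """Z-scores of per-tissue mean expression, per gene across tissues.

    Tissue means are unweighted by tissue size; the Z uses the population
    (n-denominator) standard deviation across tissues. A gene whose tissue
    means are all equal gets an all-zero row (with a warning).
    """
    tissues = tissue.loc[expression.index]
    means = expression.groupby(tissues).mean()  # tissue x gene
    if means.shape[0] < 2:
        raise ValueError("tissue Z-scores require at least 2 tissues")
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("%d genes have zero variance across tissue means", int(flat.sum()))
    sd_safe = sd.replace(0, np.nan)
    z = means.sub(mu, axis=1).div(sd_safe, axis=1).fillna(0.0)
    return z.T.rename_axis("gene")  # gene x tissue


def summarize(
    expression: pd.DataFrame,
    tissue: pd.Series,
    cutoff: float = DEFAULT_CUTOFF,
    common_min: int = DEFAULT_COMMON_MIN,
    specific_max: int = DEFAULT_SPECIFIC_MAX,
) -> LandscapeSummary:
    """Full landscape characterization in one pass."""
    mask = call_expressed(expression, cutoff)
    per_line, per_gene = prevalence(mask)
    classes = classify_prevalence(per_gene, len(expression), common_min, specific_max)
    stats = median_max(expression, tissue)
    z = tissue_zscores(expression, tissue)
    return LandscapeSummary(per_line, per_gene, classes, stats, z)
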