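"""Synthetic pharmacogenomic study generator with planted ground truth.

Emulates the statistical structure of a large cancer cell-line panel:
bimodal per-transporter expression prevalence (a common set expressed in
nearly all lines and a specific set expressed in few), tissue-of-origin
structure with tissue-restricted marker genes, sparse binary genomic
alterations, and drug response (AUC, higher = more resistant) generated
from a sparse linear model over transporter features with additive
Gaussian noise. Every generator is deterministic under its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DrugResponseTable, OmicsBundle, TransportNetwork

DEFAULT_TISSUES = [
    "blood",
    "skin",
    "kidney",
    "digestive_system",
    "lung",
    "breast",
    "bone",
    "nervous_system",
    "pancreas",
    "ovary",
    "urogenital_system",
    "soft_tissue",
    "thyroid",
]

# Expressed/silent mixture components on the RMA scale; means straddle the
# 3.5 expressed-call cutoff with realistic separation.
SILENT_MEAN, SILENT_SD = 2.0, 0.5
EXPRESSED_MEAN, EXPRESSED_SD = 6.5, 1.0


class ConfigurationError(ValueError):
    """A planted model references features the bundle does not carry."""


@dataclass
class SyntheticConfig:
    """Panel-level knobs for the generated study.

    Defaults mirror the real panel this emulates: ~1,000 lines, 417
    transporter genes (371 SLC + 46 ABC), 13 tissues, roughly a third of
    transporters commonly expressed (>= 90% of lines) and a third
    specifically expressed (< 10% of lines).
    """

    n_cell_lines: int = 1000
    n_transporter_genes: int = 417
    n_background_genes: int = 0
    fraction_common: float = 0.31
    fraction_specific: float = 0.34
    expression_cutoff: float = 3.5
    alteration_rate: float = 0.05
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    tissue_marker_fraction: float = 0.05
    tissue_marker_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_common <= 1.0 and 0.0 <= self.fraction_specific <= 1.0):
            raise ValueError("prevalence fractions must lie in [0, 1]")
        if self.fraction_common + self.fraction_specific > 1.0 + 1e-12:
            raise ValueError("fraction_common + fraction_specific must be <= 1")
        if self.n_cell_lines < 10:
            raise ValueError("n_cell_lines must be >= 10")
        if self.alteration_rate < 0 or self.alteration_rate > 1:
            raise ValueError("alteration_rate must lie in [0, 1]")


@dataclass
class PlantedModel:
    """Ground-truth sparse linear model generating one drug's AUC.

    Negative coefficients plant sensitivity associations (higher feature,
    lower AUC), positive ones resistance. Expression features are
    standardized before the coefficients are applied, so effect sizes are
    comparable across features.
    """

    drug: str
    true_effects: dict[str, float]
    intercept: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.true_effects.values()):
            raise ValueError("planted model needs at least one nonzero effect")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _gene_names(cfg: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    n_slc = int(round(cfg.n_transporter_genes * 371 / 417))
    genes, classes = [], {}
    for i in range(cfg.n_transporter_genes):
        name = f"SLC{i:04d}" if i < n_slc else f"ABC{i - n_slc:03d}"
        genes.append(name)
        classes[name] = "SLC" if i < n_slc else "ABC"
    for i in range(cfg.n_background_genes):
        name = f"GENE{i:05d}"
        genes.append(name)
        classes[name] = "other"
    return genes, classes


def generate_expression(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Draw the cell_line x gene RMA matrix, tissue labels and gene classes.

    Per gene a prevalence class is drawn (common / specific / intermediate
    with probabilities from the config); the gene's per-line expression
    probability is then uniform within a class-specific band, and entries
    come from the expressed or silent Gaussian component accordingly. With
    the defaults the per-gene count-of-expressing-lines histogram is
    bimodal. Tissue marker genes get an upward mean shift in their tissue.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, classes = _gene_names(cfg)
    lines = [f"CL{i:04d}" for i in range(cfg.n_cell_lines)]
    tissue = pd.Series(
        rng.choice(cfg.tissues, size=cfg.n_cell_lines), index=lines, name="tissue"
    )

    n_genes = len(genes)
    u = rng.random(n_genes)
    prev_class = np.where(
        u < cfg.fraction_common,
        "common",
        np.where(u < cfg.fraction_common + cfg.fraction_specific, "specific", "intermediate"),
    )
    pi = np.empty(n_genes)
    pi[prev_class == "common"] = rng.uniform(0.97, 1.0, (prev_class == "common").sum())
    pi[prev_class == "specific"] = rng.uniform(0.0, 0.05, (prev_class == "specific").sum())
    pi[prev_class == "intermediate"] = rng.uniform(
        0.15, 0.85, (prev_class == "intermediate").sum()
    )

    expressed = rng.random((cfg.n_cell_lines, n_genes)) < pi
    values = np.where(
        expressed,
        rng.normal(EXPRESSED_MEAN, EXPRESSED_SD, expressed.shape),
        rng.normal(SILENT_MEAN, SILENT_SD, expressed.shape),
    )

    # tissue-restricted markers: a small gene subset per tissue shifted up
    n_markers = int(cfg.tissue_marker_fraction * n_genes)
    for t in cfg.tissues:
        marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
        line_mask = (tissue == t).to_numpy()
        values[np.ix_(line_mask, marker_idx)] += cfg.tissue_marker_shift

    expr = pd.DataFrame(values, index=lines, columns=genes)
    return expr, tissue, classes


def generate_alterations(cfg: SyntheticConfig) -> pd.DataFrame:
    """Independent Bernoulli(alteration_rate) amp/del/var features."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes, _ = _gene_names(cfg)
    transporter_genes = [g for g in genes if not g.startswith("GENE")]
    lines = [f"CL{i:04d}" for i in range(cfg.n_cell_lines)]
    feats = [f"{p}{g}" for g in transporter_genes for p in ("amp", "del", "var")]
    mat = (rng.random((cfg.n_cell_lines, len(feats))) < cfg.alteration_rate).astype("int8")
    return pd.DataFrame(mat, index=lines, columns=feats)


def generate_bundle(cfg: SyntheticConfig) -> OmicsBundle:
    expr, tissue, classes = generate_expression(cfg)
    alt = generate_alterations(cfg)
    return OmicsBundle(expr, alt, tissue, classes)


def generate_drug_response(
    bundle: OmicsBundle,
    planted: list[PlantedModel],
    seed: int,
    missing_rate: float = 0.0,
) -> DrugResponseTable:
    """AUC = intercept + sum_f coef_f * x_f + N(0, noise_sd^2) per drug.

    Expression features are standardized (population sd) before the
    planted coefficients act; binary alteration features enter as 0/1.
    """
    rng = np.random.default_rng(seed)
    lines = bundle.cell_lines
    rows = {}
    for model in planted:
        y = np.full(len(lines), model.intercept, dtype=float)
        for feat, coef in model.true_effects.items():
            if feat in bundle.expression.columns:
                x = bundle.expression[feat].to_numpy(dtype=float)
                sd = x.std()
                x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            elif feat in bundle.alterations.columns:
                x = bundle.alterations[feat].to_numpy(dtype=float)
            else:
                raise ConfigurationError(f"planted feature {feat!r} not in bundle")
            y = y + coef * x
        y = y + rng.normal(0.0, model.noise_sd, size=len(lines))
        if missing_rate > 0:
            y = np.where(rng.random(len(lines)) < missing_rate, np.nan, y)
        rows[model.drug] = y
    auc = pd.DataFrame.from_dict(rows, orient="index", columns=lines)
    return DrugResponseTable(auc)


def generate_null_response(
    bundle: OmicsBundle, drugs: list[str], seed: int, noise_sd: float = 0.5
) -> DrugResponseTable:
    """Pure-noise AUC for null-calibration experiments."""
    rng = np.random.default_rng(seed)
    lines = bundle.cell_lines
    auc = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(len(drugs), len(lines))), index=drugs, columns=lines
    )
    return DrugResponseTable(auc)


# ---------------------------------------------------------------------------
# network fixture

FIXTURE_FAMILIES = ["ABCB", "ABCC", "ABCG", "SLCO", "SLC22", "SLC25", "SLC35", "SLC7"]


def generate_network_fixture(
    n_transporters: int, n_compounds: int, degree_law: float = 1.3, seed: int = 0
) -> tuple[TransportNetwork, dict]:
    """Random bipartite network plus an independently computed truth table.

    The fixture always contains a hub transporter (T000), a compound
    connected to exactly one transporter, and a compound exclusively shared
    by T000 and the second transporter (when two exist). The truth table is
    computed by plain dict/BFS bookkeeping on the generator side, so it can
    serve as an oracle for the curation statistics.
    """
    if n_transporters < 1 or n_compounds < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    transporters = [f"T{i:03d}" for i in range(n_transporters)]
    compounds = [f"drug{i:03d}" for i in range(n_compounds)]

    # zipf-like preferential weights make T000 a hub
    weights = 1.0 / np.arange(1, n_transporters + 1) ** degree_law
    weights /= weights.sum()

    edges: dict[tuple[str, str], int] = {}
    for j, comp in enumerate(compounds):
        if j == 0:
            chosen = [0]  # degree-1 compound on the hub
        elif j == 1 and n_transporters >= 2:
            chosen = [0, 1]  # exclusively shared by the two named transporters
        else:
            deg = min(1 + rng.geometric(0.55), n_transporters)
            chosen = list(rng.choice(n_transporters, size=deg, replace=False, p=weights))
        for ti in chosen:
            edges[(transporters[ti], comp)] = int(rng.integers(1, 5))

    fda = {c: bool(rng.random() < 0.5) for c in compounds}
    family = {t: FIXTURE_FAMILIES[i % len(FIXTURE_FAMILIES)] for i, t in enumerate(transporters)}
    net = TransportNetwork(set(transporters), set(compounds), edges, fda, family)

    # --- generator-side truth, plain loops only -------------------------
    t_deg: dict[str, int] = {t: 0 for t in transporters}
    c_nbrs: dict[str, set[str]] = {c: set() for c in compounds}
    for (t, c) in edges:
        t_deg[t] += 1
        c_nbrs[c].add(t)
    c_deg = {c: len(nbrs) for c, nbrs in c_nbrs.items()}
    hub = max(transporters, key=lambda t: (t_deg[t], t))
    exclusive_hub = sorted(c for c, nbrs in c_nbrs.items() if nbrs == {hub})
    t0, t1 = transporters[0], transporters[min(1, n_transporters - 1)]
    excl_shared = sorted(c for c, nbrs in c_nbrs.items() if nbrs == {t0, t1}) if t0 != t1 else []
    shared = (
        sorted(c for c, nbrs in c_nbrs.items() if t0 in nbrs and t1 in nbrs) if t0 != t1 else []
    )

    # connected components by BFS over an adjacency dict
    adj: dict[str, set[str]] = {n: set() for n in transporters + compounds}
    for (t, c) in edges:
        adj[t].add(c)
        adj[c].add(t)
    seen: set[str] = set()
    components: list[set[str]] = []
    for start in transporters + compounds:
        if start in seen:
            continue
        comp_nodes = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nbr in adj[node]:
                if nbr not in comp_nodes:
                    comp_nodes.add(nbr)
                    frontier.append(nbr)
        seen |= comp_nodes
        components.append(comp_nodes)
    components.sort(key=lambda s: (-len(s), sorted(s)))

    truth = {
        "transporter_degrees": dict(sorted(t_deg.items())),
        "compound_degrees": dict(sorted(c_deg.items())),
        "n_edges": len(edges),
        "hub": hub,
        "hub_degree": t_deg[hub],
        "exclusive_hub_substrates": exclusive_hub,
        "pair": [t0, t1],
        "exclusively_shared_pair": excl_shared,
        "shared_pair": shared,
        "n_components": len(components),
        "largest_component_nodes": sorted(components[0]),
    }
    return net, truth


def planted_study(
    cfg: SyntheticConfig,
    planted: list[PlantedModel],
    n_null_drugs: int = 0,
    missing_rate: float = 0.0,
) -> tuple[OmicsBundle, DrugResponseTable, list[PlantedModel]]:
    """Convenience: bundle + response for planted and null drugs together."""
    bundle = generate_bundle(cfg)
    resp = generate_drug_response(bundle, planted, seed=cfg.seed + 2, missing_rate=missing_rate)
    if n_null_drugs:
        nulls = generate_null_response(
            bundle, [f"null{i:02d}" for i in range(n_null_drugs)], seed=cfg.seed + 3
        )
        auc = pd.concat([resp.auc, nulls.auc])
        resp = DrugResponseTable(auc)
    return bundle, resp, planted


def export_study(cfg: SyntheticConfig, planted: list[PlantedModel], out_dir) -> dict:
    """Materialize a full synthetic study directory in the TSV dialect."""
    from pathlib import Path

    from .io import write_network, write_omics, write_response

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, resp, _ = planted_study(cfg, planted)
    paths = write_omics(bundle, out)
    paths["response"] = write_response(resp, out / "response_auc.tsv")
    net, truth = generate_network_fixture(40, 120, seed=cfg.seed)
    paths["network"] = write_network(net, out / "network_edges.tsv", "edge-tsv")
    import json

    (out / "network_truth.json").write_text(json.dumps(truth, indent=1))
    (out / "planted_truth.json").write_text(
        json.dumps([dataclasses.asdict(m) for m in planted], indent=1)
    )
    return paths
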