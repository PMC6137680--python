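"""Curation of multi-source transporter-compound edge tables and graph statistics.

Merges repository exports into a deduplicated bipartite network (support =
number of distinct sources per edge, after compound-name canonicalization
through an alias table), then computes degree tables, exclusive and shared
substrate sets, connected components, and one-sided hypergeometric family
enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import SourceEdgeTable, TransportNetwork

logger = logging.getLogger(__name__)


class CurationError(ValueError):
    """Invalid alias table (cycle or empty canonical name)."""


@dataclass
class EnrichmentResult:
    family: str
    in_component: int
    family_size: int
    p_value: float
    fdr: float
    significant: bool


def canonicalize(name: str, name_map: Mapping[str, str]) -> str:
    """Resolve a raw compound name through alias chains to its canonical form."""
    seen = {name}
    current = name
    while current in name_map and name_map[current] != current:
        current = name_map[current]
        if current in seen:
            raise CurationError(f"alias cycle involving {name!r}")
        seen.add(current)
    if not current or not current.strip():
        raise CurationError(f"empty canonical name for {name!r}")
    return current


def merge_sources(
    tables: Iterable[SourceEdgeTable],
    name_map: Mapping[str, str] | None = None,
    compound_fda: Mapping[str, bool] | None = None,
    gene_family: Mapping[str, str] | None = None,
) -> TransportNetwork:
    """Merge raw edge tables into one deduplicated network.

    One edge survives per unique (transporter, canonical compound); its
    support is the number of distinct sources contributing that pair.
    """
    name_map = dict(name_map or {})
    sources: dict[tuple[str, str], set[str]] = {}
    for table in tables:
        for row in table.rows.itertuples():
            compound = canonicalize(str(row.compound), name_map)
            key = (str(row.transporter), compound)
            sources.setdefault(key, set()).add(str(row.source))
    edges = {key: len(srcs) for key, srcs in sources.items()}
    transporters = {t for t, _ in edges}
    compounds = {c for _, c in edges}
    fda = {c: bool((compound_fda or {}).get(c, False)) for c in compounds}
    family = {t: str((gene_family or {}).get(t, "unknown")) for t in transporters}
    return TransportNetwork(transporters, compounds, edges, fda, family)


def degree_table(net: TransportNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node degrees, transporters and compounds separately.

    Sorted by descending degree, ties broken alphabetically.
    """
    t_deg: dict[str, int] = {t: 0 for t in net.transporters}
    c_deg: dict[str, int] = {c: 0 for c in net.compounds}
    for (t, c) in net.edges:
        t_deg[t] += 1
        c_deg[c] += 1

    def _frame(deg: dict[str, int], label: str) -> pd.DataFrame:
        rows = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=[label, "degree"])

    return _frame(t_deg, "transporter"), _frame(c_deg, "compound")


def exclusive_substrates(net: TransportNetwork, t: str) -> set[str]:
    """Compounds whose only neighbor is the given transporter."""
    if t not in net.transporters:
        raise KeyError(t)
    return {c for c in net.neighbors(t) if net.neighbors(c) == {t}}


def exclusively_shared(net: TransportNetwork, t1: str, t2: str) -> set[str]:
    """Compounds whose neighbor set is exactly {t1, t2}."""
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    for t in (t1, t2):
        if t not in net.transporters:
            raise KeyError(t)
    pair = {t1, t2}
    return {c for c in net.neighbors(t1) if net.neighbors(c) == pair}


def shared_substrates(net: TransportNetwork, t1: str, t2: str) -> set[str]:
    """Plain intersection of the two transporters' substrate sets."""
    for t in (t1, t2):
        if t not in net.transporters:
            raise KeyError(t)
    return net.neighbors(t1) & net.neighbors(t2)


def largest_component(net: TransportNetwork) -> TransportNetwork:
    """Node-induced subnetwork of the largest connected component.

    Ties go to the component with more edges, then to the
    lexicographically smallest node set.
    """
    if not (net.transporters or net.compounds):
        raise ValueError("empty network")
    g = net.to_graph()
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda nodes: (-len(nodes), -g.subgraph(nodes).number_of_edges(), sorted(nodes)))
    keep = comps[0]
    edges = {(t, c): s for (t, c), s in net.edges.items() if t in keep}
    return TransportNetwork(
        net.transporters & keep,
        net.compounds & keep,
        edges,
        {c: v for c, v in net.compound_fda.items() if c in keep},
        {t: v for t, v in net.gene_family.items() if t in keep},
    )


def family_enrichment(
    net_nodes: set[str],
    background: Mapping[str, str],
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric family over-representation in a node set.

    ``background`` maps every candidate transporter gene to its family; the
    tested set must be a subset of the background. For each family the
    upper-tail probability of drawing at least the observed number of
    members in |net_nodes| draws is computed, then BH-adjusted across
    families. Families absent from the background are skipped.
    """
    missing = net_nodes - set(background)
    if missing:
        raise ValueError(f"nodes outside the background: {sorted(missing)[:5]}")
    by_family: dict[str, list[str]] = {}
    for gene, fam in background.items():
        by_family.setdefault(fam, []).append(gene)
    M = len(background)
    N = len(net_nodes)
    rows = []
    for fam, members in sorted(by_family.items()):
        K = len(members)
        if K == 0:
            logger.warning("family %s has no background members; skipped", fam)
            continue
        k = sum(1 for g in members if g in net_nodes)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append((fam, k, K, min(p, 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(fam, k, K, p, float(q), bool(q <= fdr_threshold))
        for (fam, k, K, p), q in zip(rows, fdr)
    ]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "in_set": r.in_component,
                "family_size": r.family_size,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ]
    )
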