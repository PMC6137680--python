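"""Typed containers and TSV/SIF/GraphML readers and writers.

All tabular interchange is tab-separated UTF-8 text with a mandatory header
row, matching the export style of large pharmacogenomic releases. Networks
are bipartite transporter-compound graphs; they can be written as SIF (for
quick graph-viewer import), GraphML (lossless, via networkx) or a plain
edge table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SIF_INTERACTION = "transports"


class FormatError(ValueError):
    """A delimited-text input does not match the expected schema."""


class AlignmentError(ValueError):
    """Tables that must share identifiers have nothing in common."""


@dataclass
class SourceEdgeTable:
    """Raw transporter-compound pairs from one repository-style export.

    Each row is (source_name, compound_raw, transporter_raw); fields are
    uninterpreted strings until curation canonicalizes them.
    """

    rows: pd.DataFrame  # columns: source, compound, transporter

    def __post_init__(self) -> None:
        missing = {"source", "compound", "transporter"} - set(self.rows.columns)
        if missing:
            raise FormatError(f"edge table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TransportNetwork:
    """Bipartite graph of transporters and compounds.

    ``edges`` maps (transporter, compound) to its support: the number of
    distinct sources reporting the interaction. ``compound_fda`` flags
    FDA-approved drugs; ``gene_family`` assigns each transporter a family
    label such as "SLCO", "SLC22" or "ABCC".
    """

    transporters: set[str]
    compounds: set[str]
    edges: dict[tuple[str, str], int]
    compound_fda: dict[str, bool] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (t, c), support in self.edges.items():
            if t not in self.transporters or c not in self.compounds:
                raise ValueError(f"edge ({t!r}, {c!r}) references undeclared node")
            if support < 1:
                raise ValueError(f"edge ({t!r}, {c!r}) has support {support} < 1")
        for t in self.transporters:
            self.gene_family.setdefault(t, "unknown")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> set[str]:
        """Neighbor set of a transporter or compound node."""
        if node in self.transporters:
            return {c for (t, c) in self.edges if t == node}
        if node in self.compounds:
            return {t for (t, c) in self.edges if c == node}
        raise KeyError(node)

    def to_graph(self) -> nx.Graph:
        """networkx view with node ``kind`` and edge ``support`` attributes."""
        g = nx.Graph()
        for t in sorted(self.transporters):
            g.add_node(t, kind="transporter", family=self.gene_family.get(t, "unknown"))
        for c in sorted(self.compounds):
            g.add_node(c, kind="compound", fda=bool(self.compound_fda.get(c, False)))
        for (t, c), support in sorted(self.edges.items()):
            g.add_edge(t, c, support=int(support))
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "TransportNetwork":
        transporters = {n for n, d in g.nodes(data=True) if d.get("kind") == "transporter"}
        compounds = {n for n, d in g.nodes(data=True) if d.get("kind") == "compound"}
        edges: dict[tuple[str, str], int] = {}
        for u, v, d in g.edges(data=True):
            t, c = (u, v) if u in transporters else (v, u)
            edges[(t, c)] = int(d.get("support", 1))
        fda = {c: bool(g.nodes[c].get("fda", False)) for c in compounds}
        family = {t: str(g.nodes[t].get("family", "unknown")) for t in transporters}
        return cls(transporters, compounds, edges, fda, family)


@dataclass
class OmicsBundle:
    """Aligned per-cell-line molecular profiles.

    ``expression`` is cell_line x gene (continuous, RMA scale);
    ``alterations`` is cell_line x feature with features named
    amp<GENE>/del<GENE>/var<GENE> and values in {0,1}. Row indexes of the
    two matrices are identical after alignment. ``gene_class`` maps genes
    to "SLC", "ABC" or "other".
    """

    expression: pd.DataFrame
    alterations: pd.DataFrame
    tissue: pd.Series
    gene_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.alterations.index):
            raise AlignmentError("expression and alteration rows are not aligned")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        for feat in self.alterations.columns:
            if not feat.startswith(("amp", "del", "var")):
                raise ValueError(f"alteration feature {feat!r} lacks amp/del/var prefix")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.index)

    def class_of(self, gene: str) -> str:
        return self.gene_class.get(gene, "other")


@dataclass
class DrugResponseTable:
    """Drug x cell-line AUC matrix, oriented so larger = more resistant."""

    auc: pd.DataFrame  # index: drug, columns: cell_line; NaN allowed

    def __post_init__(self) -> None:
        empty = self.auc.index[self.auc.notna().sum(axis=1) == 0]
        if len(empty):
            raise ValueError(f"drugs with no measured response: {list(empty)}")

    def response_for(self, drug: str) -> pd.Series:
        """Non-missing AUC values for one drug, indexed by cell line."""
        return self.auc.loc[drug].dropna()


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=None)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no columns")
    return df


def read_edge_tables(paths: Iterable[str | Path]) -> list[SourceEdgeTable]:
    """Load one raw edge table per file, preserving input and row order."""
    tables = []
    for path in paths:
        df = _read_tsv(path)
        for col in ("source", "compound", "transporter"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        if len(df) == 0:
            raise FormatError(f"{path}: no data rows")
        tables.append(SourceEdgeTable(df[["source", "compound", "transporter"]].astype(str)))
    return tables


def read_gene_classes(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path)
    for col in ("gene", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["gene"].astype(str), df["class"].astype(str)))


def read_omics(
    expr_path: str | Path,
    alt_path: str | Path,
    annot_path: str | Path,
    gene_class: Mapping[str, str] | None = None,
) -> OmicsBundle:
    """Load and align expression, alterations and tissue annotation.

    Cell lines present in only one matrix are dropped (with a logged
    count); lines without a tissue annotation are kept as "unknown".
    """
    expr = _read_tsv(expr_path).set_index("cell_line")
    alt = _read_tsv(alt_path).set_index("cell_line")
    annot = _read_tsv(annot_path)
    common = expr.index.intersection(alt.index)
    if len(common) == 0:
        raise AlignmentError("no overlapping cell lines between expression and alterations")
    dropped = (len(expr) - len(common)) + (len(alt) - len(common))
    if dropped:
        logger.info("dropped %d cell-line rows present in only one matrix", dropped)
    common = common.sort_values()
    expr = expr.loc[common]
    alt = alt.loc[common].astype("int8")
    tissue_map = dict(zip(annot["cell_line"].astype(str), annot["tissue"].astype(str)))
    missing = [cl for cl in common if cl not in tissue_map]
    if missing:
        logger.warning("no tissue annotation for %d cell lines; using 'unknown'", len(missing))
    tissue = pd.Series({cl: tissue_map.get(cl, "unknown") for cl in common}, name="tissue")
    return OmicsBundle(expr, alt, tissue, dict(gene_class or {}))


def read_response(path: str | Path) -> DrugResponseTable:
    """Load a drug x cell-line AUC table (drugs as rows, 'drug' id column)."""
    df = _read_tsv(path).set_index("drug")
    return DrugResponseTable(df)


# ---------------------------------------------------------------------------
# network writers / readers

NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")


def write_network(net: TransportNetwork, path: str | Path, format: str) -> Path:
    """Serialize a network; GraphML and edge-TSV round-trip losslessly.

    SIF carries no edge attributes, so support counts are not preserved
    there (they read back as 1).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if fmt == "sif":
        lines = [f"{t}\t{SIF_INTERACTION}\t{c}" for (t, c) in sorted(net.edges)]
        connected = {n for e in net.edges for n in e}
        lines += sorted((net.transporters | net.compounds) - connected)
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        rows = [
            {
                "transporter": t,
                "compound": c,
                "support": s,
                "fda": int(net.compound_fda.get(c, False)),
                "family": net.gene_family.get(t, "unknown"),
            }
            for (t, c), s in sorted(net.edges.items())
        ]
        pd.DataFrame(rows, columns=["transporter", "compound", "support", "fda", "family"]).to_csv(
            path, sep="\t", index=False
        )
    return path


def read_network(path: str | Path, format: str) -> TransportNetwork:
    path = Path(path)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if fmt == "sif":
        transporters: set[str] = set()
        compounds: set[str] = set()
        edges: dict[tuple[str, str], int] = {}
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                # isolated node; bipartite side is unrecoverable from SIF,
                # treat as transporter (curation never emits isolated compounds)
                transporters.add(parts[0])
            elif len(parts) == 3:
                t, _, c = parts
                transporters.add(t)
                compounds.add(c)
                edges[(t, c)] = 1
            else:
                raise FormatError(f"{path}: malformed SIF line {line!r}")
        return TransportNetwork(transporters, compounds, edges)
    if fmt == "graphml":
        return TransportNetwork.from_graph(nx.read_graphml(path))
    df = _read_tsv(path)
    for col in ("transporter", "compound", "support"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    edges = {
        (str(r.transporter), str(r.compound)): int(r.support) for r in df.itertuples()
    }
    fda = {str(r.compound): bool(int(getattr(r, "fda", 0))) for r in df.itertuples()}
    family = {str(r.transporter): str(getattr(r, "family", "unknown")) for r in df.itertuples()}
    return TransportNetwork(
        {t for t, _ in edges}, {c for _, c in edges}, edges, fda, family
    )


# ---------------------------------------------------------------------------
# tabular writers (the dialect the readers consume)


def write_omics(bundle: OmicsBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "alterations": out / "alterations.tsv",
        "annotation": out / "cell_line_annotation.tsv",
        "gene_classes": out / "gene_classes.tsv",
    }
    bundle.expression.rename_axis("cell_line").to_csv(paths["expression"], sep="\t")
    bundle.alterations.rename_axis("cell_line").to_csv(paths["alterations"], sep="\t")
    bundle.tissue.rename_axis("cell_line").rename("tissue").to_frame().to_csv(
        paths["annotation"], sep="\t"
    )
    pd.DataFrame(
        sorted(bundle.gene_class.items()), columns=["gene", "class"]
    ).to_csv(paths["gene_classes"], sep="\t", index=False)
    return paths


def write_response(table: DrugResponseTable, path: str | Path) -> Path:
    path = Path(path)
    table.auc.rename_axis("drug").to_csv(path, sep="\t")
    return path
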