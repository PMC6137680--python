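"""Transporter expression landscape of the synthetic panel.

Calls genes expressed at 3.5 RMA units, summarizes per-line and per-gene
prevalence, splits transporters into common / specific / intermediate
sets (thresholds scaled to the panel size), and computes per-gene tissue
Z-scores. Tables go to results/landscape/.

Run after 01:  python analysis/03_expression_landscape.py
"""

from pathlib import Path

import pandas as pd

from transdrug.io import read_omics
from transdrug.landscape import summarize

STUDY = Path("results/synthetic_study")
OUT = Path("results/landscape")
OUT.mkdir(parents=True, exist_ok=True)

bundle = read_omics(
    STUDY / "expression.tsv", STUDY / "alterations.tsv", STUDY / "cell_line_annotation.tsv"
)
summary = summarize(bundle.expression, bundle.tissue)

summary.per_line_expressed.rename("n_expressed").rename_axis("cell_line").to_frame().to_csv(
    OUT / "per_line_expressed.tsv", sep="\t"
)
per_gene = summary.per_gene_lines.rename("n_lines").rename_axis("gene").to_frame()
labels = {g: cls for cls, genes in summary.gene_class_sets.items() for g in genes}
per_gene["prevalence_class"] = [labels[g] for g in per_gene.index]
per_gene.to_csv(OUT / "per_gene_prevalence.tsv", sep="\t")
summary.gene_stats.to_csv(OUT / "gene_stats.tsv", sep="\t")
summary.tissue_z.to_csv(OUT / "tissue_zscores.tsv", sep="\t")

n_lines, n_genes = bundle.expression.shape
print(f"panel: {n_lines} lines x {n_genes} transporter genes")
print(f"median transporters expressed per line: {summary.per_line_expressed.median():.0f}")
print(f"common set (>= 90% of lines): {len(summary.gene_class_sets['common'])} genes")
print(f"specific set (< 10% of lines): {len(summary.gene_class_sets['specific'])} genes")
print(f"intermediate: {len(summary.gene_class_sets['intermediate'])} genes")
gap = summary.gene_stats["max_expression"] - summary.gene_stats["median_expression"]
print(f"smallest max-vs-median expression gap: {gap.min():.2f} RMA units "
      f"({gap.idxmin()}, a uniformly high expresser)")
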