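"""Transporter-only elastic-net stability selection on the study drugs.

Fits 10 repeats x 5-fold cross-validated elastic-net models (alpha 0.5)
per drug on transporter expression, aggregates appearance frequency and
average normalized weight into signed association tables, scores each
drug by mean held-out concordance index, and applies the CI > 0.65
selection bar. Planted drugs should clear it with their true features on
top; null drugs should sit near CI 0.5 and be rejected. Tables go to
results/enet/.

Run after 01:  python analysis/06_enet_associations.py
"""

from pathlib import Path

import pandas as pd

from transdrug.enet import (
    aggregate_associations,
    feature_set,
    run_enet_models,
    select_drugs,
    summarize_runs,
)
from transdrug.io import read_gene_classes, read_omics, read_response
from transdrug.regression import RegressionConfig

STUDY = Path("results/synthetic_study")
OUT = Path("results/enet")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260926

bundle = read_omics(
    STUDY / "expression.tsv",
    STUDY / "alterations.tsv",
    STUDY / "cell_line_annotation.tsv",
    read_gene_classes(STUDY / "gene_classes.tsv"),
)
resp = read_response(STUDY / "response_auc.tsv")
X = feature_set(bundle, "expression")
cfg = RegressionConfig(alpha=0.5, n_repeats=10, n_folds=5, seed=SEED)

summaries = []
for drug in resp.auc.index:
    y = resp.response_for(drug)
    runs, features = run_enet_models(X.loc[y.index], y, cfg)
    assoc = aggregate_associations(runs, features)
    assoc.insert(0, "drug", drug)
    assoc.to_csv(OUT / f"associations_{drug}.tsv", sep="\t", index=False)
    summary = summarize_runs(drug, runs)
    summaries.append(summary)
    top = assoc.dropna(subset=["rank"]).nsmallest(3, "rank")
    shown = ", ".join(
        f"{r.feature} ({r.direction}, f={r.frequency:.2f})" for r in top.itertuples()
    )
    print(f"{drug}: mean CI {summary['mean_ci']:.3f} | top: {shown}")

summary_df = pd.DataFrame(summaries)
summary_df.to_csv(OUT / "drug_model_summary.tsv", sep="\t", index=False)
selected = select_drugs(summary_df, threshold=0.65)
selected.to_csv(OUT / "selected_drugs.tsv", sep="\t", index=False)
print(f"drugs clearing the CI > 0.65 bar: {list(selected['drug']) or 'none'}")
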