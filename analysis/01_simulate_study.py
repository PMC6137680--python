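"""Materialize the synthetic pharmacogenomic study all later steps analyze.

Generates a 300-line x 200-transporter-gene panel with bimodal expression
prevalence, tissue structure and sparse binary alterations, plants two
drugs with known transporter effects (one pure sensitivity effect, one
sensitivity/resistance pair) plus two signal-free null drugs, and writes
everything as TSV under results/synthetic_study/ together with the
network fixture and its truth table.

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

import pandas as pd

from transdrug.experiments import pick_variable_genes
from transdrug.io import DrugResponseTable, write_response
from transdrug.synth import (
    PlantedModel,
    SyntheticConfig,
    export_study,
    generate_bundle,
    generate_drug_response,
    generate_null_response,
)

OUT = Path("results/synthetic_study")
SEED = 20260926

cfg = SyntheticConfig(n_cell_lines=300, n_transporter_genes=200, seed=SEED)
bundle = generate_bundle(cfg)
g1, g2, g3 = pick_variable_genes(bundle, 3)
planted = [
    PlantedModel("drug_sens", {g1: -2.0}, noise_sd=0.5),
    PlantedModel("drug_dual", {g2: -2.0, g3: 2.0}, noise_sd=0.5),
]
export_study(cfg, planted, OUT)

# append null drugs to the response table the export wrote
resp = generate_drug_response(bundle, planted, seed=cfg.seed + 2)
nulls = generate_null_response(bundle, ["null_a", "null_b"], seed=cfg.seed + 3)
write_response(DrugResponseTable(pd.concat([resp.auc, nulls.auc])), OUT / "response_auc.tsv")

print(f"study written to {OUT}")
print(f"  {cfg.n_cell_lines} cell lines x {cfg.n_transporter_genes} transporter genes")
print(f"  planted sensitivity effect on {g1} (drug_sens)")
print(f"  planted pair on {g2} (sensitivity) / {g3} (resistance) (drug_dual)")
print("  null drugs: null_a, null_b")
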