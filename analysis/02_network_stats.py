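"""Characterize the curated drug-transporter network fixture.

Reads the edge table written by 01_simulate_study.py, computes degree
distributions, exclusive and shared substrate counts for the two
best-connected transporters, connected components and hypergeometric
family enrichment of the largest component, and writes the tables under
results/network/.

Run after 01:  python analysis/02_network_stats.py
"""

from pathlib import Path

import pandas as pd

from transdrug.io import read_network, write_network
from transdrug.network import (
    degree_table,
    enrichment_frame,
    exclusive_substrates,
    exclusively_shared,
    family_enrichment,
    largest_component,
    shared_substrates,
)

STUDY = Path("results/synthetic_study")
OUT = Path("results/network")
OUT.mkdir(parents=True, exist_ok=True)

net = read_network(STUDY / "network_edges.tsv", "edge-tsv")
t_deg, c_deg = degree_table(net)
t_deg.to_csv(OUT / "transporter_degrees.tsv", sep="\t", index=False)
c_deg.to_csv(OUT / "compound_degrees.tsv", sep="\t", index=False)

hub, second = t_deg["transporter"].iloc[0], t_deg["transporter"].iloc[1]
excl = exclusive_substrates(net, hub)
excl_shared = exclusively_shared(net, hub, second)
shared = shared_substrates(net, hub, second)

sub = largest_component(net)
background = dict(net.gene_family)
results = family_enrichment(sub.transporters, background)
enrichment_frame(results).to_csv(OUT / "family_enrichment.tsv", sep="\t", index=False)
write_network(sub, OUT / "largest_component.graphml", "graphml")

print(f"network: {len(net.transporters)} transporters, {len(net.compounds)} compounds, "
      f"{net.n_edges} edges")
print(f"hub {hub}: degree {t_deg['degree'].iloc[0]}, "
      f"{len(excl)} exclusive substrates")
print(f"{hub} & {second}: {len(shared)} shared substrates, "
      f"{len(excl_shared)} exclusively shared")
print(f"largest component: {len(sub.transporters) + len(sub.compounds)} of "
      f"{len(net.transporters) + len(net.compounds)} nodes")
sig = [r.family for r in results if r.significant]
print(f"families enriched at FDR <= 0.05 in the largest component: {sig or 'none'}")
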