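#!/usr/bin/env python
"""Observed structural indices for every forest and network category.

Aggregates each filtered sample table into its species-level plant x OTU
matrix, extracts the seven network categories (ALL, AM, AM_EX, ECM, ECM_EX,
SAPENDO, PATHO) and computes the observed indices: network size, fungus/plant
ratio, connectance, H2' specificity, weighted NODF nestedness and the
checkerboard C-score.  Betweenness centralities of the ALL network (used for
node sizing in visualizations) are written alongside.

Outputs: results/network_indices.tsv, results/betweenness_top5.tsv.

Run after 02:  python analysis/03_network_indices.py
"""

from pathlib import Path

import pandas as pd

from mycorrnet import (
    CATEGORIES,
    aggregate_to_species,
    betweenness_scores,
    extract_partial,
    network_summary,
)
from mycorrnet import io as mio

DATA_DIR = Path("scratch/data")
FILTERED = DATA_DIR / "filtered"
RESULTS_DIR = Path("results")


def main() -> None:
    otus = mio.read_annotations(DATA_DIR / "otu_annotations.tsv", "otu")
    plants = mio.read_annotations(DATA_DIR / "plant_annotations.tsv", "plant")
    rows = []
    centrality_rows = []
    for path in sorted(FILTERED.glob("forest_*.tsv")):
        t = mio.read_sample_table(path)
        base = aggregate_to_species(t)
        for category in CATEGORIES:
            m = extract_partial(base, otus, plants, category)
            s = network_summary(m)
            rows.append(
                {
                    "forest_id": t.forest_id,
                    "category": category,
                    "n_plants": s.n_plants,
                    "n_otus": s.n_otus,
                    "fungus_plant_ratio": s.fungus_plant_ratio,
                    "connectance": s.connectance,
                    "h2prime": s.h2prime,
                    "wnodf": s.wnodf,
                    "cscore": s.cscore,
                    "undefined": ";".join(sorted(s.undefined)) or "",
                }
            )
        for c in betweenness_scores(base)[:5]:
            centrality_rows.append(
                {
                    "forest_id": t.forest_id,
                    "node_id": c.node_id,
                    "side": c.side,
                    "betweenness": c.betweenness,
                }
            )
    indices = pd.DataFrame(rows)
    indices.to_csv(RESULTS_DIR / "network_indices.tsv", sep="\t", index=False)
    pd.DataFrame(centrality_rows).to_csv(
        RESULTS_DIR / "betweenness_top5.tsv", sep="\t", index=False
    )
    by_cat = indices.groupby("category")[["connectance", "h2prime", "wnodf"]].median()
    print("median observed indices by category:")
    print(by_cat.round(3).to_string())


if __name__ == "__main__":
    main()
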