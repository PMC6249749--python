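#!/usr/bin/env python
"""Host-label-shuffle null models and relative (z-score) indices.

For every forest and network category, builds null ensembles by shuffling
host-plant labels across samples (200 randomizations for H2' and weighted
NODF, 50 for the costlier checkerboard score), converts each randomized
sample table into a species-level matrix, and standardizes the observed
indices as relative values (observed minus null mean, over null SD).
Relative values beyond +/-2 indicate structure beyond chance; negative
relative nestedness is the anti-nested signature.

Outputs the (forest x category) property table with provenance:
results/property_table/results.tsv + results.json.

Run after 02:  python analysis/04_null_models.py [SEED]
"""

import sys
from pathlib import Path

from mycorrnet import PreprocessParams, StudyParams
from mycorrnet import io as mio
from mycorrnet.study import analyze_forest
from mycorrnet.stats import build_property_table

DATA_DIR = Path("scratch/data")
FILTERED = DATA_DIR / "filtered"
RESULTS_DIR = Path("results")

N_PERM = {"h2prime": 200, "wnodf": 200, "cscore": 50}


def main(seed: int = 13) -> None:
    otus = mio.read_annotations(DATA_DIR / "otu_annotations.tsv", "otu")
    plants = mio.read_annotations(DATA_DIR / "plant_annotations.tsv", "plant")
    params = StudyParams(preprocess=PreprocessParams(seed=seed), n_perm=dict(N_PERM))
    results = {}
    for path in sorted(FILTERED.glob("forest_*.tsv")):
        t = mio.read_sample_table(path)
        for category, row in analyze_forest(t, otus, plants, params, seed).items():
            results[(t.forest_id, category)] = row
        all_row = results[(t.forest_id, "ALL")]

        def fmt(v):
            return "undefined" if v is None else f"{v:.1f}"

        print(
            f"{t.forest_id} ALL: rel H2'={fmt(all_row['rel_h2prime'])} "
            f"rel wNODF={fmt(all_row['rel_wnodf'])} "
            f"rel C-score={fmt(all_row['rel_cscore'])}"
        )
    pt = build_property_table(results)
    mio.write_results(
        pt,
        {"seed": seed, "n_perm": N_PERM, "entry_fraction_threshold": 0.001,
         "rarefaction_depth": 1000, "null_scope": "full"},
        RESULTS_DIR / "property_table",
    )
    anti = pt[(pt.category == "ALL") & (pt.rel_wnodf < 0)]
    print(
        f"\n{len(anti)}/8 forests show anti-nested (rel wNODF < 0) ALL networks"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 13)
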