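#!/usr/bin/env python
"""Cross-forest comparison: ANOVA of relative indices and correlation PCA.

For each relative index (H2' specificity, weighted NODF nestedness,
checkerboard score), fits the ANOVA model with the number of plant taxa, the
number of fungal OTUs, connectance, locality (forest) and network category as
terms — sequential sums of squares in that order, Bonferroni over the five
terms per model — and runs a correlation-matrix PCA over the seven network
properties.

Outputs: results/anova.tsv, results/pca_loadings.tsv, results/pca_scores.tsv.

Run after 04:  python analysis/05_compare_networks.py
"""

from pathlib import Path

import pandas as pd

from mycorrnet import io as mio
from mycorrnet.stats import anova_network_properties, pca_network_properties

RESULTS_DIR = Path("results")


def main() -> None:
    pt, provenance = mio.read_results(RESULTS_DIR / "property_table")
    frames = []
    for response in ("rel_h2prime", "rel_wnodf", "rel_cscore"):
        table = anova_network_properties(pt, response)
        frame = table.as_frame()
        frame.insert(0, "response", response)
        frames.append(frame)
        significant = [
            t.name for t in table.terms if t.p_bonferroni < 0.05
        ]
        print(f"{response}: Bonferroni-significant terms: {significant or 'none'}")
    anova = pd.concat(frames, ignore_index=True)
    anova.to_csv(RESULTS_DIR / "anova.tsv", sep="\t", index=False)

    pca = pca_network_properties(pt)
    loadings = pd.DataFrame(
        pca.loadings,
        index=pca.variables,
        columns=[f"PC{k + 1}" for k in range(pca.loadings.shape[1])],
    )
    loadings.to_csv(RESULTS_DIR / "pca_loadings.tsv", sep="\t", index_label="variable")
    complete = pt.dropna(subset=pca.variables)
    scores = pd.DataFrame(
        pca.scores[:, :3], columns=["PC1", "PC2", "PC3"]
    )
    scores.insert(0, "category", complete["category"].to_numpy())
    scores.insert(0, "forest_id", complete["forest_id"].to_numpy())
    scores.to_csv(RESULTS_DIR / "pca_scores.tsv", sep="\t", index=False)
    pct = pca.explained_variance[:3] * 100
    print(
        f"PCA: PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}%, PC3 {pct[2]:.1f}% "
        f"of variance ({len(complete)} networks, seed={provenance['seed']})"
    )


if __name__ == "__main__":
    main()
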