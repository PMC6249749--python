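"""Species-level matrix construction and guild-specific partial networks.

Aggregation converts the sample x OTU table into a plant x OTU association
matrix whose cells count the *samples* in which an association was observed
(presence semantics: a sample contributes 1 whether it held one read or 999).
Seven network categories are analyzed:

ALL      every OTU, every plant
AM/ECM/PATHO/SAPENDO
         columns restricted to one fungal guild, all plants
AM_EX    AM fungi and only plants compatible with arbuscular mycorrhizae
         (AM_PLANT or DUAL)
ECM_EX   ECM fungi and only ectomycorrhizal-compatible plants
         (ECM_PLANT or DUAL)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError
from .tables import (
    OTUAnnotationTable,
    PlantAnnotationTable,
    SampleTable,
    SpeciesMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class NodeCentrality:
    node_id: str
    betweenness: float
    side: str  # "plant" or "fungus"

    def __post_init__(self) -> None:
        if self.betweenness < 0:
            raise ValidationError("betweenness must be non-negative")
        if self.side not in ("plant", "fungus"):
            raise ValidationError(f"side must be plant or fungus, got {self.side!r}")


def aggregate_to_species(t: SampleTable) -> SpeciesMatrix:
    """Count, per (plant, OTU) pair, the samples exhibiting the association.

    Plants are ordered by sorted label (canonical, row-order independent);
    OTU column order follows the sample table.  All-zero rows/columns are
    pruned.
    """
    labels = sorted(set(t.plant_labels))
    label_index = {p: i for i, p in enumerate(labels)}
    codes = np.array([label_index[p] for p in t.plant_labels])
    presence = (t.counts > 0).astype(np.int64)
    assoc = np.zeros((len(labels), t.n_otus), dtype=np.int64)
    np.add.at(assoc, codes, presence)
    return SpeciesMatrix(
        plant_labels=labels,
        otu_ids=list(t.otu_ids),
        assoc=assoc,
        category="ALL",
        forest_id=t.forest_id,
    ).pruned()


_GUILD_CATEGORIES = {"AM": "AM", "ECM": "ECM", "PATHO": "PATHO", "SAPENDO": "SAPENDO"}

#: Plant mycorrhizal types retained by the plant-filtered categories.  DUAL
#: plants (documented hosts of both symbiosis types) stay in both.
_PLANT_KEEP = {
    "AM_EX": ("AM_PLANT", "DUAL"),
    "ECM_EX": ("ECM_PLANT", "DUAL"),
}


def extract_partial(
    m: SpeciesMatrix,
    otus: OTUAnnotationTable | None,
    plants: PlantAnnotationTable | None,
    category: str,
) -> SpeciesMatrix:
    """Restrict the ALL matrix to one network category and prune empty lines.

    The output is always a submatrix of the input (values unchanged); plants
    lacking an annotation are treated as non-mycorrhizal for exclusion
    purposes, OTUs lacking one as UNKNOWN.
    """
    if category == "ALL":
        return m.pruned()
    if category in _GUILD_CATEGORIES or category in _PLANT_KEEP:
        guild = category.split("_")[0]
        if otus is None:
            raise ValidationError(f"category {category} needs OTU annotations")
        col_keep = np.array([otus.guild_of(o) == guild for o in m.otu_ids])
        row_keep = np.ones(m.n_plants, dtype=bool)
        if category in _PLANT_KEEP:
            if plants is None:
                raise ValidationError(f"category {category} needs plant annotations")
            unannotated = [p for p in m.plant_labels if p not in plants._index]
            if unannotated:
                logger.warning(
                    "%d plant(s) without mycorrhizal-type annotation treated as "
                    "NM_PLANT: %s",
                    len(unannotated),
                    unannotated[:5],
                )
            keep_types = _PLANT_KEEP[category]
            row_keep = np.array(
                [plants.type_of(p) in keep_types for p in m.plant_labels]
            )
        sub = SpeciesMatrix(
            plant_labels=[p for p, k in zip(m.plant_labels, row_keep) if k],
            otu_ids=[o for o, k in zip(m.otu_ids, col_keep) if k],
            assoc=m.assoc[np.ix_(np.flatnonzero(row_keep), np.flatnonzero(col_keep))],
            category=category,
            forest_id=m.forest_id,
        )
        return sub.pruned()
    raise ValidationError(f"unknown network category {category!r}")


def to_bipartite_graph(m: SpeciesMatrix) -> nx.Graph:
    """Unweighted bipartite graph: an edge per nonzero association cell."""
    g = nx.Graph()
    plant_nodes = [("P", p) for p in m.plant_labels]
    otu_nodes = [("F", o) for o in m.otu_ids]
    g.add_nodes_from(plant_nodes, bipartite=0)
    g.add_nodes_from(otu_nodes, bipartite=1)
    rows, cols = np.nonzero(m.assoc)
    g.add_edges_from(
        (("P", m.plant_labels[i]), ("F", m.otu_ids[j])) for i, j in zip(rows, cols)
    )
    return g


def betweenness_scores(m: SpeciesMatrix) -> list[NodeCentrality]:
    """Shortest-path betweenness on the unweighted bipartite presence graph.

    Unnormalized scores, computed per connected component by the standard
    Brandes algorithm; used for node sizing in network visualizations, ranked
    within the plant side and the fungus side separately.
    """
    g = to_bipartite_graph(m)
    bc = nx.betweenness_centrality(g, normalized=False)
    out = []
    for (side, name), score in bc.items():
        out.append(
            NodeCentrality(
                node_id=name,
                betweenness=float(score),
                side="plant" if side == "P" else "fungus",
            )
        )
    out.sort(key=lambda c: (c.side, -c.betweenness, c.node_id))
    return out
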