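"""End-to-end study driver: forests -> property table of network indices.

Chains the pipeline for every forest and network category: sample-level
preprocessing, species-matrix aggregation, category extraction, structural
indices, host-label-shuffle null ensembles and relative (z-score) indices.
The result is the (forest x category) property table consumed by the ANOVA
and PCA comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._rng import child_rng
from .errors import (
    DegenerateMatrixError,
    EnsembleError,
    UndefinedIndexError,
    ValidationError,
)
from .metrics import network_summary
from .networks import aggregate_to_species, extract_partial
from .nullmodels import null_distribution, relative_index
from .preprocess import PreprocessParams, preprocess
from .tables import (
    CATEGORIES,
    OTUAnnotationTable,
    PlantAnnotationTable,
    SampleTable,
)

logger = logging.getLogger(__name__)

RELATIVE_METRICS = ("h2prime", "wnodf", "cscore")


@dataclass
class StudyParams:
    """Settings shared by all forests of one comparative study."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    categories: tuple[str, ...] = CATEGORIES
    n_perm: dict = field(
        default_factory=lambda: {"h2prime": 1000, "wnodf": 1000, "cscore": 100}
    )
    null_scope: str = "full"


def analyze_forest(
    t: SampleTable,
    otus: OTUAnnotationTable,
    plants: PlantAnnotationTable,
    params: StudyParams,
    seed: int,
) -> dict[str, dict[str, float | None]]:
    """Per-category indices and relative indices for one preprocessed forest."""
    out: dict[str, dict[str, float | None]] = {}
    base = aggregate_to_species(t)
    for category in params.categories:
        try:
            m = extract_partial(base, otus, plants, category)
        except ValidationError as exc:
            logger.warning("%s %s: %s", t.forest_id, category, exc)
            continue
        summary = network_summary(m)
        row: dict[str, float | None] = {
            "n_plants": summary.n_plants,
            "n_otus": summary.n_otus,
            "fungus_plant_ratio": summary.fungus_plant_ratio,
            "connectance": summary.connectance,
            "rel_h2prime": None,
            "rel_wnodf": None,
            "rel_cscore": None,
        }
        if not m.degenerate:
            for metric in RELATIVE_METRICS:
                observed = getattr(summary, metric)
                if observed is None:
                    continue
                metric_seed = int(
                    child_rng(seed, "study", t.forest_id, category).integers(2**31)
                )
                try:
                    ens = null_distribution(
                        t,
                        otus,
                        plants,
                        category,
                        metric,
                        n_perm=params.n_perm[metric],
                        seed=metric_seed,
                        null_scope=params.null_scope,
                    )
                    row[f"rel_{metric}"] = relative_index(observed, ens).z
                except (DegenerateMatrixError, UndefinedIndexError, EnsembleError) as exc:
                    logger.warning(
                        "%s %s %s: %s", t.forest_id, category, metric, exc
                    )
        out[category] = row
    return out


def run_study(
    tables: list[SampleTable],
    otus: OTUAnnotationTable,
    plants: PlantAnnotationTable,
    params: StudyParams,
    seed: int,
) -> pd.DataFrame:
    """Preprocess every forest and assemble the full property table."""
    from .stats import build_property_table

    results = {}
    for t in tables:
        forest_seed = int(child_rng(seed, "preprocess", t.forest_id).integers(2**31))
        prepped = preprocess(t, params.preprocess, seed=forest_seed)
        for category, row in analyze_forest(
            prepped, otus, plants, params, seed
        ).items():
            results[(t.forest_id, category)] = row
    return build_property_table(results)
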