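"""Host-label-shuffle null models and relative (z-score) network indices.

The null hypothesis is that fungal composition is independent of the host
plant: randomized datasets are obtained by permuting the plant labels across
samples within a forest (each sample's OTU count vector untouched), converting
every randomized sample-level table into a species-level matrix, and
recomputing the index.  Observed indices are then standardized as

    relative index = (I_observed - mean(I_randomized)) / SD(I_randomized),

with the sample (n-1) standard deviation.  Relative values above/below ~2 in
magnitude indicate indices higher/lower than expected by chance; negative
relative nestedness is the "anti-nested" signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .errors import (
    DegenerateMatrixError,
    EnsembleError,
    UndefinedIndexError,
    ValidationError,
)
from .metrics import METRIC_FUNCTIONS
from .networks import aggregate_to_species, extract_partial
from .tables import OTUAnnotationTable, PlantAnnotationTable, SampleTable

#: Default randomization counts: the checkerboard score is far costlier per
#: evaluation, so its ensemble is smaller.
DEFAULT_N_PERM = {"h2prime": 1000, "wnodf": 1000, "cscore": 100}


@dataclass
class NullEnsemble:
    metric_name: str
    values: np.ndarray
    n_requested: int
    n_failed: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) + self.n_failed != self.n_requested:
            raise ValidationError("ensemble bookkeeping: values + failed != requested")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite value in null ensemble")

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_requested if self.n_requested else 0.0


@dataclass
class RelativeIndex:
    observed: float
    null_mean: float
    null_sd: float
    z: float


def _canonical_order(t: SampleTable) -> np.ndarray:
    return np.argsort(np.asarray(t.sample_ids, dtype=object))


def _shuffled_labels(t: SampleTable, rng: np.random.Generator) -> list[str]:
    """Permute plant labels uniformly; canonicalized so the result depends on
    the sample-id set, not on row order."""
    order = _canonical_order(t)
    canonical = [t.plant_labels[i] for i in order]
    perm = rng.permutation(len(canonical))
    new_labels = [""] * t.n_samples
    for k, row in enumerate(order):
        new_labels[row] = canonical[perm[k]]
    return new_labels


def shuffle_host_labels(t: SampleTable, seed: int) -> SampleTable:
    """One uniform random permutation of host-plant labels across samples."""
    rng = child_rng(seed, "shuffle")
    out = SampleTable(
        forest_id=t.forest_id,
        sample_ids=list(t.sample_ids),
        plant_labels=_shuffled_labels(t, rng),
        otu_ids=list(t.otu_ids),
        counts=t.counts.copy(),
    )
    return out


def _prune_array(a: np.ndarray) -> np.ndarray:
    rows = a.sum(axis=1) > 0
    cols = a.sum(axis=0) > 0
    if rows.all() and cols.all():
        return a
    return a[rows][:, cols]


class _FastNullSampler:
    """Precomputed state for repeated shuffle -> aggregate -> extract -> metric.

    Label shuffling preserves the plant-label multiset, so the category's row
    and column selections (which depend only on labels and annotations) are
    constant across permutations and can be applied as index masks to the
    aggregated matrix.
    """

    def __init__(
        self,
        t: SampleTable,
        otus: OTUAnnotationTable | None,
        plants: PlantAnnotationTable | None,
        category: str,
    ) -> None:
        order = _canonical_order(t)
        self.labels = sorted(set(t.plant_labels))
        label_index = {p: i for i, p in enumerate(self.labels)}
        self.codes = np.array(
            [label_index[t.plant_labels[i]] for i in order], dtype=np.intp
        )
        self.presence = (t.counts[order] > 0).astype(np.float64)
        self.n_samples = t.n_samples
        self.n_labels = len(self.labels)
        # Constant category masks, mirroring extract_partial's selection rules.
        if category == "ALL":
            self.col_idx = np.arange(t.n_otus)
        else:
            guild = category.split("_")[0]
            self.col_idx = np.array(
                [j for j, o in enumerate(t.otu_ids) if otus.guild_of(o) == guild],
                dtype=np.intp,
            )
        if category in ("AM_EX", "ECM_EX"):
            keep_types = {"AM_EX": ("AM_PLANT", "DUAL"), "ECM_EX": ("ECM_PLANT", "DUAL")}[
                category
            ]
            self.row_idx = np.array(
                [
                    i
                    for i, p in enumerate(self.labels)
                    if plants.type_of(p) in keep_types
                ],
                dtype=np.intp,
            )
        else:
            self.row_idx = np.arange(self.n_labels)
        self.presence_sel = self.presence[:, self.col_idx]

    def matrix_for_codes(self, codes: np.ndarray) -> np.ndarray:
        """Aggregate presence by plant code, restrict to the category, prune."""
        indicator = np.zeros((self.n_labels, self.n_samples))
        indicator[codes, np.arange(self.n_samples)] = 1.0
        assoc = indicator @ self.presence_sel
        return _prune_array(assoc[self.row_idx])

    def observed_matrix(self) -> np.ndarray:
        return self.matrix_for_codes(self.codes)


def _single_null_value(
    sampler: _FastNullSampler, metric: str, seed: int, k: int
) -> float | None:
    """Value of permutation ``k``, or None if the randomized matrix is degenerate.

    The child RNG is derived from (seed, metric, k) alone, so any execution
    order — serial, reversed, or split over workers — yields the same value
    for the same index.
    """
    rng = child_rng(seed, "null", metric, k)
    perm = rng.permutation(sampler.n_samples)
    a = sampler.matrix_for_codes(sampler.codes[perm])
    try:
        return float(METRIC_FUNCTIONS[metric](a))
    except (DegenerateMatrixError, UndefinedIndexError):
        return None


def observed_index(
    t: SampleTable,
    otus: OTUAnnotationTable | None,
    plants: PlantAnnotationTable | None,
    category: str,
    metric: str,
) -> float:
    """The observed (un-randomized) index for one category and metric."""
    m = extract_partial(aggregate_to_species(t), otus, plants, category)
    if m.degenerate:
        raise DegenerateMatrixError(
            f"category {category} in forest {t.forest_id} is degenerate"
        )
    return float(METRIC_FUNCTIONS[metric](m))


def null_distribution(
    t: SampleTable,
    otus: OTUAnnotationTable | None,
    plants: PlantAnnotationTable | None,
    category: str,
    metric: str,
    n_perm: int | None = None,
    seed: int = 0,
    null_scope: str = "full",
) -> NullEnsemble:
    """Null ensemble of one metric under host-label shuffling.

    Each permutation index k derives its own child RNG from (seed, metric, k),
    so ensembles are reproducible, independent of sample order, and identical
    whether permutations run serially or in parallel.  Degenerate randomized
    matrices are skipped and counted in ``n_failed``; an ensemble with more
    than half of its randomizations failed is rejected.

    ``null_scope='full'`` shuffles labels on the full table and then applies
    the category's selection rules to the randomized data;
    ``'within-category'`` restricts the table to the category's plants first
    and shuffles inside it.
    """
    if metric not in METRIC_FUNCTIONS:
        raise ValidationError(f"unknown metric {metric!r}")
    if n_perm is None:
        n_perm = DEFAULT_N_PERM.get(metric, 1000)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if null_scope not in ("full", "within-category"):
        raise ValidationError(f"unknown null scope {null_scope!r}")
    work = t
    if null_scope == "within-category" and category in ("AM_EX", "ECM_EX"):
        keep_types = {"AM_EX": ("AM_PLANT", "DUAL"), "ECM_EX": ("ECM_PLANT", "DUAL")}[
            category
        ]
        idx = [
            i
            for i, p in enumerate(t.plant_labels)
            if plants is not None and plants.type_of(p) in keep_types
        ]
        if len(idx) < 2:
            raise EnsembleError(
                f"category {category}: fewer than two compatible samples"
            )
        work = t.subset_samples(np.asarray(idx))
    sampler = _FastNullSampler(work, otus, plants, category)
    values = []
    n_failed = 0
    for k in range(n_perm):
        v = _single_null_value(sampler, metric, seed, k)
        if v is None:
            n_failed += 1
        else:
            values.append(v)
    ensemble = NullEnsemble(
        metric_name=metric,
        values=np.asarray(values),
        n_requested=n_perm,
        n_failed=n_failed,
        seed=seed,
    )
    if n_failed > n_perm / 2:
        raise EnsembleError(
            f"null ensemble for {metric} ({category}): {n_failed}/{n_perm} "
            "randomizations degenerate"
        )
    return ensemble


def relative_index(observed: float, e: NullEnsemble) -> RelativeIndex:
    """Standardize an observed index against its null ensemble (z-score)."""
    if len(e.values) < 2:
        raise UndefinedIndexError("relative index needs >= 2 null values")
    null_mean = float(np.mean(e.values))
    null_sd = float(np.std(e.values, ddof=1))
    if null_sd <= 0:
        raise UndefinedIndexError("relative index undefined: null SD is zero")
    return RelativeIndex(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=(float(observed) - null_mean) / null_sd,
    )


def relative_index_for(
    t: SampleTable,
    otus: OTUAnnotationTable | None,
    plants: PlantAnnotationTable | None,
    category: str,
    metric: str,
    n_perm: int | None = None,
    seed: int = 0,
    null_scope: str = "full",
) -> RelativeIndex:
    """Observed index plus its null standardization in one call."""
    obs = observed_index(t, otus, plants, category, metric)
    ensemble = null_distribution(
        t, otus, plants, category, metric, n_perm=n_perm, seed=seed, null_scope=null_scope
    )
    return relative_index(obs, ensemble)
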