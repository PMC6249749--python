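"""Sample-level quality pipeline: rare-entry filter, rarefaction, subsampling.

The stages run in a fixed order — rare-entry filter, rarefaction to a common
depth, equal-size subsampling of samples per forest — mirroring the standard
treatment of root metabarcoding count tables before network construction.
Rarefaction is a multivariate-hypergeometric draw (subsampling reads without
replacement), and every stochastic stage derives per-sample child seeds by
hashing stable identifiers, so results do not depend on row order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .errors import ValidationError
from .tables import SampleTable

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Quality-pipeline settings.

    entry_fraction_threshold
        Cells carrying less than this fraction of their sample's pre-filter
        read total are zeroed (default 0.001, i.e. 0.1%); such rare entries
        typically stem from soil carry-over or PCR/sequencing errors.
    rarefaction_depth
        Common per-sample read depth after rarefaction (default 1000); samples
        below it are dropped.
    samples_per_forest
        Number of retained samples drawn per forest so depth is equal across
        forests (default 240).
    """

    entry_fraction_threshold: float = 0.001
    rarefaction_depth: int = 1000
    samples_per_forest: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.entry_fraction_threshold < 1):
            raise ValidationError("entry_fraction_threshold must be in [0, 1)")
        if self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")
        if self.samples_per_forest < 1:
            raise ValidationError("samples_per_forest must be >= 1")


def filter_rare_entries(t: SampleTable, p: PreprocessParams) -> SampleTable:
    """Zero every cell below the per-sample relative-abundance threshold.

    The comparison is strict (< threshold) and uses each sample's *pre-filter*
    total; cells exactly at the threshold survive.  Columns that become
    all-zero are kept — dropping them is deferred to network construction so
    that sample-level label shuffling stays well defined.
    """
    totals = t.sample_totals()
    zero_rows = totals == 0
    if zero_rows.any():
        logger.warning(
            "%d sample(s) with zero total reads left unchanged in forest %s",
            int(zero_rows.sum()),
            t.forest_id,
        )
    counts = t.counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / totals[:, None]
    mask = (frac < p.entry_fraction_threshold) & (totals[:, None] > 0)
    counts[mask] = 0
    return t.with_counts(counts)


def _rarefy_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw `depth` reads from one sample without replacement."""
    return rng.multivariate_hypergeometric(row, depth)


def rarefy(t: SampleTable, p: PreprocessParams, seed: int | None = None) -> SampleTable:
    """Rarefy every sample to ``rarefaction_depth`` reads, dropping shallower ones.

    Each retained sample's counts are a uniform random subsample of its reads
    without replacement, summing exactly to the depth.  Child RNGs are keyed by
    sample id, so the draw for a given sample is independent of table order.
    """
    if seed is None:
        seed = p.seed
    totals = t.sample_totals()
    keep = totals >= p.rarefaction_depth
    if not keep.any():
        raise ValidationError(
            f"forest {t.forest_id}: no sample reaches rarefaction depth "
            f"{p.rarefaction_depth}"
        )
    kept_idx = np.flatnonzero(keep)
    out = t.subset_samples(kept_idx)
    counts = out.counts
    new_counts = np.empty_like(counts)
    for i, sid in enumerate(out.sample_ids):
        row = counts[i]
        if row.sum() == p.rarefaction_depth:
            new_counts[i] = row
        else:
            rng = child_rng(seed, "rarefy", sid)
            new_counts[i] = _rarefy_row(row.astype(np.int64), p.rarefaction_depth, rng)
    return out.with_counts(new_counts)


def subsample_samples(
    t: SampleTable, p: PreprocessParams, seed: int | None = None
) -> SampleTable:
    """Draw exactly ``samples_per_forest`` samples uniformly without replacement.

    The draw is made over the lexicographically sorted sample ids (so the
    selected *set* is invariant to input row order); the returned table keeps
    the input's relative row order restricted to the selection.
    """
    if seed is None:
        seed = p.seed
    n = t.n_samples
    k = p.samples_per_forest
    if n < k:
        raise ValidationError(
            f"forest {t.forest_id}: only {n} samples available, {k} requested"
        )
    order = np.argsort(np.asarray(t.sample_ids, dtype=object))
    rng = child_rng(seed, "subsample", t.forest_id)
    chosen_sorted = rng.choice(n, size=k, replace=False)
    chosen = set(order[chosen_sorted].tolist())
    index = [i for i in range(n) if i in chosen]
    return t.subset_samples(index)


def preprocess(
    t: SampleTable, p: PreprocessParams, seed: int | None = None
) -> SampleTable:
    """filter -> rarefy -> subsample, the full sample-level pipeline.

    Retains exactly ``min(samples_per_forest, #samples at depth)`` samples:
    when fewer samples survive rarefaction than requested, all survivors are
    kept (with a warning) rather than failing the forest.
    """
    filtered = filter_rare_entries(t, p)
    rare = rarefy(filtered, p, seed=seed)
    if rare.n_samples < p.samples_per_forest:
        logger.warning(
            "forest %s: only %d samples at depth %d (requested %d); keeping all",
            t.forest_id,
            rare.n_samples,
            p.rarefaction_depth,
            p.samples_per_forest,
        )
        return rare
    return subsample_samples(rare, p, seed=seed)


def accumulation_curve(t: SampleTable) -> np.ndarray:
    """Analytic sample-based accumulation curve of expected OTU richness.

    For k samples drawn equiprobably without replacement from the N available,
    the expected number of observed OTUs is

        E[S_k] = sum_i [ 1 - C(N - n_i, k) / C(N, k) ],

    where n_i is the number of samples containing OTU i.  Computed with exact
    integer binomials, so the curve is deterministic.  Returns an array of
    shape (N, 2) with columns (k, E[S_k]).
    """
    if t.n_samples == 0:
        raise ValidationError("empty table has no accumulation curve")
    presence_counts = (t.counts > 0).sum(axis=0)
    presence_counts = presence_counts[presence_counts > 0]
    n_samples = t.n_samples
    uniq, mult = np.unique(presence_counts, return_counts=True)
    curve = np.empty((n_samples, 2))
    for ki, k in enumerate(range(1, n_samples + 1)):
        denom = math.comb(n_samples, k)
        expected = 0.0
        for n_i, w in zip(uniq, mult):
            expected += w * (1.0 - math.comb(n_samples - int(n_i), k) / denom)
        curve[ki] = (k, expected)
    return curve
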