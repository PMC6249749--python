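"""Synthetic root-metabarcoding datasets with controllable network structure.

The generator emulates the sampling design of a multi-forest root-tip survey:
in each forest a fixed number of terminal-root samples is collected, each
sample belongs to one host plant (drawn from an uneven, geometric abundance
distribution), and its fungal reads follow a plant-conditional multinomial
over the OTU pool.  The plant x OTU affinity matrix composes four ingredients:

* a guild-compatibility mask — AM fungi with AM/dual plants, ECM fungi with
  ECM/dual plants, other guilds with every plant — softened by a leakage
  weight ``guild_leakage_eps`` for out-of-guild associations;
* per-plant Dirichlet-style preference draws with concentration
  ``specialization_alpha`` (small alpha -> each plant concentrates on few
  OTUs, i.e. high host specificity);
* OTU-level generalism weights following a power law in ``generalism_gamma``
  (a broad spread of generalists and specialists promotes nested structure);
* an optional block mask (``block_structure``) confining plants and OTUs to
  compartments, the regime producing anti-nested, host-differentiated
  networks.

Read depths are negative-binomially over-dispersed so the rarefaction drop
path is exercised, and Poisson "contamination" adds single-read spurious
entries that the 0.1% entry filter should remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_rng
from .errors import ValidationError
from .tables import (
    GUILDS,
    OTUAnnotationTable,
    PlantAnnotationTable,
    SampleTable,
)

#: Default per-guild OTU pool, shaped like a root-associated fungal community:
#: saprotroph/endophyte-rich, a sizable unassignable fraction, and only a
#: handful of confirmed pathogens.
DEFAULT_OTU_POOL = {"AM": 150, "ECM": 250, "SAPENDO": 350, "PATHO": 20, "UNKNOWN": 430}

#: Mycorrhizal-type composition of the default plant pool.
_PLANT_TYPE_FRACTIONS = {
    "AM_PLANT": 0.55,
    "ECM_PLANT": 0.25,
    "NM_PLANT": 0.12,
    "DUAL": 0.08,
}


@dataclass
class SyntheticConfig:
    """Generative parameters for a multi-forest synthetic study.

    Defaults mirror the emulated sampling design: 8 forests, 383 samples
    collected per forest, 17-55 plant species/taxa per forest, ~1200 fungal
    OTUs spread over five guilds, and mean read depths high enough that
    rarefaction to 1000 reads retains most samples.
    """

    n_forests: int = 8
    n_samples_collected: int = 383
    plant_pool_size: int = 80
    plants_per_forest: tuple[int, int] = (17, 55)
    otu_pool: dict = field(default_factory=lambda: dict(DEFAULT_OTU_POOL))
    specialization_alpha: float = 1.0
    concentration_scale: float = 10.0
    generalism_gamma: float = 1.0
    otu_occupancy: float = 0.7
    block_structure: bool = False
    n_blocks: int = 4
    block_leakage: float = 0.02
    guild_leakage_eps: float = 0.05
    reads_mean: float = 1500.0
    reads_dispersion: float = 10.0
    contamination_rate: float = 2.0
    abundance_ratio: float = 0.88
    exchangeable: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.specialization_alpha <= 0:
            raise ValidationError("specialization_alpha must be > 0")
        if not (0 <= self.guild_leakage_eps <= 1):
            raise ValidationError("guild_leakage_eps must be in [0, 1]")
        if not (0 <= self.block_leakage <= 1):
            raise ValidationError("block_leakage must be in [0, 1]")
        if self.reads_mean < 1:
            raise ValidationError("reads_mean must be >= 1")
        if not (0 < self.otu_occupancy <= 1):
            raise ValidationError("otu_occupancy must be in (0, 1]")
        lo, hi = self.plants_per_forest
        if not (1 <= lo <= hi <= self.plant_pool_size):
            raise ValidationError("plants_per_forest range incompatible with pool size")
        for g in self.otu_pool:
            if g not in GUILDS:
                raise ValidationError(f"unknown guild {g!r} in otu_pool")


@dataclass
class GroundTruth:
    """Per-forest affinity matrices and the config that generated them."""

    affinity: dict  # forest_id -> (plant_labels, otu_ids, matrix)
    sample_plants: dict  # forest_id -> list of true plant labels per sample
    config: SyntheticConfig


def exchangeable_config(base: SyntheticConfig) -> SyntheticConfig:
    """Variant in which every plant shares one affinity vector.

    Fungal composition is then independent of the host label, so the
    host-label-shuffle null hypothesis is exactly true; used to calibrate
    relative indices.  ``specialization_alpha`` has no effect in this regime.
    """
    return replace(base, exchangeable=True)


def _build_pools(cfg: SyntheticConfig):
    otu_ids: list[str] = []
    guilds: list[str] = []
    for guild in GUILDS:
        n = int(cfg.otu_pool.get(guild, 0))
        start = len(otu_ids)
        otu_ids.extend(f"OTU{start + k + 1:05d}" for k in range(n))
        guilds.extend([guild] * n)
    if len(otu_ids) < 2:
        raise ValidationError("otu_pool must contain at least 2 OTUs")
    plant_labels = [f"plant_{i + 1:03d}" for i in range(cfg.plant_pool_size)]
    types: list[str] = []
    # Deterministic type assignment by fixed fractions, interleaved so any
    # contiguous pool slice mixes all four types.
    quota = {
        t: max(1, round(f * cfg.plant_pool_size))
        for t, f in _PLANT_TYPE_FRACTIONS.items()
    }
    cycle = [t for t, n in quota.items() for _ in range(n)]
    while len(cycle) < cfg.plant_pool_size:
        cycle.append("AM_PLANT")
    rng = child_rng(cfg.seed, "plant-types")
    types = list(rng.permutation(np.asarray(cycle[: cfg.plant_pool_size], dtype=object)))
    return otu_ids, guilds, plant_labels, [str(t) for t in types]


def _compatibility(plant_type: str, guild: str) -> bool:
    if guild == "AM":
        return plant_type in ("AM_PLANT", "DUAL")
    if guild == "ECM":
        return plant_type in ("ECM_PLANT", "DUAL")
    return True


def _forest_affinity(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    plant_types: list[str],
    guilds: list[str],
) -> np.ndarray:
    """Row-stochastic plant x OTU affinity matrix for one forest."""
    n_plants = len(plant_types)
    n_otus = len(guilds)
    # OTU generalism: power-law weights on a random ordering of OTUs,
    # normalized to mean 1 so they set relative, not absolute, concentration.
    ranks = rng.permutation(n_otus) + 1
    weights = ranks.astype(np.float64) ** (-cfg.generalism_gamma)
    # Metacommunity turnover: each forest hosts only part of the OTU pool,
    # so per-forest richness varies and communities differ between forests.
    occupied = rng.random(n_otus) < cfg.otu_occupancy
    if occupied.sum() < 2:
        raise ValidationError("infeasible config: fewer than 2 OTUs occupy the forest")
    weights = weights * occupied
    weights = weights / weights.mean()
    if cfg.exchangeable:
        shared = rng.gamma(cfg.concentration_scale * weights)
        if shared.sum() == 0:
            raise ValidationError("degenerate shared affinity")
        affinity = np.tile(shared / shared.sum(), (n_plants, 1))
        return affinity
    mask = np.empty((n_plants, n_otus))
    for i, ptype in enumerate(plant_types):
        for_guild = np.array([_compatibility(ptype, g) for g in guilds])
        mask[i] = np.where(for_guild, 1.0, cfg.guild_leakage_eps)
    if cfg.block_structure:
        plant_block = np.arange(n_plants) % cfg.n_blocks
        otu_block = rng.permutation(n_otus) % cfg.n_blocks
        same = plant_block[:, None] == otu_block[None, :]
        mask = mask * np.where(same, 1.0, cfg.block_leakage)
    # Plant preferences: Dirichlet-style gamma draws whose concentration is
    # proportional to alpha and aligned with the generalism weights.  Each
    # plant applies its own steepness multiplier to the shared OTU ranking,
    # so a broad weight spread (large gamma) yields ordered breadth
    # differences over common generalist OTUs — nested partner sets — while
    # a small alpha concentrates each plant on few, idiosyncratic OTUs.
    # Breadth heterogeneity grows with the weight spread: at gamma = 1 every
    # plant shares the same mild ranking; steeper regimes spread plants over
    # ordered breadths (mean steepness stays equal to gamma).
    steepness = 1.0 + (cfg.generalism_gamma - 1.0) * rng.uniform(
        0.5, 1.5, size=n_plants
    )
    plant_weights = ranks.astype(np.float64)[None, :] ** (-steepness[:, None])
    plant_weights = plant_weights * occupied[None, :]
    plant_weights = plant_weights / plant_weights.mean(axis=1, keepdims=True)
    shape = cfg.specialization_alpha * cfg.concentration_scale * plant_weights
    prefs = rng.gamma(shape)
    affinity = mask * prefs
    row_sums = affinity.sum(axis=1)
    dead = row_sums == 0
    if dead.any():
        raise ValidationError(
            "infeasible config: plant(s) with zero compatible affinity mass "
            f"(indices {np.flatnonzero(dead).tolist()})"
        )
    return affinity / row_sums[:, None]


def _negative_binomial_totals(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Over-dispersed read totals: NB with mean ``mean`` and shape ``dispersion``."""
    p = dispersion / (dispersion + mean)
    totals = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(totals, 1)


def generate_forest(
    cfg: SyntheticConfig, forest_index: int
) -> tuple[SampleTable, list[str], np.ndarray, list[str]]:
    """One forest's sample table plus its ground-truth affinity."""
    otu_ids, guilds, pool_labels, pool_types = _build_pools(cfg)
    forest_id = f"forest_{forest_index + 1}"
    rng = child_rng(cfg.seed, "forest", forest_index)
    lo, hi = cfg.plants_per_forest
    n_plants = int(rng.integers(lo, hi + 1))
    chosen = np.sort(rng.choice(cfg.plant_pool_size, size=n_plants, replace=False))
    plant_labels = [pool_labels[i] for i in chosen]
    plant_types = [pool_types[i] for i in chosen]
    # Geometric rank-abundance: a few dominant hosts, many rare ones.
    abundance = cfg.abundance_ratio ** np.arange(n_plants)
    abundance = abundance / abundance.sum()
    affinity = _forest_affinity(cfg, rng, plant_types, guilds)
    n_otus = len(otu_ids)
    counts = np.zeros((cfg.n_samples_collected, n_otus), dtype=np.int64)
    sample_plants_idx = rng.choice(n_plants, size=cfg.n_samples_collected, p=abundance)
    totals = _negative_binomial_totals(
        rng, cfg.reads_mean, cfg.reads_dispersion, cfg.n_samples_collected
    )
    for s in range(cfg.n_samples_collected):
        counts[s] = rng.multinomial(totals[s], affinity[sample_plants_idx[s]])
        n_cont = rng.poisson(cfg.contamination_rate)
        if n_cont:
            cont_otus = rng.integers(0, n_otus, size=n_cont)
            np.add.at(counts[s], cont_otus, 1)
    table = SampleTable(
        forest_id=forest_id,
        sample_ids=[f"{forest_id}_s{k + 1:04d}" for k in range(cfg.n_samples_collected)],
        plant_labels=[plant_labels[i] for i in sample_plants_idx],
        otu_ids=otu_ids,
        counts=counts,
    )
    return table, plant_labels, affinity, plant_types


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[SampleTable], OTUAnnotationTable, PlantAnnotationTable, GroundTruth]:
    """Full multi-forest dataset: sample tables, annotations, ground truth."""
    otu_ids, guilds, pool_labels, pool_types = _build_pools(cfg)
    taxonomy = [f"Fungi;guild_{g.lower()};unidentified" for g in guilds]
    otu_ann = OTUAnnotationTable(otu_ids=otu_ids, guilds=guilds, taxonomy=taxonomy)
    plant_ann = PlantAnnotationTable(
        plant_labels=pool_labels, mycorrhizal_types=pool_types
    )
    tables = []
    affinity = {}
    sample_plants = {}
    for f in range(cfg.n_forests):
        table, plant_labels, aff, _ = generate_forest(cfg, f)
        tables.append(table)
        affinity[table.forest_id] = (plant_labels, otu_ids, aff)
        sample_plants[table.forest_id] = list(table.plant_labels)
    truth = GroundTruth(affinity=affinity, sample_plants=sample_plants, config=cfg)
    return tables, otu_ann, plant_ann, truth
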