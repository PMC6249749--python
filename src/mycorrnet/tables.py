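"""Core in-memory containers for the pipeline.

The analysis moves through two matrix representations:

* :class:`SampleTable` — one root *sample* per row, one fungal OTU per column,
  integer read counts in cells.  This is the unit on which quality filtering,
  rarefaction and the host-label-shuffle null model operate.
* :class:`SpeciesMatrix` — one plant species/taxon per row, one fungal OTU per
  column; a cell counts the number of samples in which that plant-OTU
  association was observed.  Network indices are computed on this matrix.

Annotation tables attach a functional guild to each OTU and a mycorrhizal type
to each plant; they drive the extraction of guild-specific partial networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

GUILDS = ("AM", "ECM", "SAPENDO", "PATHO", "UNKNOWN")
MYCORRHIZAL_TYPES = ("AM_PLANT", "ECM_PLANT", "NM_PLANT", "DUAL")
CATEGORIES = ("ALL", "AM", "AM_EX", "ECM", "ECM_EX", "SAPENDO", "PATHO")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class SampleTable:
    """Sample x OTU read-count matrix for one forest, with a plant label per sample."""

    forest_id: str
    sample_ids: list[str]
    plant_labels: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = list(self.sample_ids)
        self.plant_labels = list(self.plant_labels)
        self.otu_ids = list(self.otu_ids)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, m = self.counts.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample_ids but {n} count rows"
            )
        if len(self.plant_labels) != n:
            raise ValidationError(
                f"{len(self.plant_labels)} plant_labels for {n} samples"
            )
        if len(self.otu_ids) != m:
            raise ValidationError(f"{len(self.otu_ids)} otu_ids but {m} count columns")
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.otu_ids, "otu_id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                bad = np.argwhere(self.counts != np.floor(self.counts))
                if bad.size:
                    i, j = bad[0]
                    raise ValidationError(
                        f"non-integer count at sample {self.sample_ids[i]!r}, "
                        f"OTU {self.otu_ids[j]!r}: {self.counts[i, j]}"
                    )
                self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean sample x OTU occurrence matrix."""
        return self.counts > 0

    def with_counts(self, counts: np.ndarray) -> "SampleTable":
        return replace(self, counts=counts)

    def subset_samples(self, index: np.ndarray | list[int]) -> "SampleTable":
        index = np.asarray(index)
        return SampleTable(
            forest_id=self.forest_id,
            sample_ids=[self.sample_ids[i] for i in index],
            plant_labels=[self.plant_labels[i] for i in index],
            otu_ids=list(self.otu_ids),
            counts=self.counts[index].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        return (
            self.forest_id == other.forest_id
            and self.sample_ids == other.sample_ids
            and self.plant_labels == other.plant_labels
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class OTUAnnotationTable:
    """Functional guild (and optional taxonomy) for each fungal OTU.

    Guilds form a closed five-value vocabulary; OTUs whose ecology could not be
    inferred carry UNKNOWN.
    """

    otu_ids: list[str]
    guilds: list[str]
    taxonomy: list[str] | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.otu_ids, "otu_id")
        if len(self.guilds) != len(self.otu_ids):
            raise ValidationError("guilds and otu_ids length mismatch")
        for otu, g in zip(self.otu_ids, self.guilds):
            if g not in GUILDS:
                raise ValidationError(f"guild {g!r} for OTU {otu!r} not in {GUILDS}")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.otu_ids):
            raise ValidationError("taxonomy and otu_ids length mismatch")
        self._index = dict(zip(self.otu_ids, self.guilds))

    def guild_of(self, otu_id: str, default: str = "UNKNOWN") -> str:
        return self._index.get(otu_id, default)


@dataclass
class PlantAnnotationTable:
    """Mycorrhizal type for each plant species/taxon.

    DUAL marks plants documented to engage in both arbuscular and
    ectomycorrhizal symbioses.
    """

    plant_labels: list[str]
    mycorrhizal_types: list[str]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.plant_labels, "plant_label")
        if len(self.mycorrhizal_types) != len(self.plant_labels):
            raise ValidationError("mycorrhizal_types and plant_labels length mismatch")
        for p, t in zip(self.plant_labels, self.mycorrhizal_types):
            if t not in MYCORRHIZAL_TYPES:
                raise ValidationError(
                    f"mycorrhizal type {t!r} for plant {p!r} not in {MYCORRHIZAL_TYPES}"
                )
        self._index = dict(zip(self.plant_labels, self.mycorrhizal_types))

    def type_of(self, plant_label: str, default: str = "NM_PLANT") -> str:
        return self._index.get(plant_label, default)


@dataclass
class SpeciesMatrix:
    """Plant x OTU association matrix; cells count samples exhibiting the link."""

    plant_labels: list[str]
    otu_ids: list[str]
    assoc: np.ndarray
    category: str = "ALL"
    forest_id: str = ""

    def __post_init__(self) -> None:
        self.assoc = np.asarray(self.assoc)
        self.plant_labels = list(self.plant_labels)
        self.otu_ids = list(self.otu_ids)
        if self.category not in CATEGORIES:
            raise ValidationError(f"category {self.category!r} not in {CATEGORIES}")
        if self.assoc.shape != (len(self.plant_labels), len(self.otu_ids)):
            raise ValidationError("assoc shape does not match label lists")
        if np.any(self.assoc < 0):
            raise ValidationError("negative association count")

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def degenerate(self) -> bool:
        """Too small for network indices: fewer than 2 plants or 2 OTUs."""
        return self.n_plants < 2 or self.n_otus < 2

    def pruned(self) -> "SpeciesMatrix":
        """Drop all-zero rows and columns (a fixpoint: pruning twice is pruning once)."""
        rows = np.flatnonzero(self.assoc.sum(axis=1) > 0)
        cols = np.flatnonzero(self.assoc.sum(axis=0) > 0)
        return SpeciesMatrix(
            plant_labels=[self.plant_labels[i] for i in rows],
            otu_ids=[self.otu_ids[j] for j in cols],
            assoc=self.assoc[np.ix_(rows, cols)].copy(),
            category=self.category,
            forest_id=self.forest_id,
        )
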