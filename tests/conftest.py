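import numpy as np
import pytest

from mycorrnet import (
    OTUAnnotationTable,
    PlantAnnotationTable,
    PreprocessParams,
    SampleTable,
    SyntheticConfig,
)

#: Compact OTU pool used by simulation-backed tests (200 OTUs).
SMALL_POOL = {"AM": 40, "ECM": 50, "SAPENDO": 60, "PATHO": 10, "UNKNOWN": 40}


@pytest.fixture
def tiny_table() -> SampleTable:
    """Two samples, two OTUs, the smallest non-trivial table."""
    return SampleTable(
        forest_id="f1",
        sample_ids=["s1", "s2"],
        plant_labels=["plantA", "plantB"],
        otu_ids=["otu1", "otu2"],
        counts=np.array([[3, 0], [0, 5]]),
    )


@pytest.fixture
def random_table() -> SampleTable:
    """A moderately sized random table for oracle comparisons."""
    rng = np.random.default_rng(42)
    n, m = 20, 15
    return SampleTable(
        forest_id="f1",
        sample_ids=[f"s{i}" for i in range(n)],
        plant_labels=[f"plant{rng.integers(0, 5)}" for _ in range(n)],
        otu_ids=[f"otu{j}" for j in range(m)],
        counts=rng.integers(0, 50, size=(n, m)),
    )


@pytest.fixture
def annotations() -> tuple[OTUAnnotationTable, PlantAnnotationTable]:
    otus = OTUAnnotationTable(
        otu_ids=[f"otu{j}" for j in range(15)],
        guilds=(["AM"] * 4 + ["ECM"] * 4 + ["SAPENDO"] * 3 + ["PATHO"] * 2 + ["UNKNOWN"] * 2),
    )
    plants = PlantAnnotationTable(
        plant_labels=[f"plant{i}" for i in range(5)],
        mycorrhizal_types=["AM_PLANT", "ECM_PLANT", "NM_PLANT", "DUAL", "AM_PLANT"],
    )
    return otus, plants


@pytest.fixture
def small_config() -> SyntheticConfig:
    """One small forest; fast to generate and preprocess."""
    return SyntheticConfig(
        n_forests=1,
        n_samples_collected=120,
        plant_pool_size=12,
        plants_per_forest=(10, 12),
        otu_pool=dict(SMALL_POOL),
        seed=7,
    )


@pytest.fixture
def default_params() -> PreprocessParams:
    return PreprocessParams(seed=1)
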