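import numpy as np
import pandas as pd
import pytest

from braincci import (
    ExpressionMatrix,
    MarkerSetCollection,
    SampleMetadata,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_markers() -> MarkerSetCollection:
    return MarkerSetCollection({
        "neu": ["SYT1", "SNAP25", "GRIN1"],
        "ast": ["GFAP", "AQP4", "SLC1A2"],
        "mic": ["AIF1", "CX3CR1", "TMEM119"],
    })


@pytest.fixture
def toy_expression(toy_markers) -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = toy_markers.all_genes + ["BG1", "BG2", "BG3"]
    data = pd.DataFrame(
        rng.lognormal(3.0, 0.5, (len(genes), 8)),
        index=genes,
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(data, "linear")


@pytest.fixture
def toy_metadata(toy_expression) -> SampleMetadata:
    ids = toy_expression.sample_ids
    half = len(ids) // 2
    return SampleMetadata(pd.DataFrame({
        "group": ["control"] * half + ["case"] * (len(ids) - half),
        "severity": np.arange(len(ids), dtype=float),
    }, index=pd.Index(ids, name="sample_id")))


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no composition difference between groups."""
    return simulate_cohort(SimulationConfig(n_case=20, n_control=20,
                                            n_background_genes=100, seed=3))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with neuronal loss planted in cases (fraction halved)."""
    return simulate_cohort(SimulationConfig(effect_map={"neu": 0.5},
                                            n_case=60, n_control=60, seed=5))
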