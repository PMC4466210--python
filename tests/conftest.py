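import numpy as np
import pandas as pd
import pytest

from mitonuclear import datasets as ds
from mitonuclear.lineage import HaplotypeReference, genotypes_from_printed_tokens
from mitonuclear.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def published_refs() -> tuple[HaplotypeReference, HaplotypeReference]:
    """The two breed reference rows, panel calls only."""
    return (
        HaplotypeReference(
            "Large White", ds.LARGE_WHITE_ACCESSION, dict(ds.LARGE_WHITE_CALLS)
        ),
        HaplotypeReference("Duroc", ds.DUROC_ACCESSION, dict(ds.DUROC_CALLS)),
    )


@pytest.fixture(scope="session")
def published_genotypes():
    return genotypes_from_printed_tokens(ds.ANIMAL_PANEL_CALLS, ds.PANEL_POSITIONS)


@pytest.fixture(scope="session")
def published_design() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": a, "group": g, "role": r}
            for a, g, r, _ in ds.ANIMAL_PANEL_CALLS
        ]
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fast default for slide-level tests: full cohort, few probes."""
    return SimulationConfig(
        n_probes=300,
        n_nuclear_mito=60,
        n_mtdna=20,
        noise_sd=0.25,
        treatment_effect_sd=0.6,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
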