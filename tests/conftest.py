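import numpy as np
import pandas as pd
import pytest

from evoparallel.simulate import SimParams, simulate_study
from evoparallel.types import OmicsMatrix, RunConfig, meta_frame, SampleMeta


SMALL = SimParams(
    n_genes=600,
    n_metabolites=60,
    genes_per_module=5,
    seed=42,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SMALL


@pytest.fixture(scope="session")
def small_study(small_params):
    """One reduced-size draw of the full study design, shared across tests."""
    return simulate_study(small_params)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig(rng_seed=42)


@pytest.fixture()
def tiny_counts() -> OmicsMatrix:
    """3 genes x 8 samples (5 ancestral + one evolved population of 3)."""
    samples = [SampleMeta(f"anc_{i}", "anc", "ancestral", i) for i in range(1, 6)]
    samples += [SampleMeta(f"pop1_{i}", "pop1", "evolved", i) for i in range(1, 4)]
    meta = meta_frame(samples)
    values = pd.DataFrame(
        np.array(
            [
                [10, 12, 11, 9, 13, 30, 28, 35],
                [100, 90, 110, 95, 105, 100, 98, 102],
                [0, 0, 0, 0, 0, 0, 0, 0],
            ]
        ),
        index=["gA", "gB", "gC"],
        columns=[s.sample_id for s in samples],
    )
    return OmicsMatrix(values=values, meta=meta, value_kind="counts")
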