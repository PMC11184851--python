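"""Shared fixtures.

Expensive artifacts (the default synthetic dataset and the full seed-1
pipeline run used by the acceptance tests) are computed once per session.
"""

import numpy as np
import pandas as pd
import pytest

from scfibro import (GeneratorConfig, LrProgram, PipelineConfig,
                     generate_counts, run_pipeline)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic experiment (3,000 cells, 12 populations), seed 1."""
    config = GeneratorConfig(seed=1, lr_programs=[LrProgram()])
    counts, meta, truth = generate_counts(config)
    return config, counts, meta, truth


@pytest.fixture(scope="session")
def seed1_run():
    """Full pipeline run at the acceptance configuration (seed 1)."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def tiny_counts():
    """4 cells x 5 genes with a mitochondrial gene and hand-checkable totals."""
    return pd.DataFrame(
        [[5, 0, 3, 2, 0],
         [1, 1, 1, 1, 1],
         [0, 0, 0, 4, 0],
         [10, 2, 0, 0, 8]],
        index=[f"c{i}" for i in range(4)],
        columns=["mt-1", "g1", "g2", "g3", "g4"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
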