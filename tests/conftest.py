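"""Shared fixtures.

The expensive end-to-end run (default study conditions: 20,000 variants,
three case-control GWAS of 5,000 cases + 5,000 controls with half-shared
controls, a 5,000-case target cohort) is computed once per session and
reused by every test that needs realistic pipeline output.
"""

import numpy as np
import pandas as pd
import pytest

from liabsem.genotypes import GenotypeData
from liabsem.pipeline import run_pipeline
from liabsem.simulate import SimulationConfig, simulate_study

FULL_SEED = 11


@pytest.fixture(scope="session")
def full_study():
    return simulate_study(SimulationConfig(), seed=FULL_SEED)


@pytest.fixture(scope="session")
def full_result(full_study):
    return run_pipeline(full_study, run_associations=True, score_sources=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_genotypes(matrix, chrom=None, pos=None, ids=None) -> GenotypeData:
    """GenotypeData from a raw 0/1/2 matrix with a minimal variant map."""
    matrix = np.asarray(matrix, dtype=np.int8)
    m = matrix.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypeData(matrix, variants)
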