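import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from imna import (
    AtlasConfig,
    ArrayInfo,
    ExpressionMatrix,
    RAW_INTENSITY,
    LOG2_CENTERED,
    filter_expressed_probes,
    generate_atlas,
    normalize_log2_center,
)


def make_matrix(values, columns=None, probes=None, scale=LOG2_CENTERED):
    """Build a small ExpressionMatrix from a 2-D array.

    Column ids follow the `<population>__rep<k>` convention; default columns
    are two populations ("A", "B") filled round-robin with replicates.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_probes, n_arrays = values.shape
    if probes is None:
        probes = [f"P{i:03d}" for i in range(n_probes)]
    if columns is None:
        half = (n_arrays + 1) // 2
        columns = [f"A__rep{i + 1}" for i in range(half)] + \
                  [f"B__rep{i + 1}" for i in range(n_arrays - half)]
    from imna.expression import parse_array_id

    arrays = [parse_array_id(c) for c in columns]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=columns),
        gene_symbols=pd.Series(probes, index=probes),
        arrays=arrays,
        scale=scale,
    )


SMALL_ATLAS = dict(
    n_populations=8, n_replicates=3, n_genes=240, n_modules=6,
    n_regulators=12, n_planted_regulators=6, n_known_listed=4,
    n_low_probes=20,
)


@pytest.fixture(scope="session")
def default_atlas():
    cfg = AtlasConfig(seed=1)
    matrix, truth = generate_atlas(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def normalized_default(default_atlas):
    _, matrix, _ = default_atlas
    return normalize_log2_center(filter_expressed_probes(matrix))


@pytest.fixture(scope="session")
def noiseless_atlas():
    cfg = AtlasConfig(seed=1, noise_sd=0.0)
    matrix, truth = generate_atlas(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_atlas():
    cfg = AtlasConfig(seed=7, **SMALL_ATLAS)
    matrix, truth = generate_atlas(cfg)
    return cfg, matrix, truth
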