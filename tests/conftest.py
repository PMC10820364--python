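import numpy as np
import pytest

from aopqsar.assay_labeling import aggregate_hitcalls
from aopqsar.synthetic_data import (
    SyntheticConfig,
    AssaySpec,
    generate_assay_matrix,
    generate_library,
)


@pytest.fixture(scope="session")
def small_library():
    """200 compounds (60 active / 140 inactive) with planted toxicophore."""
    cfg = SyntheticConfig(n_active=60, n_inactive=140, seed=11)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_smiles(small_library):
    compounds, _ = small_library
    return [c.canonical_smiles for c in compounds]


@pytest.fixture(scope="session")
def small_endpoint(small_library):
    """Noise-free endpoint dataset over the small library (labels = truth)."""
    compounds, truth = small_library
    cfg = SyntheticConfig(
        n_active=60,
        n_inactive=140,
        assay_specs=[AssaySpec(f"a{j}") for j in range(3)],
        seed=11,
    )
    matrix = generate_assay_matrix(compounds, truth, cfg)
    return aggregate_hitcalls(matrix, matrix.assays, endpoint_name="toy")


@pytest.fixture(scope="session")
def small_fp(small_library):
    from aopqsar.encoders import compute_circular_fp

    compounds, _ = small_library
    return compute_circular_fp(compounds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
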