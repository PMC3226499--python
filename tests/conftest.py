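import numpy as np
import pandas as pd
import pytest

from pvdc import AnnotationTable, AssayAnnotation, PotencyMatrix
from pvdc.datasets import (
    load_rabbit_specific_endpoints,
    load_reference_vascular_targets,
)


@pytest.fixture(scope="session")
def vascular_screen():
    """Reference biochemical screen: (potency matrix, metadata)."""
    return load_reference_vascular_targets()


@pytest.fixture(scope="session")
def rabbit_records():
    return load_rabbit_specific_endpoints()


@pytest.fixture(scope="session")
def six_target_annotations():
    """Two assays per vascular target feature, twelve assays total."""
    from pvdc.simulate import GeneratorConfig, make_annotations

    cfg = GeneratorConfig(n_assays=12, seed=0)
    return make_annotations(cfg)


def random_matrix(rng, n_chem=10, n_assay=10, hit_rate=0.3, prefix="A"):
    """Random sparse potency matrix for oracle comparisons."""
    values = np.where(
        rng.random((n_chem, n_assay)) < hit_rate,
        10.0 ** rng.uniform(-1, np.log10(50), size=(n_chem, n_assay)),
        1e6,
    )
    return PotencyMatrix(
        pd.DataFrame(
            values,
            index=[f"C{i}" for i in range(n_chem)],
            columns=[f"{prefix}{j}" for j in range(n_assay)],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
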