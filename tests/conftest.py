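import numpy as np
import pytest

from metkern import (KernelMatrix, balanced_split, build_study_kernels,
                     generate_study)
from metkern.benchmark import default_study_metrics


def random_psd_kernel(n: int, seed: int, ids=None) -> KernelMatrix:
    """Random PSD Gram matrix A A^T over n genes (test helper)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n + 2))
    ids = ids or [f"g{i}" for i in range(n)]
    return KernelMatrix(tuple(ids), A @ A.T, f"rand{seed}")


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study for integration tests."""
    return generate_study(seed=7, n_genes=40, edge_density=0.12)


@pytest.fixture(scope="session")
def small_study_kernels(small_study):
    return build_study_kernels(small_study)


@pytest.fixture(scope="session")
def small_dataset(small_study):
    return balanced_split(small_study.network,
                          2 * small_study.network.n_edges, seed=7)


@pytest.fixture(scope="session")
def default_metrics():
    """Per-seed pipeline metrics on the default study, 10 seeds.

    This is the expensive end-to-end surface (several minutes); every test
    that needs it shares this one computation.
    """
    return default_study_metrics(seeds=tuple(range(1, 11)))
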