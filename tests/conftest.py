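import warnings

import numpy as np
import pytest

from fsmkl.data_io import LabelVector, OmicsBlock
from fsmkl.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def tiny_ds():
    """Small simulated multi-omics dataset shared across tests."""
    cfg = SimConfig(n_samples=80, n_features=(30, 30), n_pathways=6,
                    pathway_size=(4, 8), n_informative_pathways=2,
                    beta=1.0, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate(cfg)


@pytest.fixture()
def separable_1d():
    """Four 1-D points with an analytic maximal-margin separator at x = 0."""
    x = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([-1, -1, 1, 1])
    block = OmicsBlock("X", [f"s{i}" for i in range(4)], ["x"], x)
    labels = LabelVector(block.samples, y)
    return block, labels


def random_bank(seed, n=10, n_kernels=2, n_features=6, C_scale=1.0):
    """Seeded random instance: a bank of linear kernels on disjoint feature
    subsets plus balanced random labels."""
    from fsmkl.kernel_bank import BaseKernel, KernelBank, KernelSpec

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_kernels * n_features)) * C_scale
    y = np.ones(n, dtype=int)
    y[: n // 2] = -1
    rng.shuffle(y)
    kernels = []
    for k in range(n_kernels):
        cols = slice(k * n_features, (k + 1) * n_features)
        gram = X[:, cols] @ X[:, cols].T
        tr = float(np.trace(gram))
        spec = KernelSpec("X", tuple(f"f{j}" for j in range(n_features)),
                          "full_block", {"part": k}, "linear", {})
        kernels.append(BaseKernel(spec, gram / tr, tr))
    bank = KernelBank(kernels, [f"s{i}" for i in range(n)])
    return bank, y
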