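import numpy as np
import pandas as pd
import pytest

import resistsig as rs


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale study configuration used across the suite."""
    return rs.SimulationConfig(n_genes=400, n_true=40, n_cancer_genes=40,
                               seed=11)


@pytest.fixture(scope="session")
def paired_small(small_cfg):
    return rs.simulate_paired(small_cfg)


@pytest.fixture(scope="session")
def cohort_small(small_cfg, paired_small):
    _, _, truth = paired_small
    return rs.simulate_cohort(small_cfg, truth)


@pytest.fixture(scope="session")
def signature_small(paired_small):
    m, d, _ = paired_small
    return rs.extract_signature(rs.paired_moderated_t(m, d, prior="fit"), 0.01)


def make_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return rs.ExpressionMatrix(values, probes, samples)


@pytest.fixture
def toy_matrix():
    return make_matrix
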