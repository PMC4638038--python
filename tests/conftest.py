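import numpy as np
import pandas as pd
import pytest

from proteopanel import preprocess, quantify, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-subtype cohort with a planted differential set."""
    cfg = simulate.SimConfig(
        n_proteins=300,
        frac_differential=0.15,
        log2fc_range=(1.5, 2.5),
        frac_in_standard=0.8,
        seed=11,
    )
    return cfg, *simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def quantified(small_cohort):
    _, table, truth = small_cohort
    matrix, report = quantify.quantify_matrix(table)
    return matrix, report, truth


@pytest.fixture(scope="session")
def normalized(quantified):
    matrix, _, truth = quantified
    filtered, _ = preprocess.filter_valid_values(matrix)
    imputed = preprocess.impute(filtered, preprocess.ImputeParams(seed=4))
    return preprocess.width_normalize(imputed), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_matrix(rng):
    """Complete 40 x 8 log-intensity matrix."""
    data = rng.normal(25.0, 2.0, size=(40, 8))
    return pd.DataFrame(
        data,
        index=[f"P{i:03d}" for i in range(40)],
        columns=[f"S{j}" for j in range(8)],
    )
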