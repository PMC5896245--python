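import pandas as pd
import pytest

from devilseq.classify import SampleRoles
from devilseq.signatures import synthetic_signature_matrix
from devilseq.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def sigmatrix() -> pd.DataFrame:
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_germline=120, n_trunk=80, n_unique=80,
                       n_lowcov_normals=10, seed=11)
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth, SampleRoles.from_config(cfg)
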