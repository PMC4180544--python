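import numpy as np
import pandas as pd
import pytest

from statresp.preprocess import add_log_change, normalize_expression, screen_and_adjust_covariates
from statresp.simulate import SimConfig, batch_table, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_samples=120,
        n_genes=300,
        n_signature=30,
        n_eqtl_genes=10,
        eqtl_r2=0.8,
        n_gwas_snps=5,
        trait_r2_expression=0.4,
        trait_r2_snps=0.1,
        age_effect=-0.004,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def adjusted_records(small_cohort):
    records = add_log_change(small_cohort.phenotypes)
    _, records = screen_and_adjust_covariates(records)
    return records


@pytest.fixture(scope="session")
def responses(adjusted_records):
    return pd.Series({r.sample_id: r.adjusted_change for r in adjusted_records})


@pytest.fixture(scope="session")
def normalized_expression(small_cohort):
    return normalize_expression(small_cohort.expression, batch_table(small_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
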