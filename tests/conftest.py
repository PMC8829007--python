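import numpy as np
import pandas as pd
import pytest

from immunopipe.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_samples=120, n_genes=800, n_signatures=12, n_signature_genes=15,
        n_modules=4, k_subtypes=3, subtype_separation=3.0, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def random_expression(rng):
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{j}" for j in range(10)]
    return pd.DataFrame(rng.standard_normal((50, 10)), index=genes, columns=samples)


def make_survival(time, event, index=None):
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int)})
    if index is not None:
        df.index = pd.Index(index, name="sample_id")
    return df
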