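import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paritysig import SyntheticConfig, simulate_test_cohort, simulate_training_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic study used across tests."""
    return SyntheticConfig(
        n_genes=400,
        n_signature_genes=40,
        train_n_parous=24,
        train_n_nulliparous=18,
        test_n_subjects=60,
        noise_sd=0.5,
        log2fc_range=(0.4, 1.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_training(small_cfg):
    return simulate_training_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_test(small_cfg, small_training):
    _, _, truth = small_training
    return simulate_test_cohort(small_cfg, truth)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with easily traceable values."""
    return pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [1.0, 1.0, 1.0, 1.0],
            ]
        ),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )


def make_annotation(sample_ids, parity, **extra):
    """Minimal annotation frame for a list of samples."""
    n = len(sample_ids)
    base = {
        "sample_id": list(sample_ids),
        "subject_id": list(sample_ids),
        "parity": list(parity),
        "tissue": ["normal"] * n,
        "er_status": ["unknown"] * n,
        "menopausal": ["unknown"] * n,
        "age_first_birth_years": [np.nan] * n,
        "years_since_last_birth": [np.nan] * n,
    }
    base.update(extra)
    ann = pd.DataFrame(base, index=list(sample_ids))
    ann.index.name = None
    return ann
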