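import numpy as np
import pandas as pd
import pytest

import neurostack as ns
from neurostack.cohort import CohortConfig


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_per_group=(20, 10, 10), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = ns.generate_cohort(small_config)
    return ns.generate_mmse_trajectories(cohort, small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_config):
    return ns.generate_mo_ms_features(small_cohort, small_config)


@pytest.fixture(scope="session")
def mini_full_table(small_cohort, small_config, small_features):
    """688-column master table for the 40-subject toy cohort (2 rewired
    small-world references to keep GT extraction quick)."""
    connectomes = ns.generate_connectomes(small_cohort, small_config)
    gt = ns.gt_feature_table(connectomes, seed=small_config.seed,
                             subject_ids=[s.subject_id for s in small_cohort],
                             n_random_refs=2)
    from neurostack.ablation import prepare_feature_table
    from neurostack.cohort import abeta_table
    return prepare_feature_table(small_features, gt,
                                 abeta_table(small_cohort), small_cohort)


@pytest.fixture()
def toy_demographics():
    """Balanced demographics frame for transform tests."""
    rng = np.random.default_rng(11)
    n = 40
    return pd.DataFrame(
        {"age": rng.uniform(55, 95, n),
         "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
         "diagnosis": np.where(np.arange(n) < n // 2, "CN", "ADD")},
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"))
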