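import numpy as np
import pytest

from mbpower import AbundanceTable, CommunityModel, GroupLabels, generate_table


@pytest.fixture
def toy_table() -> AbundanceTable:
    """3 features x 2 samples, raw counts."""
    return AbundanceTable(
        feature_ids=("fA", "fB", "fC"),
        sample_ids=("s1", "s2"),
        values=np.array([[1.0, 2.0], [1.0, 3.0], [8.0, 5.0]]),
        scale="raw",
    )


@pytest.fixture(scope="session")
def community_table() -> AbundanceTable:
    """Default-parameter synthetic community at desk scale."""
    return generate_table(CommunityModel(n_features=2000, n_samples=88, seed=11))


@pytest.fixture(scope="session")
def small_table() -> AbundanceTable:
    """Small dense synthetic table for statistic-level tests."""
    return generate_table(
        CommunityModel(
            n_features=100,
            n_samples=88,
            correlation_blocks=((30, 0.8),),
            sparsity_curve=None,
            depth_dispersion=0.8,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def balanced_labels(small_table) -> GroupLabels:
    ids = small_table.sample_ids
    return GroupLabels(case=ids[:44], control=ids[44:])
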