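import numpy as np
import pytest

from clusticc import ClusterDataset, load_emip_fixture


@pytest.fixture
def toy_dataset() -> ClusterDataset:
    """Three clusters of three: {1,2,3}, {4,5,6}, {7,8,9}."""
    return ClusterDataset(
        variable_name="toy",
        var_type="continuous",
        clusters=np.repeat(["h1", "h2", "h3"], 3),
        values=np.arange(1.0, 10.0),
    )


@pytest.fixture(scope="session")
def fixture_table():
    return load_emip_fixture()


def make_dataset(values_by_cluster, var_type="continuous", name="x") -> ClusterDataset:
    """Build a ClusterDataset from a list of per-cluster value lists."""
    clusters = np.concatenate(
        [np.full(len(vals), i) for i, vals in enumerate(values_by_cluster)]
    )
    values = np.concatenate([np.asarray(v, dtype=float) for v in values_by_cluster])
    return ClusterDataset(name, var_type, clusters, values)
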