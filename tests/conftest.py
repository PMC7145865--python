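import numpy as np
import pandas as pd
import pytest

from stressnet import CohortSpec, DotProbeSpec
from stressnet.connectivity import ConnectivityMatrix, NetworkPartition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort: 3 networks, short scans, fast to simulate."""
    return CohortSpec(
        n_subjects=12,
        t_points=60,
        partition_sizes=(("DMN", 5), ("VAN", 4), ("VN", 3)),
        within_targets=0.3,
        between_targets=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def probe_spec():
    return DotProbeSpec(n_subjects=5, seed=11)


def random_connectivity(rng, n_nodes):
    """Random valid correlation matrix from random time series."""
    ts = rng.standard_normal((n_nodes + 40, n_nodes))
    A = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(A, 1.0)
    return ConnectivityMatrix(A=(A + A.T) / 2, node_ids=tuple(f"n{i}" for i in range(n_nodes)))


def random_partition(rng, node_ids, n_networks):
    """Random partition of node_ids into n_networks nonempty networks."""
    names = [f"net{k}" for k in range(n_networks)]
    while True:
        labels = rng.integers(0, n_networks, len(node_ids))
        if len(set(labels)) == n_networks:
            break
    return NetworkPartition(
        assignment={n: names[l] for n, l in zip(node_ids, labels)}, networks=tuple(names)
    )
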