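"""Connectivity matrix and within/between-network statistic tests."""

import numpy as np
import pandas as pd
import pytest

from stressnet.connectivity import (
    ConnectivityMatrix,
    ConnectivityProfiler,
    NetworkPartition,
    TimeSeriesMatrix,
    between_network_connectivity,
    correlation_matrix,
    profile_cohort,
    profiles_to_frame,
    within_network_connectivity,
)
from stressnet.synthetic import CohortSpec, simulate_timeseries

from conftest import random_connectivity, random_partition


def brute_force_within(A, partition, diagonal_policy):
    """Independent double-loop implementation of W_a."""
    out = {}
    pos = {n: i for i, n in enumerate(A.node_ids)}
    for net in partition.networks:
        members = [pos[n] for n in partition.members(net)]
        n = len(members)
        if diagonal_policy == "literal":
            total = 0.0
            for i in members:
                for j in members:
                    total += A.A[i, j]
            out[net] = total / n**2
        else:
            total, count = 0.0, 0
            for i in members:
                for j in members:
                    if i != j:
                        total += A.A[i, j]
                        count += 1
            out[net] = total / count if count else float("nan")
    return out


def brute_force_between(A, partition):
    """Independent double-loop implementation of PB_ab."""
    out = {}
    pos = {n: i for i, n in enumerate(A.node_ids)}
    for a, b in partition.pairs():
        ia = [pos[n] for n in partition.members(a)]
        ib = [pos[n] for n in partition.members(b)]
        total = sum(A.A[i, j] for i in ia for j in ib)
        out[(a, b)] = total / (len(ia) * len(ib))
    return out


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self):
        x = np.linspace(0, 1, 10)
        ts = TimeSeriesMatrix(np.column_stack([x, x]), ("a", "b"), "s1")
        A = correlation_matrix(ts)
        assert A.A[0, 1] == pytest.approx(1.0)

    def test_negated_column_gives_minus_one(self):
        x = np.sin(np.arange(20))
        ts = TimeSeriesMatrix(np.column_stack([x, -x]), ("a", "b"), "s1")
        assert correlation_matrix(ts).A[0, 1] == pytest.approx(-1.0)

    def test_four_point_toy_series(self):
        # hand computation: r = 6.5 / sqrt(5 * 8.75) = 0.9827 (4 d.p.)
        ts = TimeSeriesMatrix(
            np.column_stack([[1, 2, 3, 4], [1, 2, 3, 5]]), ("x", "y"), "s1"
        )
        assert correlation_matrix(ts).A[0, 1] == pytest.approx(0.9827, abs=5e-5)

    def test_constant_column_raises_naming_node(self):
        ts = TimeSeriesMatrix(
            np.column_stack([np.arange(5.0), np.ones(5)]), ("good", "flat"), "s1"
        )
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(ts)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            TimeSeriesMatrix(np.ones((2, 2)), ("a", "b"), "s1")


class TestNetworkStatistics:
    def test_perfectly_correlated_network_gives_unit_w(self):
        x = np.linspace(0, 1, 30)
        ts = TimeSeriesMatrix(np.column_stack([x, 2 * x, 3 * x]), ("a", "b", "c"), "s")
        A = correlation_matrix(ts)
        p = NetworkPartition({"a": "N1", "b": "N1", "c": "N1"})
        assert within_network_connectivity(A, p, "literal")["N1"] == pytest.approx(1.0)
        assert within_network_connectivity(A, p, "exclude_diagonal")["N1"] == pytest.approx(1.0)

    def test_two_node_half_correlation(self):
        A = ConnectivityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ("a", "b"))
        p = NetworkPartition({"a": "N1", "b": "N1"})
        assert within_network_connectivity(A, p, "literal")["N1"] == pytest.approx(0.75)
        assert within_network_connectivity(A, p, "exclude_diagonal")["N1"] == pytest.approx(0.5)

    def test_singleton_pair_between(self):
        A = ConnectivityMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]), ("a", "b"))
        p = NetworkPartition({"a": "N1", "b": "N2"})
        assert between_network_connectivity(A, p)[("N1", "N2")] == pytest.approx(0.3)

    def test_same_network_pair_not_in_between_map(self):
        A = ConnectivityMatrix(np.eye(2), ("a", "b"))
        p = NetworkPartition({"a": "N1", "b": "N1"})
        assert between_network_connectivity(A, p) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_connectivity(rng, 20)
        p = random_partition(rng, A.node_ids, 4)
        for policy in ("literal", "exclude_diagonal"):
            got = within_network_connectivity(A, p, policy)
            want = brute_force_within(A, p, policy)
            assert got == pytest.approx(want, abs=1e-12)
        assert between_network_connectivity(A, p) == pytest.approx(
            brute_force_between(A, p), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_literal_exclude_identity(self, seed):
        # W_literal = ((N_a - 1) * W_excl + 1) / N_a
        rng = np.random.default_rng(100 + seed)
        A = random_connectivity(rng, 15)
        p = random_partition(rng, A.node_ids, 3)
        lit = within_network_connectivity(A, p, "literal")
        exc = within_network_connectivity(A, p, "exclude_diagonal")
        sizes = p.sizes()
        for net in p.networks:
            n = sizes[net]
            if n == 1:
                continue
            assert lit[net] == pytest.approx(((n - 1) * exc[net] + 1) / n, abs=1e-12)

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(5)
        A = random_connectivity(rng, 12)
        p = random_partition(rng, A.node_ids, 3)
        perm = rng.permutation(12)
        A2 = ConnectivityMatrix(
            A.A[np.ix_(perm, perm)], tuple(A.node_ids[i] for i in perm)
        )
        assert within_network_connectivity(A, p) == pytest.approx(
            within_network_connectivity(A2, p), abs=1e-12
        )
        assert between_network_connectivity(A, p) == pytest.approx(
            between_network_connectivity(A2, p), abs=1e-12
        )

    def test_independent_series_between_near_zero(self):
        rng = np.random.default_rng(6)
        T = 4000
        ts = TimeSeriesMatrix(
            rng.standard_normal((T, 6)), tuple(f"n{i}" for i in range(6)), "s"
        )
        A = correlation_matrix(ts)
        p = NetworkPartition({f"n{i}": ("N1" if i < 3 else "N2") for i in range(6)})
        pb = between_network_connectivity(A, p)[("N1", "N2")]
        assert abs(pb) < 3 / np.sqrt(T)


class TestCohortProfiling:
    def test_single_subject_fully_populated(self, tiny_spec):
        ts = simulate_timeseries(tiny_spec, 0)
        profiles = profile_cohort([ts], tiny_spec.partition())
        assert len(profiles) == 1
        assert len(profiles[0].within) == 3
        assert len(profiles[0].between) == 3

    def test_empty_list_gives_empty_result(self, tiny_spec):
        assert profile_cohort([], tiny_spec.partition()) == []
        assert profiles_to_frame([]).empty

    def test_node_mismatch_names_subject(self, tiny_spec):
        ts = simulate_timeseries(tiny_spec, 0)
        bad = NetworkPartition({"zz0": "N1", "zz1": "N2"})
        with pytest.raises(ValueError, match=ts.subject_id):
            profile_cohort([ts], bad)

    def test_generator_ordering_preserved(self):
        # two networks with different within targets: mean W order follows targets
        spec = CohortSpec(
            n_subjects=10,
            t_points=300,
            partition_sizes=(("A", 6), ("B", 6)),
            within_targets={"A": 0.5, "B": 0.1},
            between_targets=0.0,
            mediation_coeffs=(0.0, 0.0, 0.0),
            target_sd=0.0,
            seed=3,
        )
        frame = profiles_to_frame(
            profile_cohort([simulate_timeseries(spec, i) for i in range(10)], spec.partition())
        )
        assert frame["within:A"].mean() > frame["within:B"].mean()

    def test_profiler_transform_shape_and_names(self, tiny_spec):
        prof = ConnectivityProfiler(partition=tiny_spec.partition()).fit([])
        frame = prof.transform(simulate_timeseries(tiny_spec, i) for i in range(3))
        assert frame.shape == (3, 6)
        assert list(frame.columns) == list(prof.get_feature_names_out())
        assert frame.columns[0].startswith("within:")

    def test_fisher_z_requires_exclude_diagonal(self):
        A = ConnectivityMatrix(np.eye(2), ("a", "b"))
        p = NetworkPartition({"a": "N1", "b": "N1"})
        with pytest.raises(ValueError, match="fisher_z"):
            within_network_connectivity(A, p, "literal", fisher_z=True)


class TestIO:
    def test_timeseries_tsv_roundtrip(self, tiny_spec, tmp_path):
        ts = simulate_timeseries(tiny_spec, 1)
        path = tmp_path / "sub.tsv"
        ts.to_tsv(path)
        back = TimeSeriesMatrix.from_tsv(path, subject_id=ts.subject_id)
        np.testing.assert_allclose(back.values, ts.values, atol=1e-12)
        assert back.node_ids == ts.node_ids

    def test_partition_csv_roundtrip(self, tiny_spec, tmp_path):
        p = tiny_spec.partition()
        path = tmp_path / "part.csv"
        p.to_csv(path)
        back = NetworkPartition.from_csv(path)
        assert back.assignment == p.assignment

    def test_partition_validation(self):
        with pytest.raises(ValueError, match="unique"):
            NetworkPartition({"a": "N1"}, networks=("N1", "N1"))
        with pytest.raises(ValueError, match="no nodes"):
            NetworkPartition({"a": "N1"}, networks=("N1", "N2"))
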