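"""Pearson connectivity matrices and network-level connectivity statistics.

A subject's resting-state signal is a ``T x N`` matrix (time points by ROI
nodes).  Functional connectivity between two nodes is the Pearson correlation
of their time courses.  Given a partition of the nodes into named networks,
two summary statistics condense the ``N x N`` matrix into a short profile:

* within-network connectivity ``W_a = (sum_{i,j in a} A_ij) / N_a**2`` —
  the block sum over all ordered node pairs of network ``a`` (including the
  unit diagonal) divided by the squared node count;
* between-network connectivity ``PB_ab = (sum_{i in a, j in b} A_ij) /
  (N_a * N_b)`` — the mean cross-block correlation for an unordered pair of
  distinct networks.

The literal ``W_a`` includes the diagonal and counts each undirected link
twice; ``diagonal_policy="exclude_diagonal"`` instead averages the strictly
off-diagonal within-block entries, the conventional alternative.  The two are
related by ``W_literal = ((N_a - 1) * W_excl + 1) / N_a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

DIAGONAL_POLICIES = ("literal", "exclude_diagonal")

#: Canonical network ordering for a 10-network partition.
DEFAULT_NETWORKS = ("DMN", "SN", "FPN", "CON", "SMN", "VN", "VAN", "DAN", "AN", "SUB")


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """One subject's ``T x N`` ROI time-series matrix."""

    values: np.ndarray
    node_ids: tuple[str, ...]
    subject_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        if values.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {values.shape}")
        if values.shape[0] < 3:
            raise ValueError(
                f"subject {self.subject_id}: need at least 3 time points, got {values.shape[0]}"
            )
        if values.shape[1] != len(self.node_ids):
            raise ValueError(
                f"subject {self.subject_id}: {values.shape[1]} columns but "
                f"{len(self.node_ids)} node ids"
            )
        if not np.isfinite(values).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str | None = None) -> "TimeSeriesMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        return cls(
            values=frame.to_numpy(dtype=float),
            node_ids=tuple(frame.columns),
            subject_id=subject_id or path.stem,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=list(self.node_ids)).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of each node to exactly one named network."""

    assignment: Mapping[str, str]
    networks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assignment = {str(k): str(v) for k, v in self.assignment.items()}
        object.__setattr__(self, "assignment", assignment)
        seen: list[str] = []
        for name in assignment.values():
            if name not in seen:
                seen.append(name)
        networks = tuple(self.networks) if self.networks else tuple(seen)
        if len(set(networks)) != len(networks):
            raise ValueError("network names must be unique")
        missing = set(seen) - set(networks)
        if missing:
            raise ValueError(f"networks {sorted(missing)} present in assignment but not listed")
        empty = set(networks) - set(seen)
        if empty:
            raise ValueError(f"networks {sorted(empty)} have no nodes")
        object.__setattr__(self, "networks", networks)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.assignment.keys())

    def members(self, network: str) -> tuple[str, ...]:
        return tuple(n for n, net in self.assignment.items() if net == network)

    def sizes(self) -> dict[str, int]:
        counts: dict[str, int] = {name: 0 for name in self.networks}
        for net in self.assignment.values():
            counts[net] += 1
        return counts

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered distinct network pairs, keyed by sorted name."""
        names = self.networks
        return sorted(
            tuple(sorted((a, b))) for i, a in enumerate(names) for b in names[i + 1 :]
        )

    @classmethod
    def from_sizes(
        cls, sizes: Sequence[tuple[str, int]], node_prefix: str = "node"
    ) -> "NetworkPartition":
        assignment: dict[str, str] = {}
        idx = 0
        for name, count in sizes:
            if count <= 0:
                raise ValueError(f"network {name!r} must have a positive node count")
            for _ in range(count):
                assignment[f"{node_prefix}{idx:03d}"] = name
                idx += 1
        return cls(assignment=assignment, networks=tuple(name for name, _ in sizes))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NetworkPartition":
        frame = pd.read_csv(path)
        if not {"node_id", "network_name"} <= set(frame.columns):
            raise ValueError("partition CSV needs columns node_id, network_name")
        return cls(
            assignment=dict(
                zip(frame["node_id"].astype(str), frame["network_name"].astype(str))
            )
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"node_id": list(self.assignment), "network_name": list(self.assignment.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ``N x N`` Pearson correlation matrix with unit diagonal."""

    A: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        if A.shape != (len(self.node_ids),) * 2:
            raise ValueError("matrix shape does not match node ids")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(A).max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class ConnectivityProfile:
    """Per-subject within- and between-network connectivity values."""

    within: dict[str, float]
    between: dict[tuple[str, str], float]
    subject_id: str

    def to_series(self) -> pd.Series:
        data = {f"within:{k}": v for k, v in self.within.items()}
        data.update({f"between:{a}-{b}": v for (a, b), v in self.between.items()})
        return pd.Series(data, name=self.subject_id)


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation matrix of a subject's node time courses.

    Raises
    ------
    ValueError
        If any column is constant (its correlation is undefined), naming
        the offending node.
    """
    sd = ts.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.node_ids[i] for i in bad]
        raise ValueError(f"subject {ts.subject_id}: constant time course for nodes {names}")
    A = np.corrcoef(ts.values, rowvar=False)
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return ConnectivityMatrix(A=A, node_ids=ts.node_ids)


def _block_indices(A_nodes: Sequence[str], partition: NetworkPartition) -> dict[str, np.ndarray]:
    if set(A_nodes) != set(partition.node_ids):
        raise ValueError("connectivity matrix and partition cover different node sets")
    pos = {node: i for i, node in enumerate(A_nodes)}
    return {
        net: np.array([pos[n] for n in partition.members(net)], dtype=int)
        for net in partition.networks
    }


def within_network_connectivity(
    A: ConnectivityMatrix,
    partition: NetworkPartition,
    diagonal_policy: str = "literal",
    fisher_z: bool = False,
) -> dict[str, float]:
    """Within-network connectivity ``W_a`` for every network.

    ``literal`` sums all ordered pairs ``i, j`` inside the block — including
    the unit diagonal — and divides by ``N_a**2``.  ``exclude_diagonal``
    averages only the strictly off-diagonal entries.  ``fisher_z`` applies
    ``arctanh`` to each correlation before averaging (off-diagonal only, so
    it requires ``exclude_diagonal``).
    """
    if diagonal_policy not in DIAGONAL_POLICIES:
        raise ValueError(f"diagonal_policy must be one of {DIAGONAL_POLICIES}")
    if fisher_z and diagonal_policy == "literal":
        raise ValueError("fisher_z requires diagonal_policy='exclude_diagonal'")
    blocks = _block_indices(A.node_ids, partition)
    out: dict[str, float] = {}
    for net, idx in blocks.items():
        block = A.A[np.ix_(idx, idx)]
        n = idx.size
        if diagonal_policy == "literal":
            out[net] = float(block.sum() / n**2)
        else:
            if n == 1:
                out[net] = float("nan")
                continue
            off = block[~np.eye(n, dtype=bool)]
            if fisher_z:
                off = np.arctanh(np.clip(off, -1 + 1e-15, 1 - 1e-15))
            out[net] = float(off.mean())
    return out


def between_network_connectivity(
    A: ConnectivityMatrix,
    partition: NetworkPartition,
    fisher_z: bool = False,
) -> dict[tuple[str, str], float]:
    """Between-network connectivity ``PB_ab`` for every unordered pair."""
    blocks = _block_indices(A.node_ids, partition)
    out: dict[tuple[str, str], float] = {}
    for a, b in partition.pairs():
        cross = A.A[np.ix_(blocks[a], blocks[b])]
        if fisher_z:
            cross = np.arctanh(np.clip(cross, -1 + 1e-15, 1 - 1e-15))
        out[(a, b)] = float(cross.mean())
    return out


def connectivity_profile(
    ts: TimeSeriesMatrix,
    partition: NetworkPartition,
    diagonal_policy: str = "literal",
    fisher_z: bool = False,
) -> ConnectivityProfile:
    A = correlation_matrix(ts)
    return ConnectivityProfile(
        within=within_network_connectivity(A, partition, diagonal_policy, fisher_z),
        between=between_network_connectivity(A, partition, fisher_z),
        subject_id=ts.subject_id,
    )


def profile_cohort(
    timeseries: Iterable[TimeSeriesMatrix | str | Path],
    partition: NetworkPartition,
    diagonal_policy: str = "literal",
    fisher_z: bool = False,
) -> list[ConnectivityProfile]:
    """Profile every subject, preserving order.

    Per-subject failures are re-raised with the subject named; they are never
    silently dropped.
    """
    profiles: list[ConnectivityProfile] = []
    count = 0
    for item in timeseries:
        count += 1
        ts = item if isinstance(item, TimeSeriesMatrix) else TimeSeriesMatrix.from_tsv(item)
        try:
            profiles.append(connectivity_profile(ts, partition, diagonal_policy, fisher_z))
        except ValueError as exc:
            raise ValueError(f"subject {ts.subject_id}: {exc}") from exc
    if count == 0:
        logger.warning("profile_cohort received an empty subject list")
    return profiles


def profiles_to_frame(profiles: Sequence[ConnectivityProfile]) -> pd.DataFrame:
    """Subjects-by-measures feature matrix (55 columns for a 10-network partition)."""
    if not profiles:
        return pd.DataFrame()
    return pd.DataFrame([p.to_series() for p in profiles])


def profiles_to_tidy(profiles: Sequence[ConnectivityProfile]) -> pd.DataFrame:
    """Long-format profile table: subject_id, measure_type, network_or_pair, value."""
    rows = []
    for p in profiles:
        for net, v in p.within.items():
            rows.append((p.subject_id, "within", net, v))
        for (a, b), v in p.between.items():
            rows.append((p.subject_id, "between", f"{a}-{b}", v))
    return pd.DataFrame(rows, columns=["subject_id", "measure_type", "network_or_pair", "value"])


class ConnectivityProfiler(TransformerMixin, BaseEstimator):
    """Transformer turning subject time-series matrices into connectivity profiles.

    Parameters
    ----------
    partition : NetworkPartition
        Node-to-network assignment defining the blocks.
    diagonal_policy : {"literal", "exclude_diagonal"}
        Whether ``W_a`` includes the unit diagonal (the printed formula) or
        averages strictly off-diagonal entries.
    fisher_z : bool
        Apply Fisher's z transform to correlations before averaging.
    """

    def __init__(
        self,
        partition: NetworkPartition | None = None,
        diagonal_policy: str = "literal",
        fisher_z: bool = False,
    ):
        self.partition = partition
        self.diagonal_policy = diagonal_policy
        self.fisher_z = fisher_z

    def fit(self, X: Iterable[TimeSeriesMatrix], y=None) -> "ConnectivityProfiler":
        if self.partition is None:
            raise ValueError("ConnectivityProfiler requires a partition")
        if self.diagonal_policy not in DIAGONAL_POLICIES:
            raise ValueError(f"diagonal_policy must be one of {DIAGONAL_POLICIES}")
        self.feature_names_out_ = [f"within:{n}" for n in self.partition.networks] + [
            f"between:{a}-{b}" for a, b in self.partition.pairs()
        ]
        return self

    def transform(self, X: Iterable[TimeSeriesMatrix]) -> pd.DataFrame:
        profiles = profile_cohort(X, self.partition, self.diagonal_policy, self.fisher_z)
        frame = profiles_to_frame(profiles)
        return frame.reindex(columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
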