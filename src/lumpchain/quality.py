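"""Lumped Markov chain, persistence probabilities and partition quality.

Given a partition of the node set into q clusters, encoded by the N x q
binary collecting matrix H, the q-state lumped chain of the stationary
random walker is

    U = diag(H^T pi)^-1  H^T diag(pi) P H,

a row-stochastic matrix that shares the (collected) stationary
distribution H^T pi with the original chain.  Its diagonal entry U[c, c]
is the *persistence probability* of cluster c: the probability that a
stationary walker currently in c is still in c one step later.  A cluster
is an alpha-community when its persistence is at least alpha, and a
partition is an alpha-partition when all of its clusters are.

Explicitly,

    p_c = sum_{i in c} pi_i sum_{j in c} P[i, j]  /  sum_{i in c} pi_i,

which for undirected networks reduces to the fraction of the total
strength of the cluster that stays inside it (internal weight, counted in
both directions, over cluster strength).  For unweighted undirected
networks p_c > 1/2 is exactly Radicchi's "community in a weak sense" and
p_c = 1 - (normalized cut of c).

This module also hosts the standard comparison metrics: Newman-Girvan
modularity, LinkRank modularity (their directed random-walk
generalization, which reduces to Newman's on undirected networks), the
walker's per-cluster link fractions against the independence null, the
relative persistence, and normalized mutual information between
partitions.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .errors import ParseError, ValidationError
from .graph import Network
from .markov import TransitionModel

__all__ = [
    "Partition",
    "LumpedChain",
    "QualityReport",
    "read_partition",
    "write_partition",
    "lump",
    "persistence_probabilities",
    "persistence_undirected",
    "is_alpha_partition",
    "escape_times",
    "normalized_cut",
    "weak_community_test",
    "modularity",
    "linkrank_modularity",
    "local_link_fractions",
    "relative_persistence",
    "normalized_mutual_information",
    "quality_report",
]


class Partition:
    """Assignment of every node to exactly one of q nonempty clusters."""

    def __init__(self, node_labels: Sequence[str], assignment: Sequence[int]):
        self.node_labels = tuple(str(x) for x in node_labels)
        a = np.asarray(assignment, dtype=int)
        if a.shape != (len(self.node_labels),):
            raise ValidationError("assignment length must match node_labels")
        if a.size == 0:
            raise ValidationError("empty partition")
        if a.min() < 0:
            raise ValidationError("cluster indices must be nonnegative")
        q = int(a.max()) + 1
        present = np.bincount(a, minlength=q)
        if np.any(present == 0):
            raise ValidationError("every cluster index in 0..q-1 must be nonempty")
        self.assignment = a
        self.q = q

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def H(self) -> np.ndarray:
        """N x q binary collecting matrix."""
        H = np.zeros((self.N, self.q))
        H[np.arange(self.N), self.assignment] = 1.0
        return H

    @classmethod
    def from_clusters(
        cls, node_labels: Sequence[str], clusters: Iterable[Iterable[str]]
    ) -> "Partition":
        labels = [str(x) for x in node_labels]
        lut = {lab: i for i, lab in enumerate(labels)}
        a = np.full(len(labels), -1, dtype=int)
        for c, members in enumerate(clusters):
            for m in members:
                i = lut.get(str(m))
                if i is None:
                    raise ValidationError(f"cluster member {m!r} not in node set")
                if a[i] != -1:
                    raise ValidationError(f"node {m!r} assigned to two clusters")
                a[i] = c
        if np.any(a == -1):
            missing = [labels[i] for i in np.flatnonzero(a == -1)]
            raise ValidationError(f"nodes not assigned to any cluster: {missing}")
        return cls(labels, a)

    @classmethod
    def trivial(cls, node_labels: Sequence[str]) -> "Partition":
        return cls(node_labels, np.zeros(len(tuple(node_labels)), dtype=int))

    @classmethod
    def identity(cls, node_labels: Sequence[str]) -> "Partition":
        n = len(tuple(node_labels))
        return cls(node_labels, np.arange(n))

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.q)]
        for lab, c in zip(self.node_labels, self.assignment):
            out[c].append(lab)
        return out

    def relabel_first_appearance(self) -> "Partition":
        """Renumber clusters in order of first appearance (canonical form)."""
        mapping: dict[int, int] = {}
        new = np.empty_like(self.assignment)
        for i, c in enumerate(self.assignment):
            if c not in mapping:
                mapping[c] = len(mapping)
            new[i] = mapping[c]
        return Partition(self.node_labels, new)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.node_labels == other.node_labels and np.array_equal(
            self.relabel_first_appearance().assignment,
            other.relabel_first_appearance().assignment,
        )

    def __repr__(self) -> str:
        return f"Partition(N={self.N}, q={self.q})"


@dataclasses.dataclass(frozen=True)
class LumpedChain:
    """q-state aggregate chain: U, collected stationary vector, diag(U)."""

    U: np.ndarray
    pi_collected: np.ndarray
    persistence: np.ndarray


def read_partition(path, node_labels: Sequence[str] | None = None) -> Partition:
    """Read a two-column ``node_label cluster_id`` TSV partition file.

    When ``node_labels`` is given, the assignment is aligned to that node
    order and must cover exactly that node set.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 'node cluster'")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ParseError(f"{path}: empty partition file")
    seen: dict[str, str] = {}
    for node, cl in pairs:
        if node in seen:
            raise ValidationError(f"{path}: node {node!r} listed twice")
        seen[node] = cl
    if node_labels is None:
        node_labels = [node for node, _ in pairs]
    else:
        node_labels = [str(x) for x in node_labels]
        missing = [lab for lab in node_labels if lab not in seen]
        extra = [lab for lab in seen if lab not in set(node_labels)]
        if missing or extra:
            raise ValidationError(
                f"{path}: partition/node-set mismatch "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
    cluster_ids: dict[str, int] = {}
    a = np.empty(len(node_labels), dtype=int)
    for i, lab in enumerate(node_labels):
        cl = seen[lab]
        if cl not in cluster_ids:
            cluster_ids[cl] = len(cluster_ids)
        a[i] = cluster_ids[cl]
    return Partition(node_labels, a)


def write_partition(part: Partition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab, c in zip(part.node_labels, part.assignment):
            fh.write(f"{lab}\t{c}\n")


def _check_same_nodes(model_labels: tuple[str, ...], part: Partition) -> None:
    if tuple(part.node_labels) != tuple(model_labels):
        if set(part.node_labels) == set(model_labels):
            raise ValidationError(
                "partition node order differs from model; realign the partition"
            )
        raise ValidationError("partition and model are over different node sets")


def lump(model: TransitionModel, part: Partition) -> LumpedChain:
    """Aggregate the walker chain over the clusters of ``part``.

    Computes U = diag(H^T pi)^-1 H^T diag(pi) P H; the collected
    stationary vector H^T pi is invariant under U, and diag(U) holds the
    per-cluster persistence probabilities.
    """
    _check_same_nodes(model.node_labels, part)
    pi = model.stationary()
    H = part.H
    c = H.T @ pi
    U = (H.T * pi) @ model.P @ H / c[:, None]
    return LumpedChain(U=U, pi_collected=c, persistence=np.diag(U).copy())


def persistence_probabilities(model: TransitionModel, part: Partition) -> np.ndarray:
    """Per-cluster persistence via the explicit stationary-flow formula.

    p_c = (sum_{i in c} pi_i sum_{j in c} P[i, j]) / sum_{i in c} pi_i;
    identical to diag(U) from :func:`lump`.
    """
    _check_same_nodes(model.node_labels, part)
    pi = model.stationary()
    H = part.H
    stay = (model.P @ H)[np.arange(part.N), part.assignment]  # P(stay in own cluster)
    num = np.bincount(part.assignment, weights=pi * stay, minlength=part.q)
    den = np.bincount(part.assignment, weights=pi, minlength=part.q)
    return num / den


def persistence_undirected(net: Network, part: Partition) -> np.ndarray:
    """Strength-fraction form of persistence for undirected networks.

    p_c = (internal weight of c, both directions) / (total strength of c).
    Equal to :func:`persistence_probabilities` on the same network.
    """
    if net.directed:
        raise ValidationError("persistence_undirected requires an undirected network")
    _check_same_nodes(net.node_labels, part)
    H = part.H
    internal = np.diag(H.T @ net.weights @ H)
    strength = H.T @ net.weights.sum(axis=1)
    return internal / strength


def is_alpha_partition(
    persistence: np.ndarray, alpha: float
) -> tuple[bool, list[int]]:
    """Non-strict alpha test: every cluster's persistence >= alpha.

    Returns the verdict and the indices of clusters below alpha.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    p = np.asarray(persistence, dtype=float)
    failing = [int(i) for i in np.flatnonzero(p < alpha)]
    return len(failing) == 0, failing


def escape_times(persistence: np.ndarray) -> np.ndarray:
    """Expected escape time 1/(1-p) per cluster; inf where p = 1."""
    p = np.asarray(persistence, dtype=float)
    out = np.full_like(p, np.inf)
    mask = p < 1
    out[mask] = 1.0 / (1.0 - p[mask])
    return out


def _cluster_mask(net: Network, cluster: Iterable[str]) -> np.ndarray:
    idx = net.indices(cluster)
    mask = np.zeros(net.N, dtype=bool)
    mask[idx] = True
    return mask


def normalized_cut(net: Network, cluster: Iterable[str]) -> float:
    """Outbound weight of the cluster over its total strength (undirected).

    Satisfies persistence = 1 - ncut on undirected networks.
    """
    if net.directed:
        raise ValidationError("normalized_cut is defined for undirected networks")
    mask = _cluster_mask(net, cluster)
    W = net.weights
    cut = W[np.ix_(mask, ~mask)].sum()
    strength = W[mask, :].sum()
    return float(cut / strength)


def weak_community_test(net: Network, cluster: Iterable[str]) -> bool:
    """Radicchi weak-community test: internal strength strictly exceeds
    outbound strength; equivalent to persistence > 1/2 (undirected)."""
    if net.directed:
        raise ValidationError("weak_community_test is defined for undirected networks")
    mask = _cluster_mask(net, cluster)
    W = net.weights
    internal = W[np.ix_(mask, mask)].sum()
    outbound = W[np.ix_(mask, ~mask)].sum()
    return bool(internal > outbound)


def modularity(net: Network, part: Partition) -> float:
    """Newman-Girvan weighted modularity (undirected networks).

    Q = sum_c [ w_cc / w  -  (s_c / w)^2 ] under the symmetric-storage
    convention (w counts every undirected edge twice).
    """
    if net.directed:
        raise ValidationError(
            "modularity is defined for undirected networks; "
            "use linkrank_modularity for directed ones"
        )
    _check_same_nodes(net.node_labels, part)
    W = net.weights
    w = W.sum()
    H = part.H
    internal = np.diag(H.T @ W @ H)
    strength = H.T @ W.sum(axis=1)
    return float(np.sum(internal / w - (strength / w) ** 2))


def linkrank_modularity(model: TransitionModel, part: Partition) -> float:
    """Random-walk (LinkRank) modularity.

    Q_LR = sum_c [ sum_{i,j in c} pi_i P_ij  -  (sum_{i in c} pi_i)^2 ]:
    stationary probability mass on intra-cluster links minus its value in
    the independence null.  Reduces to Newman modularity when the network
    is undirected.
    """
    q_c, q_null, _ = local_link_fractions(model, part)
    return float(np.sum(q_c - q_null))


def local_link_fractions(
    model: TransitionModel, part: Partition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster (q_c, q_c^null, local modularity q_c - q_c^null).

    q_c is the fraction of time a stationary walker spends on links
    internal to c (so q_c = pi_collected[c] * persistence[c]); the null
    value is pi_collected[c]^2.
    """
    chain = lump(model, part)
    q_c = chain.pi_collected * chain.persistence
    q_null = chain.pi_collected**2
    return q_c, q_null, q_c - q_null


def relative_persistence(model: TransitionModel, part: Partition) -> np.ndarray:
    """Persistence minus its value under the stationary independence null.

    The null walker chooses its next cluster from the collected stationary
    distribution regardless of where it is, so the null persistence of
    cluster c is pi_collected[c].
    """
    chain = lump(model, part)
    return chain.persistence - chain.pi_collected


def normalized_mutual_information(a: Partition, b: Partition) -> float:
    """NMI between two partitions of the same node set.

    Danon normalization 2 I(a,b) / (H(a) + H(b)) with natural logarithms:
    1 for identical partitions (up to relabelling), expectation near 0 for
    independent ones.  Two trivial one-cluster partitions count as
    identical (NMI 1).
    """
    if set(a.node_labels) != set(b.node_labels):
        raise ValidationError("partitions are over different node sets")
    if a.node_labels != b.node_labels:
        lut = {lab: c for lab, c in zip(b.node_labels, b.assignment)}
        b_assign = np.array([lut[lab] for lab in a.node_labels])
    else:
        b_assign = b.assignment
    if a.q == 1 and b.q == 1:
        return 1.0
    if a.q == 1 or b.q == 1:
        return 0.0
    return float(
        normalized_mutual_info_score(
            a.assignment, b_assign, average_method="arithmetic"
        )
    )


@dataclasses.dataclass
class QualityReport:
    """Per-cluster and per-partition quality summary for one partition."""

    per_cluster: pd.DataFrame
    summary: dict

    def to_tsv(self, path) -> None:
        self.per_cluster.to_csv(path, sep="\t", index=False, float_format="%.15g")

    def to_json(self, path) -> None:
        payload = {
            "summary": self.summary,
            "clusters": self.per_cluster.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
            fh.write("\n")


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and np.isinf(x):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(x)}")


def quality_report(
    net: Network,
    part: Partition,
    alpha: float | None = None,
    model: TransitionModel | None = None,
) -> QualityReport:
    """Full quality assessment of one partition of one network.

    Persistence, escape time, link fractions, local modularity and
    relative persistence for every cluster; normalized cut and the weak
    community flag where the network is undirected; partition-level
    (LinkRank) modularity and the alpha classification when requested.
    """
    if model is None:
        model = TransitionModel.from_network(net)
    chain = lump(model, part)
    p = chain.persistence
    q_c, q_null, local_mod = local_link_fractions(model, part)
    clusters = part.clusters()
    rows: dict[str, list] = {
        "cluster": list(range(part.q)),
        "size": [len(c) for c in clusters],
        "persistence": list(p),
        "escape_time": list(escape_times(p)),
        "pi_collected": list(chain.pi_collected),
        "link_fraction": list(q_c),
        "null_link_fraction": list(q_null),
        "local_modularity": list(local_mod),
        "relative_persistence": list(p - chain.pi_collected),
    }
    if not net.directed:
        rows["normalized_cut"] = [normalized_cut(net, c) for c in clusters]
        rows["weak_community"] = [weak_community_test(net, c) for c in clusters]
    if alpha is not None:
        ok, failing = is_alpha_partition(p, alpha)
        rows["alpha_community"] = [i not in failing for i in range(part.q)]
    df = pd.DataFrame(rows)
    summary = {
        "q": part.q,
        "min_persistence": float(p.min()),
        "linkrank_modularity": linkrank_modularity(model, part),
    }
    if not net.directed:
        summary["modularity"] = modularity(net, part)
    if alpha is not None:
        summary["alpha"] = alpha
        summary["is_alpha_partition"] = bool(ok)
    return QualityReport(per_cluster=df, summary=summary)
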