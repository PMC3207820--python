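"""Partition generation by random-walk similarity and hierarchical clustering.

A fleet of walkers started at node i makes, in expectation, a known
number of visits to every node during the first T steps; averaging over
the two start nodes gives a symmetric node similarity

    s(i, j) = (1 / 2T) * sum_{t=1..T} ( [P^t]_ij + [P^t]_ji ).

Any positive affine rescaling of s (e.g. by a fleet size) produces the
same distance matrix after complement-and-normalize,

    d(i, j) = (s_max - s(i, j)) / (s_max - s_min),

so the fleet size is fixed to 1 without loss of generality.  Average
linkage on d yields a dendrogram; the walk horizon T is selected by
maximizing the cophenetic correlation coefficient — the Pearson
correlation between the input distances and the dendrogram-induced
(cophenetic) distances — over T = 1 .. T_max, preferring the smallest T
on ties.  Top-down cuts of the winning dendrogram give the nested
sequence of candidate partitions whose persistence is then diagrammed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import NumericalError, ValidationError
from .markov import TransitionModel, matrix_power_cumsum
from .quality import Partition

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "HorizonScan",
    "similarity_matrix",
    "distance_matrix",
    "hierarchical_cluster",
    "cophenetic_distances",
    "cophenetic_correlation",
    "select_horizon",
    "cut_dendrogram",
    "partition_sequence",
]

LINKAGES = ("average", "complete", "single")
T_MAX_CAP = 200


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    values: np.ndarray  # N x N symmetric, nonnegative
    horizon: int


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray  # N x N symmetric, zero diagonal, off-diag in [0, 1]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


class Dendrogram:
    """Agglomerative merge tree, wrapping a SciPy linkage matrix."""

    def __init__(self, Z: np.ndarray, node_labels: tuple[str, ...]):
        self.Z = np.asarray(Z, dtype=float)
        self.node_labels = tuple(node_labels)
        if self.Z.shape != (len(self.node_labels) - 1, 4):
            raise ValidationError("linkage matrix shape does not match leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.node_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.node_labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node = n + k
            text[node] = f"({text[a]}:{la:.12g},{text[b]}:{lb:.12g})"
            height[node] = h
        return text[2 * n - 2] + ";"


@dataclasses.dataclass(frozen=True)
class HorizonRecord:
    T: int
    rho_c: float
    dendrogram: Dendrogram


@dataclasses.dataclass(frozen=True)
class HorizonScan:
    records: list[HorizonRecord]
    selected_T: int

    @property
    def selected(self) -> HorizonRecord:
        for rec in self.records:
            if rec.T == self.selected_T:
                return rec
        raise ValidationError("selected horizon missing from scan records")

    @property
    def selected_dendrogram(self) -> Dendrogram:
        return self.selected.dendrogram

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("T\trho_c\tselected\n")
            for rec in self.records:
                fh.write(
                    f"{rec.T}\t{rec.rho_c:.15g}\t"
                    f"{int(rec.T == self.selected_T)}\n"
                )


def similarity_matrix(model: TransitionModel, T: int) -> SimilarityMatrix:
    """Symmetrized time-averaged expected visit counts over horizon T."""
    S = matrix_power_cumsum(model, T)
    sim = (S + S.T) / (2.0 * T)
    return SimilarityMatrix(values=sim, horizon=T)


def distance_matrix(sim: SimilarityMatrix) -> DistanceMatrix:
    """Complement similarities and normalize off-diagonal values to [0, 1]."""
    s = sim.values
    n = s.shape[0]
    if n < 2:
        raise ValidationError("need at least two nodes for a distance matrix")
    off = ~np.eye(n, dtype=bool)
    smax = s[off].max()
    smin = s[off].min()
    if smax == smin:
        raise ValidationError(
            "all off-diagonal similarities are equal; distances are undefined"
        )
    d = (smax - s) / (smax - smin)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    d = (d + d.T) / 2.0  # exact symmetry against round-off
    return DistanceMatrix(values=d)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering under the named linkage (deterministic)."""
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    n = dist.values.shape[0]
    Z = hierarchy.linkage(dist.condensed(), method=linkage)
    labels = tuple(str(i) for i in range(n))
    return Dendrogram(Z, labels)


def cophenetic_distances(dend: Dendrogram) -> np.ndarray:
    """Matrix of merge heights of lowest common merges (ultrametric)."""
    cond = hierarchy.cophenet(dend.Z)
    return squareform(cond, checks=False)


def cophenetic_correlation(dist: DistanceMatrix, coph: np.ndarray) -> float:
    """Pearson correlation between distances and cophenetic distances."""
    x = dist.condensed()
    y = squareform(np.asarray(coph, dtype=float), checks=False)
    if x.size < 3:
        raise ValidationError("need at least three nodes (three pairs)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NumericalError("zero variance: cophenetic correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _labelled_dendrogram(dend: Dendrogram, node_labels) -> Dendrogram:
    return Dendrogram(dend.Z, tuple(node_labels))


def select_horizon(
    model: TransitionModel,
    T_max: int | None = None,
    linkage: str = "average",
) -> HorizonScan:
    """Scan horizons T = 1..T_max and keep the cophenetic-correlation argmax.

    T_max defaults to the node count ("of the order of N"), capped at 200
    for large networks.  Ties, and horizons whose correlation is
    undefined, resolve toward the smallest valid T.
    """
    n = model.N
    if T_max is None:
        T_max = n
        if n > T_MAX_CAP:
            warnings.warn(f"horizon scan capped at T_max={T_MAX_CAP} (N={n})",
                          stacklevel=2)
            T_max = T_MAX_CAP
    if T_max < 1:
        raise ValidationError("T_max must be >= 1")
    P = model.P
    Pt = np.eye(n)
    S = np.zeros_like(P)
    records: list[HorizonRecord] = []
    for T in range(1, T_max + 1):
        Pt = Pt @ P
        S += Pt
        sim = SimilarityMatrix(values=(S + S.T) / (2.0 * T), horizon=T)
        try:
            dist = distance_matrix(sim)
            dend = _labelled_dendrogram(
                hierarchical_cluster(dist, linkage), model.node_labels
            )
            rho = cophenetic_correlation(dist, cophenetic_distances(dend))
        except (ValidationError, NumericalError):
            continue
        records.append(HorizonRecord(T=T, rho_c=rho, dendrogram=dend))
    if not records:
        raise NumericalError("no horizon produced a valid dendrogram")
    best = max(records, key=lambda r: (r.rho_c, -r.T))
    return HorizonScan(records=records, selected_T=best.T)


def cut_dendrogram(dend: Dendrogram, q: int) -> Partition:
    """Partition into exactly q clusters by undoing the last q-1 merges."""
    n = dend.n_leaves
    if not (1 <= q <= n):
        raise ValidationError(f"q must be in 1..{n}")
    labels = hierarchy.cut_tree(dend.Z, n_clusters=q).ravel()
    return Partition(dend.node_labels, labels).relabel_first_appearance()


def partition_sequence(dend: Dendrogram, q_max: int) -> list[Partition]:
    """Nested partitions for q = 1..q_max (each refines the previous)."""
    if q_max > dend.n_leaves:
        raise ValidationError("q_max exceeds the number of leaves")
    return [cut_dendrogram(dend, q) for q in range(1, q_max + 1)]
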