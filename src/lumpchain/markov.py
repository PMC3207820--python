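"""Random-walker Markov chain on a network.

The transition matrix is the row-normalized weight matrix,

    P[i, j] = w_ij / s_i^out,

so a walker at node i jumps to j with probability proportional to the
weight of the outgoing edge.  On a strongly connected network P is
irreducible and has a unique strictly positive stationary distribution
pi with pi P = pi; for undirected networks pi is the normalized node
strength vector in closed form, while for directed networks it is
computed numerically.
"""

from __future__ import annotations

import bisect
import dataclasses
import random
import warnings

import numpy as np
import networkx as nx

from .errors import NumericalError, ValidationError
from .graph import Network, strongly_connected_components

__all__ = [
    "TransitionModel",
    "transition_matrix",
    "stationary_distribution",
    "matrix_power_cumsum",
    "simulate_walk",
]

POWER_TOL = 1e-13
POWER_MAXITER = 10**6


@dataclasses.dataclass
class TransitionModel:
    """Row-stochastic transition matrix with (lazily computed) stationary pi.

    ``strengths`` keeps the out-strength vector of the source network so
    the undirected closed form ``pi_i = s_i / sum_j s_j`` stays available,
    and ``undirected`` records whether that closed form applies.
    """

    P: np.ndarray
    node_labels: tuple[str, ...]
    pi: np.ndarray | None = None
    strengths: np.ndarray | None = None
    undirected: bool = False

    @property
    def N(self) -> int:
        return self.P.shape[0]

    @classmethod
    def from_network(cls, net: Network) -> "TransitionModel":
        model = transition_matrix(net)
        model.pi = stationary_distribution(model)
        return model

    def stationary(self) -> np.ndarray:
        if self.pi is None:
            self.pi = stationary_distribution(self)
        return self.pi


def transition_matrix(net: Network) -> TransitionModel:
    """Row-normalize the weight matrix of a strongly connected network.

    Raises a validation error if the network is not strongly connected
    (analyze each component separately via ``restrict_to_component``) or
    if any node has zero out-strength.
    """
    comps = strongly_connected_components(net)
    if len(comps) != 1:
        raise ValidationError(
            f"network has {len(comps)} strongly connected components; "
            "restrict_to_component each one before analysis"
        )
    s = net.weights.sum(axis=1)
    if np.any(s <= 0):
        bad = [net.node_labels[i] for i in np.flatnonzero(s <= 0)]
        raise ValidationError(f"nodes with zero out-strength: {bad}")
    P = net.weights / s[:, None]
    if net.N > 1 and not _is_aperiodic(P):
        warnings.warn(
            "transition matrix is periodic: the stationary distribution is "
            "still unique, but the lumped chain's transient approximation "
            "does not converge exponentially",
            stacklevel=2,
        )
    return TransitionModel(
        P=P,
        node_labels=net.node_labels,
        strengths=s,
        undirected=not net.directed,
    )


def _is_aperiodic(P: np.ndarray) -> bool:
    if np.any(np.diag(P) > 0):
        return True
    G = nx.from_numpy_array(P, create_using=nx.DiGraph)
    return nx.is_aperiodic(G)


def stationary_distribution(model: TransitionModel, method: str = "auto") -> np.ndarray:
    """Unique stationary vector pi of the irreducible chain.

    method:
      * ``closed_form`` — undirected networks only: pi proportional to the
        node strengths (exact).
      * ``linear`` — solve (P^T - I) pi = 0 with the normalization
        sum(pi) = 1 replacing one equation.
      * ``power`` — left power iteration to max-abs residual 1e-13.
      * ``auto`` — closed form when available, else linear with a power
        fallback.
    """
    if method not in ("auto", "closed_form", "power", "linear"):
        raise ValidationError(f"unknown stationary method {method!r}")
    if method == "closed_form" or (method == "auto" and model.undirected):
        if not model.undirected or model.strengths is None:
            raise ValidationError("closed form requires an undirected source network")
        s = model.strengths
        return s / s.sum()
    if method == "power":
        return _power_iteration(model.P)
    pi = _linear_solve(model.P)
    if pi is None:
        if method == "linear":
            raise NumericalError("linear solve for the stationary vector failed")
        pi = _power_iteration(model.P)
    return pi


def _linear_solve(P: np.ndarray) -> np.ndarray | None:
    n = P.shape[0]
    A = P.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    if np.any(pi <= 0) or not np.all(np.isfinite(pi)):
        return None
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ P - pi)) > 1e-10:
        return None
    return pi


def _power_iteration(P: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(POWER_MAXITER):
        w = v @ P
        w /= w.sum()
        resid = np.max(np.abs(w - v))
        v = w
        if resid < POWER_TOL:
            return v
    resid = float(np.max(np.abs(v @ P - v)))
    raise NumericalError(
        f"power iteration did not converge within {POWER_MAXITER} iterations "
        f"(residual {resid:.3e})"
    )


def matrix_power_cumsum(model: TransitionModel, T: int) -> np.ndarray:
    """Cumulative sum of transition-matrix powers, sum_{t=1..T} P^t.

    Entry (i, j) is the expected number of visits to j during steps 1..T
    of a walk started at i; every row sums to T.
    """
    if T < 1:
        raise ValidationError("horizon T must be >= 1")
    P = model.P
    Pt = P.copy()
    S = P.copy()
    for _ in range(T - 1):
        Pt = Pt @ P
        S += Pt
    return S


def simulate_walk(model: TransitionModel, start, steps: int, seed: int) -> np.ndarray:
    """Monte-Carlo trajectory of the chain (testing oracle).

    Returns the node indices visited at steps 1..steps from ``start``
    (a label or an index); deterministic for a fixed seed.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    if isinstance(start, str):
        start = model.node_labels.index(start)
    rng = random.Random(seed)
    cum = np.cumsum(model.P, axis=1)
    cum[:, -1] = 1.0  # guard against round-off at the right edge
    rows = [row.tolist() for row in cum]
    out = np.empty(steps, dtype=np.int64)
    cur = int(start)
    rnd = rng.random
    bis = bisect.bisect_left
    for t in range(steps):
        cur = bis(rows[cur], rnd())
        out[t] = cur
    return out
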