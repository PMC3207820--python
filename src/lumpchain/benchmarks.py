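"""Seeded generators of planted-community benchmark graphs.

Everything the detection pipeline is tested on is generated here, with
three levels of realism:

* :func:`planted_partition_graph` — equal-size blocks with independent
  Bernoulli edges inside (p_in) and between (p_out) blocks; the simplest
  planted model and the workhorse of the recovery tests.
* :func:`lfr_like_graph` — heterogeneous benchmark in the LFR spirit:
  node degrees and community sizes drawn from truncated power laws, and
  each node wiring a fraction mu of its edges outside its own community
  through configuration-model stub matching.  mu is the *mixing
  parameter*: at low mu communities are strong (persistence near 1 - mu),
  at high mu the planted structure dissolves.
* :func:`toy_three_cluster` and :func:`erdos_renyi` — a hand-checkable
  three-clique toy and a null model with no community structure.

All generators are deterministic given their seed.  Because the
random-walk analysis requires strong connectivity, a generated graph
that comes out disconnected is resampled a bounded number of times and,
as a last resort, repaired by adding single edges along a random cycle
through the components; repair edges are recorded in the provenance.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .errors import ValidationError
from .graph import Network, strongly_connected_components
from .quality import Partition

__all__ = [
    "BenchmarkSpec",
    "PlantedGraph",
    "planted_partition_graph",
    "lfr_like_graph",
    "toy_three_cluster",
    "erdos_renyi",
]

MAX_RESAMPLE = 20


@dataclasses.dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the heterogeneous (LFR-like) benchmark generator."""

    N: int = 300
    avg_degree: float = 10.0
    max_degree: int = 30
    degree_exponent: float = 2.5
    community_size_exponent: float = 1.5
    mixing: float = 0.2
    min_community: int = 20
    max_community: int = 60
    directed: bool = False
    weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mixing < 1):
            raise ValidationError("mixing must lie in [0, 1)")
        if self.degree_exponent <= 1 or self.community_size_exponent <= 1:
            raise ValidationError("power-law exponents must exceed 1")
        if not (1 <= self.min_community <= self.max_community <= self.N):
            raise ValidationError("community size bounds cannot tile N")
        if self.avg_degree >= self.max_degree:
            raise ValidationError("avg_degree must be below max_degree")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BenchmarkSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclasses.dataclass(frozen=True)
class PlantedGraph:
    """A generated network with its planted partition and realized mixing."""

    network: Network
    planted_partition: Partition
    realized_mixing: np.ndarray  # per node: fraction of strength outside
    provenance: dict


def _labels(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


def _realized_mixing(W: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    same = assignment[:, None] == assignment[None, :]
    external = (W * ~same).sum(axis=1)
    total = W.sum(axis=1)
    if not np.array_equal(W, W.T):
        external = external + (W * ~same).sum(axis=0)
        total = total + W.sum(axis=0)
    return np.where(total > 0, external / total, 0.0)


def _repair_connectivity(
    W: np.ndarray, directed: bool, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Add unit edges along a random cycle through the components (in place)."""
    A = W if directed else np.maximum(W, W.T)
    comps = strongly_connected_components(
        Network(_labels(W.shape[0]), np.where(A > 0, 1.0, 0.0),
                directed if directed else False)
    )
    if len(comps) == 1:
        return []
    reps = []
    for comp in comps:
        members = sorted(int(lab[1:]) for lab in comp)
        reps.append(int(rng.choice(members)))
    order = rng.permutation(len(reps))
    added = []
    for k in range(len(reps)):
        a = reps[order[k]]
        b = reps[order[(k + 1) % len(reps)]]
        W[a, b] = max(W[a, b], 1.0)
        if not directed:
            W[b, a] = W[a, b]
        added.append((a, b))
    return added


def planted_partition_graph(
    N: int, K: int, p_in: float, p_out: float, seed: int
) -> PlantedGraph:
    """Equal-block planted-partition (stochastic block model) graph.

    Undirected, unweighted; intra-block pairs are edges with probability
    p_in, inter-block pairs with probability p_out (p_in > p_out
    required).  Connectivity is enforced by bounded resampling with a
    final spanning-cycle repair.
    """
    if N % K != 0:
        raise ValidationError("N must be divisible by K (equal block sizes)")
    if not (p_in > p_out >= 0) or p_in > 1:
        raise ValidationError("need 1 >= p_in > p_out >= 0")
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(K), N // K)
    prov: dict = {"generator": "planted_partition", "N": N, "K": K,
                  "p_in": p_in, "p_out": p_out, "seed": seed}
    for attempt in range(MAX_RESAMPLE):
        same = assignment[:, None] == assignment[None, :]
        probs = np.where(same, p_in, p_out)
        upper = np.triu(rng.random((N, N)) < probs, k=1)
        W = (upper | upper.T).astype(float)
        net = Network(_labels(N), W, directed=False)
        if len(strongly_connected_components(net)) == 1:
            prov["resamples"] = attempt
            prov["repair_edges"] = []
            break
    else:
        added = _repair_connectivity(W, False, rng)
        prov["resamples"] = MAX_RESAMPLE
        prov["repair_edges"] = added
        net = Network(_labels(N), W, directed=False)
        if len(strongly_connected_components(net)) != 1:
            raise ValidationError(
                "could not generate a connected planted-partition graph; "
                "increase p_in/p_out or N"
            )
    part = Partition(net.node_labels, assignment)
    return PlantedGraph(net, part, _realized_mixing(W, assignment), prov)


# ---------------------------------------------------------------------------
# truncated power laws


def _powerlaw_sample(
    rng: np.random.Generator, gamma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Continuous truncated power law x^-gamma on [lo, hi] (inverse CDF)."""
    u = rng.random(size)
    a = 1.0 - gamma
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def _powerlaw_mean(gamma: float, lo: float, hi: float) -> float:
    a = 1.0 - gamma
    b = 2.0 - gamma
    num = (hi**b - lo**b) / b if abs(b) > 1e-12 else math.log(hi / lo)
    den = (hi**a - lo**a) / a if abs(a) > 1e-12 else math.log(hi / lo)
    return num / den


def _solve_kmin(avg: float, gamma: float, kmax: float) -> float:
    lo, hi = 1.0, float(kmax)
    if _powerlaw_mean(gamma, lo, kmax) > avg:
        raise ValidationError(
            "avg_degree is unreachable: the power law's mean exceeds it even "
            "with minimum degree 1; lower avg_degree or raise the exponent"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _powerlaw_mean(gamma, mid, kmax) < avg:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_degrees(rng, spec: BenchmarkSpec) -> np.ndarray:
    kmin = _solve_kmin(spec.avg_degree, spec.degree_exponent, spec.max_degree)
    k = _powerlaw_sample(rng, spec.degree_exponent, kmin, spec.max_degree, spec.N)
    k = np.clip(np.rint(k).astype(int), 1, spec.max_degree)
    return k


def _sample_community_sizes(rng, spec: BenchmarkSpec) -> list[int]:
    """Power-law community sizes adjusted to tile N exactly within bounds."""
    lo, hi = spec.min_community, spec.max_community
    for _ in range(1000):
        sizes: list[int] = []
        while sum(sizes) < spec.N:
            s = int(np.rint(_powerlaw_sample(
                rng, spec.community_size_exponent, lo, hi, 1)[0]))
            sizes.append(int(np.clip(s, lo, hi)))
        overflow = sum(sizes) - spec.N
        slack = sum(s - lo for s in sizes)
        if slack < overflow:
            continue
        order = np.argsort(sizes)[::-1]
        for idx in order:
            take = min(overflow, sizes[idx] - lo)
            sizes[idx] -= take
            overflow -= take
            if overflow == 0:
                break
        if overflow == 0:
            return sizes
    raise ValidationError("community sizes cannot tile N within the bounds")


# ---------------------------------------------------------------------------
# stub matching


def _pair_stubs(
    stubs_a: np.ndarray,
    stubs_b: np.ndarray | None,
    rng: np.random.Generator,
    group: np.ndarray | None,
    forbid_same_group: bool,
    existing: set[tuple[int, int]],
    directed: bool,
) -> list[tuple[int, int]]:
    """Pair stubs into edges, rejecting self-loops, multi-edges and (when
    requested) same-group pairs by bounded random partner swaps.

    ``stubs_b`` is None for undirected matching (pairs within one list);
    otherwise out-stubs in ``stubs_a`` are matched to in-stubs in
    ``stubs_b``.  Irreparable conflicts are dropped (the caller records
    them); dropping more than 5% of the intended edges raises.
    """
    if stubs_b is None:
        arr = rng.permutation(stubs_a)
        if len(arr) % 2 == 1:
            arr = arr[:-1]
        pairs = [(int(arr[2 * i]), int(arr[2 * i + 1])) for i in range(len(arr) // 2)]
    else:
        a = rng.permutation(stubs_a)
        b = rng.permutation(stubs_b)
        m = min(len(a), len(b))
        pairs = [(int(a[i]), int(b[i])) for i in range(m)]

    def key(p: tuple[int, int]) -> tuple[int, int]:
        return p if directed else (min(p), max(p))

    def conflicts(p: tuple[int, int], seen: set) -> bool:
        if p[0] == p[1]:
            return True
        if forbid_same_group and group is not None and group[p[0]] == group[p[1]]:
            return True
        return key(p) in seen

    budget = 200 * max(1, len(pairs))
    for _ in range(1000):
        seen = set(existing)
        bad: list[int] = []
        for i, p in enumerate(pairs):
            if conflicts(p, seen):
                bad.append(i)
            else:
                seen.add(key(p))
        if not bad or budget <= 0:
            break
        for i in bad:
            j = int(rng.integers(len(pairs)))
            budget -= 1
            pi, pj = pairs[i], pairs[j]
            cand_i, cand_j = (pi[0], pj[1]), (pj[0], pi[1])
            pairs[i], pairs[j] = cand_i, cand_j
    # drop whatever is still conflicting
    seen = set(existing)
    kept: list[tuple[int, int]] = []
    dropped = 0
    for p in pairs:
        if conflicts(p, seen):
            dropped += 1
            continue
        seen.add(key(p))
        kept.append(p)
    if dropped == 0:
        return kept
    # randomized matching left conflicts: realize the full stub sequence
    # greedily (Havel-Hakimi style), which handles extreme sequences such
    # as a node that must link to every other member of its community
    kept, dropped_stubs = _greedy_match(
        stubs_a, stubs_b, rng, group, forbid_same_group, existing, directed
    )
    intended = len(pairs)
    if intended and dropped_stubs / 2 > 0.05 * intended:
        raise ValidationError(
            "stub matching infeasible (too many irreparable conflicts); "
            "lower the mixing or the maximum degree relative to community size"
        )
    return kept


def _greedy_match(
    stubs_a, stubs_b, rng, group, forbid_same_group, existing, directed
) -> tuple[list[tuple[int, int]], int]:
    """Greedy largest-first realization of a stub sequence.

    Repeatedly takes the node with the most remaining (out-)stubs and
    connects it to the admissible partners with the most remaining
    (in-)stubs, randomized among ties through a pre-shuffled node order.
    Returns the edges and the number of stubs left unplaced.
    """
    shared = stubs_b is None  # undirected: one stub pool
    n = int(max(np.max(stubs_a), 0 if shared else np.max(stubs_b))) + 1
    out_count = np.bincount(stubs_a, minlength=n).astype(int)
    in_count = out_count if shared else np.bincount(stubs_b, minlength=n).astype(int)
    jitter = rng.random(n)  # random tie-break, fixed per call

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if directed else (min(a, b), max(a, b))

    seen = set(existing)
    edges: list[tuple[int, int]] = []
    while True:
        active = np.flatnonzero(out_count > 0)
        if active.size == 0:
            break
        u = int(active[np.lexsort((jitter[active], -out_count[active]))[0]])
        need = int(out_count[u])
        cand = np.flatnonzero(in_count > 0)
        cand = cand[cand != u]
        if forbid_same_group and group is not None:
            cand = cand[group[cand] != group[u]]
        cand = np.array([v for v in cand if key(u, int(v)) not in seen], dtype=int)
        if cand.size == 0:
            out_count[u] = 0  # drop u's remaining stubs
            continue
        order = cand[np.lexsort((jitter[cand], -in_count[cand]))]
        take = order[:need]
        placed = len(take)
        out_count[u] -= placed  # before partner updates: u may be a partner
        for v in take:
            v = int(v)
            edges.append((u, v))
            seen.add(key(u, v))
            in_count[v] -= 1
        if out_count[u] > 0:
            out_count[u] = 0  # partners exhausted; drop the remainder
    dropped = int(out_count.sum() + (0 if shared else int(in_count.sum())))
    return edges, dropped


def lfr_like_graph(spec: BenchmarkSpec) -> PlantedGraph:
    """Heterogeneous planted benchmark with power-law degrees and sizes.

    Each node of degree k wires round((1 - mu) k) stubs inside its own
    community and the rest outside, via configuration-model matching; the
    directed variant matches out-stubs to in-stubs, and the weighted
    variant draws geometric edge weights with the external weights
    rescaled so the aggregate strength mixing matches mu.
    """
    rng = np.random.default_rng(spec.seed)
    N, mu = spec.N, spec.mixing
    degrees = _sample_degrees(rng, spec)
    sizes = _sample_community_sizes(rng, spec)
    K = len(sizes)

    # assign nodes to communities, largest internal degrees to the largest
    # communities so that every node fits (internal degree <= size - 1)
    assignment = np.full(N, -1, dtype=int)
    k_int = np.rint((1.0 - mu) * degrees).astype(int)
    k_int = np.minimum(k_int, degrees)
    order = rng.permutation(N)
    capacity = list(sizes)
    comm_order = np.argsort(sizes)[::-1]
    for i in order:
        placed = False
        choices = rng.permutation(K)
        for c in choices:
            if capacity[c] > 0 and k_int[i] <= sizes[c] - 1:
                assignment[i] = c
                capacity[c] -= 1
                placed = True
                break
        if not placed:
            for c in comm_order:
                if capacity[c] > 0:
                    assignment[i] = c
                    capacity[c] -= 1
                    k_int[i] = min(k_int[i], sizes[c] - 1)
                    placed = True
                    break
        if not placed:
            raise ValidationError("internal degrees incompatible with community sizes")

    k_ext = degrees - k_int
    prov: dict = {
        "generator": "lfr_like",
        "spec": dataclasses.asdict(spec),
        "K": K,
        "community_sizes": sizes,
    }

    W = np.zeros((N, N))
    existing: set[tuple[int, int]] = set()
    if not spec.directed:
        # internal matching, one community at a time
        for c in range(K):
            members = np.flatnonzero(assignment == c)
            stubs = np.repeat(members, k_int[members])
            for a, b in _pair_stubs(stubs, None, rng, None, False, existing, False):
                existing.add((min(a, b), max(a, b)))
                W[a, b] = W[b, a] = 1.0
        stubs = np.repeat(np.arange(N), k_ext)
        for a, b in _pair_stubs(stubs, None, rng, assignment, True, existing, False):
            existing.add((min(a, b), max(a, b)))
            W[a, b] = W[b, a] = 1.0
    else:
        # in-degrees: permute the degree multiset within each community so
        # internal in- and out-stub totals match by construction
        k_in = np.empty(N, dtype=int)
        for c in range(K):
            members = np.flatnonzero(assignment == c)
            k_in[members] = rng.permutation(degrees[members])
        kin_int = np.rint((1.0 - mu) * k_in).astype(int)
        kin_int = np.minimum(kin_int, k_in)
        kin_ext = k_in - kin_int
        for c in range(K):
            members = np.flatnonzero(assignment == c)
            out_stubs = np.repeat(members, k_int[members])
            in_stubs = np.repeat(members, kin_int[members])
            for a, b in _pair_stubs(out_stubs, in_stubs, rng, None, False,
                                    existing, True):
                existing.add((a, b))
                W[a, b] = 1.0
        out_stubs = np.repeat(np.arange(N), k_ext)
        in_stubs = np.repeat(np.arange(N), kin_ext)
        for a, b in _pair_stubs(out_stubs, in_stubs, rng, assignment, True,
                                existing, True):
            existing.add((a, b))
            W[a, b] = 1.0

    if spec.weighted:
        _apply_weights(W, assignment, mu, spec.directed, rng)

    added = _repair_connectivity(W, spec.directed, rng)
    prov["repair_edges"] = added
    net = Network(_labels(N), W if spec.directed else (W + W.T) / 2.0, spec.directed)
    if len(strongly_connected_components(net)) != 1:
        raise ValidationError("benchmark graph could not be made strongly connected")
    part = Partition(net.node_labels, assignment)
    return PlantedGraph(net, part, _realized_mixing(net.weights, assignment), prov)


def _apply_weights(
    W: np.ndarray, assignment: np.ndarray, mu: float,
    directed: bool, rng: np.random.Generator,
) -> None:
    """Geometric edge weights; external weights rescaled so the aggregate
    external-strength fraction equals the mixing parameter (in place)."""
    nz = np.argwhere(W > 0)
    for i, j in nz:
        if not directed and i > j:
            continue
        w = float(rng.geometric(1.0 / 3.0))
        W[i, j] = w
        if not directed:
            W[j, i] = w
    same = assignment[:, None] == assignment[None, :]
    internal = (W * same).sum()
    external = (W * ~same).sum()
    if external > 0 and mu > 0:
        scale = mu * internal / ((1.0 - mu) * external)
        W[~same] *= scale


def toy_three_cluster(clique_size: int = 5) -> PlantedGraph:
    """Three cliques joined pairwise by single bridge edges.

    Each clique is a planted community with persistence
    m(m-1) / (m(m-1) + 2) for clique size m (two bridge endpoints per
    clique); for m = 5 that is 20/22 = 10/11.
    """
    m = int(clique_size)
    if m < 3:
        raise ValidationError("clique_size must be >= 3")
    N = 3 * m
    W = np.zeros((N, N))
    for c in range(3):
        lo = c * m
        block = np.ones((m, m)) - np.eye(m)
        W[lo:lo + m, lo:lo + m] = block
    # pairwise bridges, distinct endpoints inside each clique
    bridges = [(0, m), (m + 1, 2 * m), (2 * m + 1, 1)]
    for a, b in bridges:
        W[a, b] = W[b, a] = 1.0
    net = Network(_labels(N), W, directed=False)
    part = Partition(net.node_labels, np.repeat(np.arange(3), m))
    prov = {"generator": "toy_three_cluster", "clique_size": m}
    return PlantedGraph(net, part, _realized_mixing(W, part.assignment), prov)


def erdos_renyi(N: int, p: float, seed: int) -> Network:
    """Undirected G(N, p) null graph, connectivity enforced as elsewhere."""
    if not (0 < p <= 1):
        raise ValidationError("p must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    for attempt in range(MAX_RESAMPLE):
        upper = np.triu(rng.random((N, N)) < p, k=1)
        W = (upper | upper.T).astype(float)
        net = Network(_labels(N), W, directed=False)
        if len(strongly_connected_components(net)) == 1:
            return net
    _repair_connectivity(W, False, rng)
    net = Network(_labels(N), W, directed=False)
    if len(strongly_connected_components(net)) != 1:
        raise ValidationError("could not generate a connected G(N, p) graph")
    return net
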