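# Methods

## Model

`lumpchain` analyzes a strongly connected network with nonnegative
weight matrix `W` through the discrete-time random walker
`P = diag(s^out)⁻¹ W`. Undirected networks are stored symmetrically (an
undirected edge contributes its weight to both ordered entries), which
makes the walker's stationary distribution the normalized strength
vector `π_i = s_i / Σ_j s_j` in closed form; for directed networks `π`
is computed numerically. Strong connectivity is a hard precondition:
disconnected inputs are rejected, and each strongly connected component
must be analyzed separately (the CLI offers `--largest-scc`).

Given a partition with collecting matrix `H`, the lumped chain
`U = diag(Hᵀπ)⁻¹ Hᵀ diag(π) P H` is row stochastic and leaves `Hᵀπ`
invariant. Its diagonal entries are the persistence probabilities; they
simultaneously equal the explicit stationary-flow formula and, on
undirected networks, the internal-strength fraction of each cluster.
These identities, together with `p = 1 − ncut`, the weak-community
equivalence `p > 1/2`, the equality of LinkRank and Newman modularity
on undirected networks, and the trace identity between the clustered
one-step autocovariance and LinkRank modularity, are enforced by the
test suite at 1e−12 (1e−10 for stationarity residuals).

Conventions worth knowing:

* α-comparisons are non-strict (`p ≥ α`); the weak-community test is
  strict (internal strength must *exceed* outbound strength).
* Self-loops are allowed and count toward persistence — a self-loop
  keeps the walker in its cluster.
* Cluster-internal weight sums over all ordered pairs inside the
  cluster, so the undirected strength form is an exact algebraic
  identity with the stationary-flow form.
* *Relative persistence* is the difference `p_c − (Hᵀπ)_c` (absolute
  persistence minus its value under the stationary independence null).
  The difference form, rather than a ratio, was chosen because it ties
  algebraically to the local modularity:
  `(Hᵀπ)_c · (p_c − (Hᵀπ)_c) = q_c − q_c^null`.
* NMI uses natural logarithms and the Danon normalization
  `2I/(H_a + H_b)`; two one-cluster partitions count as identical
  (NMI 1) to avoid 0/0.

## Stationary solver

`auto` uses the undirected closed form when available, otherwise a
dense linear solve of `(Pᵀ − I)π = 0` with the normalization `Σπ = 1`
replacing one equation, falling back to left power iteration (max-abs
residual tolerance 1e−13, cap 10⁶ iterations). Periodic irreducible
chains still have a unique `π` and all stationarity-based quantities
remain well defined; a warning notes that only the *transient*
approximation quality of the lumped chain (its exponential convergence)
is lost. Matrices are dense throughout: the intended scale is desk-size
networks (up to a few thousand nodes), where dense BLAS is both faster
and simpler than sparse bookkeeping.

## Partition generation

The node similarity is the symmetrized time-averaged expected visit
count `s(i,j) = (1/2T) Σ_{t=1..T}([Pᵗ]_ij + [Pᵗ]_ji)` of a fleet of
walkers; the fleet size is fixed to 1 because any positive affine
rescaling of the similarity yields the identical distance matrix
`d = (s_max − s)/(s_max − s_min)` (a property test asserts this at
1e−12, and at 1e−9 under hypothesis-generated scalings). Hierarchical
clustering uses average linkage by default (complete and single are
selectable): average linkage is the standard companion of cophenetic
validation, and the linkage is guaranteed monotone, so top-down cuts
are unambiguous. Cuts are defined by merge count (undoing the last
q−1 merges), not by height thresholds, so tied heights cannot produce
ambiguous partitions. Agglomeration runs on SciPy's deterministic
implementation; a brute-force O(N³) average-linkage reference with
lowest-index tie-breaking reproduces its merge heights on random
(tie-free) inputs.

The horizon scan evaluates T = 1..T_max (default T_max = N, "of the
order of" the node count, capped at 200 with a warning for larger
networks) and keeps the T maximizing the cophenetic correlation
coefficient — the Pearson correlation between input distances and
dendrogram-induced cophenetic distances — with ties resolved toward
the smallest T. Horizons whose distance matrix or correlation is
degenerate (constant similarities, zero variance) are skipped.

## Selection rules

The persistence diagram records `diag(U)` for the nested partition
sequence q = 1..q_max (default q_max = min(N, 30); the diagram's
interesting structure lives at small q, and the full minimum-persistence
curve is always reported so an analyst can fix α a posteriori).
*Finest-α* selection returns the largest scanned q whose minimum
persistence is ≥ α; the trivial partition always qualifies, so a result
always exists. *Drop* selection returns the q ≥ 2 maximizing
`min_p(q) − min_p(q+1)`, ties toward smaller q; the q = 1→2 step is
excluded because persistence 1 at q = 1 holds by construction and would
otherwise dominate. A flat curve triggers a warning that no structure
was found.

## Synthetic benchmarks

The generators define the conditions under which the pipeline is
validated; all are deterministic given their seed.

* **Planted partition**: equal blocks, Bernoulli edges with p_in
  inside and p_out between. Recovery experiments use N = 128, K = 4,
  p_in = 0.3, p_out = 0.02: expected internal degree ≈ 9.3 against ≈
  1.9 external, giving planted persistence ≈ 0.83 — strong but not
  trivial structure, comparable to a low-mixing benchmark regime.
* **LFR-like**: degrees from a truncated power law (default exponent
  2.5, mean 10, cap 30; the lower cutoff is solved numerically to hit
  the mean), community sizes from a truncated power law (exponent 1.5,
  bounds 20–60, adjusted to tile N = 300 exactly), and per-node stub
  splitting with mixing parameter μ: round((1−μ)k) stubs inside the
  community, the rest outside, matched configuration-model style.
  Random matching with bounded pair-swap repair removes self-loops,
  multi-edges and (for external stubs) same-community pairs; when the
  randomized matching cannot finish — e.g. a node whose internal degree
  forces edges to *every* other member — a greedy largest-first
  realization takes over, and at most 5% of intended edges may be
  dropped before the generator raises. The default minimum community
  size of 20 keeps internal degree sequences graphical at mean degree
  10; at smaller sizes the internal subgraphs approach completeness and
  no simple graph realizes them. The directed variant permutes the
  degree multiset within each community to obtain in-degrees, so
  internal in/out stub totals match by construction; the weighted
  variant draws geometric edge weights and rescales the external ones
  by a single factor so the aggregate strength mixing equals μ.
* **Toy three-cluster**: three m-cliques joined pairwise by single
  bridges; each clique has persistence m(m−1)/(m(m−1)+2), hand-checkable.
* **Erdős–Rényi**: the no-structure null.

Graphs that come out disconnected are resampled (bounded retries) and,
as a last resort, repaired by unit edges along a random cycle through
the components; repair edges are recorded in the provenance. What the
generators do *not* emulate: degree–degree correlations, clustering
coefficients beyond what the planted blocks induce, overlapping or
hierarchical communities, and real-world weight distributions. Passing
recovery tests therefore demonstrates correctness of the method on
networks whose only structure is the planted partition, not performance
on arbitrary empirical networks.

## Problem sizes and verification scale

The test suite verifies the undirected equivalences exhaustively over
every cluster of every connected unweighted graph with N ≤ 6
(vectorized over all ~27k six-node graphs), the lumping identities on
hundreds of random digraphs up to N = 50, Monte-Carlo consistency with
10⁶-step walks on ten random graph/partition pairs (3 binomial standard
errors), and full-pipeline recovery on ten 128-node planted graphs.
`scripts/acceptance.py` re-runs the recovery and mixing-regime
experiments at the same sizes. These scales were chosen as the smallest
at which the statistical claims are sharp; all quantities are
dimensionless probabilities or scores.

## Known limitations

* Dense linear algebra bounds practical use to a few thousand nodes.
* The heuristic search space is a single nested dendrogram sequence;
  the globally finest α-partition over *all* partitions is not sought
  (the underlying optimization is intractable), so the reported
  partition is optimal only within the generated sequence.
* Persistence is a one-step quantity; long-range or multi-scale
  structure is visible only through the horizon scan, not the score.
* Overlapping communities and time-varying networks are out of scope.
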