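# lumpchain

Community analysis in directed, weighted networks via **lumped Markov
chains** and **persistence probabilities**.

Most community-detection tools return a partition but say little about
how good each individual cluster is. `lumpchain` attaches a sharp,
dynamically meaningful quality score to every candidate community of a
network — biological, social, economic or otherwise — and builds a full
detection pipeline on top of it. It is aimed at network analysts (e.g.
in systems biology, where modules of metabolic, neural or interaction
networks need individual quality assessment) who want to *test*
partitions they already have as much as to *find* new ones.

## The model

A random walker on a strongly connected network with weight matrix
`W` moves with transition probabilities `P_ij = w_ij / s_i^out`
(row-normalized weights) and has a unique stationary distribution `π`
(`πP = π`, `π > 0`). Given a partition of the `N` nodes into `q`
clusters, encoded by the binary collecting matrix `H` (N×q), the
**lumped Markov chain** is the q-state aggregate

```
U = diag(Hᵀπ)⁻¹ · Hᵀ · diag(π) · P · H ,
```

a row-stochastic matrix that exactly describes the walker at cluster
scale when started at stationarity, and shares its stationary
distribution (`Hᵀπ`) with the original chain.

The diagonal entry `u_cc` is the **persistence probability** of cluster
`c`: the probability that a stationary walker currently in `c` is still
in `c` one step later. Explicitly

```
p_c = Σ_{i∈c} π_i Σ_{j∈c} P_ij  /  Σ_{i∈c} π_i ,
```

with expected escape time `1/(1 − p_c)`. A cluster is an
**α-community** if `p_c ≥ α`, and a partition is an **α-partition** if
all its clusters are. For undirected networks `p_c` is simply the
fraction of the cluster's strength that stays internal, so
`p_c = 1 − ncut(c)` and, for unweighted networks, `p_c > 1/2` is
exactly Radicchi's "community in a weak sense".

Detection works by (1) a random-walk node similarity
`s(i,j) = (1/2T) Σ_{t≤T} ([Pᵗ]_ij + [Pᵗ]_ji)`, (2) complement-and-
normalize into distances, (3) average-linkage hierarchical clustering,
with the horizon `T` selected by maximizing the cophenetic correlation
coefficient, and (4) scoring the nested partition sequence in a
*persistence probabilities' diagram*. The finest α-partition, or the
largest sudden drop of the minimum persistence, selects the answer.

## Worked example

```python
import numpy as np
from lumpchain import (Network, Partition, TransitionModel,
                       lump, modularity, detect_communities, toy_three_cluster)

# two unit triangles joined by one edge ("barbell")
W = np.zeros((6, 6))
for tri in ((0, 1, 2), (3, 4, 5)):
    for i in tri:
        for j in tri:
            if i != j:
                W[i, j] = 1.0
W[2, 3] = W[3, 2] = 1.0
net = Network(tuple("abcdef"), W, directed=False)
part = Partition.from_clusters(net.node_labels, [list("abc"), list("def")])

model = TransitionModel.from_network(net)
chain = lump(model, part)
print(chain.persistence)            # [0.85714286 0.85714286]
print(modularity(net, part))        # 0.3571428571428571

# full pipeline on three 5-cliques joined by single bridges
pg = toy_three_cluster(5)
result, diagram, scan = detect_communities(pg.network, alpha=0.5)
print(result.q, scan.selected_T)    # 3 5
print(result.persistence)           # [0.90909091 0.90909091 0.90909091]
```

Each triangle keeps 6 of its 7 strength units internal, hence
persistence 6/7 ≈ 0.857 — both clusters are α-communities for any
α ≤ 6/7 — and the two-triangle split has modularity 5/14. On the
three-clique toy graph the pipeline selects the walk horizon T = 5 by
cophenetic correlation and recovers the three cliques, each with
persistence 10/11 ≈ 0.909.

The same analyses run from the shell:

```sh
lumpchain test graph.edgelist partition.tsv --alpha 0.5
lumpchain detect graph.edgelist --alpha 0.5 --out-dir results/
lumpchain benchmark spec.json --out-dir bench/
lumpchain compare planted.tsv detected.tsv
```

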