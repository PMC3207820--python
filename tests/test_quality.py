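"""Lumped chain, persistence probabilities, alpha tests and quality metrics."""

import itertools
import json

import numpy as np
import pytest

from lumpchain import (
    Network,
    Partition,
    TransitionModel,
    escape_times,
    is_alpha_partition,
    linkrank_modularity,
    local_link_fractions,
    lump,
    modularity,
    normalized_cut,
    normalized_mutual_information,
    persistence_probabilities,
    persistence_undirected,
    quality_report,
    read_partition,
    relative_persistence,
    simulate_walk,
    weak_community_test,
    write_partition,
)
from lumpchain.errors import ValidationError

from conftest import (
    random_connected_undirected,
    random_partition,
    random_strongly_connected_digraph,
)


class TestPartition:
    def test_rows_of_H_sum_to_one(self):
        part = Partition(("a", "b", "c"), [0, 1, 0])
        np.testing.assert_array_equal(part.H.sum(axis=1), 1.0)
        assert part.q == 2

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            Partition(("a", "b"), [0, 2])

    def test_from_clusters_requires_cover(self):
        with pytest.raises(ValidationError, match="not assigned"):
            Partition.from_clusters(("a", "b", "c"), [["a", "b"]])

    def test_file_roundtrip(self, tmp_path):
        part = Partition(("x", "y", "z"), [1, 0, 1])
        path = tmp_path / "p.tsv"
        write_partition(part, path)
        back = read_partition(path, node_labels=("x", "y", "z"))
        assert back == part

    def test_duplicate_node_in_file_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("a\t0\na\t1\n")
        with pytest.raises(ValidationError):
            read_partition(path)


class TestLump:
    def test_identity_partition_returns_P(self, model_of, barbell):
        m = model_of(barbell)
        chain = lump(m, Partition.identity(barbell.node_labels))
        np.testing.assert_allclose(chain.U, m.P, atol=1e-14)

    def test_trivial_partition_persistence_one(self, model_of, barbell):
        m = model_of(barbell)
        chain = lump(m, Partition.trivial(barbell.node_labels))
        np.testing.assert_allclose(chain.U, [[1.0]])
        np.testing.assert_allclose(chain.persistence, [1.0])

    def test_directed_cycle_hand_value(self, model_of, cycle3):
        m = model_of(cycle3)
        part = Partition.from_clusters(cycle3.node_labels, [["0", "1"], ["2"]])
        chain = lump(m, part)
        np.testing.assert_allclose(chain.U, [[0.5, 0.5], [1.0, 0.0]], atol=1e-14)
        np.testing.assert_allclose(chain.pi_collected, [2 / 3, 1 / 3], atol=1e-14)
        np.testing.assert_allclose(chain.pi_collected @ chain.U,
                                   chain.pi_collected, atol=1e-12)

    def test_lump_consistency_random_pairs(self):
        """diag(U), the explicit formula and the undirected strength form
        agree, and the collected stationary vector is invariant under U."""
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            net = random_connected_undirected(rng, n)
            m = TransitionModel.from_network(net)
            part = random_partition(rng, net.node_labels, int(rng.integers(2, n)))
            chain = lump(m, part)
            np.testing.assert_allclose(chain.U.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(
                chain.persistence, persistence_probabilities(m, part), atol=1e-12)
            np.testing.assert_allclose(
                chain.persistence, persistence_undirected(net, part), atol=1e-12)
            np.testing.assert_allclose(
                chain.pi_collected @ chain.U, chain.pi_collected, atol=1e-10)


class TestPersistence:
    def test_barbell_triangle(self, barbell, barbell_partition, model_of):
        p = persistence_probabilities(model_of(barbell), barbell_partition)
        np.testing.assert_allclose(p, [6 / 7, 6 / 7], atol=1e-14)

    def test_four_cycle_adjacent_pairs(self, four_cycle, model_of):
        part = Partition.from_clusters(four_cycle.node_labels,
                                       [["a", "b"], ["c", "d"]])
        p = persistence_probabilities(model_of(four_cycle), part)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-14)

    def test_path_cluster(self, path3, model_of):
        part = Partition.from_clusters(path3.node_labels, [["1", "2"], ["3"]])
        p = persistence_undirected(path3, part)
        assert abs(p[0] - 2 / 3) < 1e-14

    def test_whole_network_is_one(self, barbell):
        p = persistence_undirected(barbell, Partition.trivial(barbell.node_labels))
        np.testing.assert_allclose(p, [1.0])

    def test_undirected_form_rejects_directed(self, cycle3):
        part = Partition.trivial(cycle3.node_labels)
        with pytest.raises(ValidationError):
            persistence_undirected(cycle3, part)

    def test_monte_carlo_stay_frequency(self, barbell, barbell_partition, model_of):
        """Empirical one-step stay frequency matches persistence (3 SE)."""
        m = model_of(barbell)
        p = persistence_probabilities(m, barbell_partition)
        walk = simulate_walk(m, 0, 200_000, seed=3)
        a = barbell_partition.assignment
        cl = a[walk]
        for c in range(2):
            at_c = cl[:-1] == c
            stay = np.mean(cl[1:][at_c] == c)
            se = np.sqrt(p[c] * (1 - p[c]) / at_c.sum())
            assert abs(stay - p[c]) < 3 * se


class TestAlphaAndEscape:
    def test_alpha_pass_and_fail(self):
        ok, failing = is_alpha_partition(np.array([0.9, 0.8]), 0.5)
        assert ok and failing == []
        ok, failing = is_alpha_partition(np.array([0.9, 0.3]), 0.5)
        assert not ok and failing == [1]

    def test_alpha_boundary_non_strict(self):
        ok, _ = is_alpha_partition(np.array([0.5, 0.7]), 0.5)
        assert ok

    def test_alpha_out_of_range(self):
        with pytest.raises(ValidationError):
            is_alpha_partition(np.array([0.5]), 0.0)

    def test_escape_times(self):
        np.testing.assert_allclose(escape_times(np.array([0.5])), [2.0])
        assert np.isinf(escape_times(np.array([1.0]))[0])

    def test_mean_sojourn_matches_escape_time(self, cycle3, model_of):
        """Simulated sojourn in {0,1} of the 3-cycle has mean ~ 1/(1-p) = 2."""
        m = model_of(cycle3)
        walk = simulate_walk(m, 0, 100_000, seed=5)
        inside = (walk <= 1).astype(int)
        # lengths of runs of 1s
        runs, cur = [], 0
        for x in inside:
            if x:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        runs = np.array(runs)
        se = runs.std(ddof=1) / np.sqrt(len(runs))
        assert abs(runs.mean() - 2.0) < 3 * se


class TestCutAndWeak:
    def test_barbell_ncut_identity(self, barbell, barbell_partition, model_of):
        nc = normalized_cut(barbell, list("abc"))
        assert abs(nc - 1 / 7) < 1e-14
        p = persistence_probabilities(model_of(barbell), barbell_partition)
        assert abs((1 - nc) - p[0]) < 1e-14

    def test_whole_network_cut_zero(self, barbell):
        assert normalized_cut(barbell, list("abcdef")) == 0.0

    def test_weak_community_strict_boundary(self, barbell, four_cycle):
        assert weak_community_test(barbell, list("abc"))
        assert not weak_community_test(four_cycle, ["a", "b"])  # tie is not "more"

    def test_identity_on_random_clusters(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            net = random_connected_undirected(rng, n)
            m = TransitionModel.from_network(net)
            k = int(rng.integers(1, n))
            cluster = [str(i) for i in rng.choice(n, size=k, replace=False)]
            rest = [lab for lab in net.node_labels if lab not in cluster]
            clusters = [cluster] + ([rest] if rest else [])
            part = Partition.from_clusters(net.node_labels, clusters)
            p = persistence_probabilities(m, part)[0]
            assert abs((1 - normalized_cut(net, cluster)) - p) < 1e-12
            assert weak_community_test(net, cluster) == (p > 0.5)


class TestModularity:
    def test_trivial_partition_zero(self, barbell):
        assert abs(modularity(barbell, Partition.trivial(barbell.node_labels))) < 1e-15

    def test_barbell_two_triangles(self, barbell, barbell_partition):
        assert abs(modularity(barbell, barbell_partition) - 5 / 14) < 1e-14

    def test_linkrank_identity_directed_cycle(self, cycle3, model_of):
        q = linkrank_modularity(model_of(cycle3),
                                Partition.identity(cycle3.node_labels))
        assert abs(q - (-1 / 3)) < 1e-14

    def test_linkrank_equals_newman_undirected(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            net = random_connected_undirected(rng, n)
            m = TransitionModel.from_network(net)
            part = random_partition(rng, net.node_labels, int(rng.integers(2, n)))
            assert abs(linkrank_modularity(m, part) - modularity(net, part)) < 1e-12

    def test_autocovariance_trace_is_linkrank(self):
        """trace of R(1) = diag(c) U - c c^T equals LinkRank modularity."""
        rng = np.random.default_rng(43)
        for _ in range(20):
            n = int(rng.integers(4, 25))
            net = random_strongly_connected_digraph(rng, n)
            m = TransitionModel.from_network(net)
            part = random_partition(rng, net.node_labels, int(rng.integers(2, n)))
            chain = lump(m, part)
            c = chain.pi_collected
            R1 = np.diag(c) @ chain.U - np.outer(c, c)
            assert abs(np.trace(R1) - linkrank_modularity(m, part)) < 1e-12

    def test_directed_newman_rejected(self, cycle3):
        with pytest.raises(ValidationError):
            modularity(cycle3, Partition.trivial(cycle3.node_labels))


class TestLocalFractionsAndRelativePersistence:
    def test_trivial_partition(self, barbell, model_of):
        m = model_of(barbell)
        part = Partition.trivial(barbell.node_labels)
        q_c, q_null, local = local_link_fractions(m, part)
        np.testing.assert_allclose(q_c, [1.0])
        np.testing.assert_allclose(q_null, [1.0])
        np.testing.assert_allclose(local, [0.0], atol=1e-15)
        np.testing.assert_allclose(relative_persistence(m, part), [0.0], atol=1e-15)

    def test_directed_cycle_hand_values(self, cycle3, model_of):
        m = model_of(cycle3)
        part = Partition.from_clusters(cycle3.node_labels, [["0", "1"], ["2"]])
        q_c, q_null, _ = local_link_fractions(m, part)
        np.testing.assert_allclose(q_c, [1 / 3, 0.0], atol=1e-14)
        np.testing.assert_allclose(q_null, [4 / 9, 1 / 9], atol=1e-14)

    def test_barbell_relative_persistence(self, barbell, barbell_partition, model_of):
        rel = relative_persistence(model_of(barbell), barbell_partition)
        np.testing.assert_allclose(rel, [5 / 14, 5 / 14], atol=1e-14)

    def test_algebraic_identities(self):
        rng = np.random.default_rng(51)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            net = random_strongly_connected_digraph(rng, n)
            m = TransitionModel.from_network(net)
            part = random_partition(rng, net.node_labels, int(rng.integers(2, n)))
            chain = lump(m, part)
            q_c, q_null, local = local_link_fractions(m, part)
            np.testing.assert_allclose(
                q_c / chain.pi_collected, chain.persistence, atol=1e-12)
            rel = relative_persistence(m, part)
            np.testing.assert_allclose(chain.pi_collected * rel, local, atol=1e-12)
            assert q_c.sum() <= 1 + 1e-12 and q_null.sum() <= 1 + 1e-12


def _nmi_reference(a: np.ndarray, b: np.ndarray) -> float:
    """Direct confusion-matrix NMI (Danon 2I/(Ha+Hb), natural logs)."""
    n = len(a)
    conf = np.zeros((a.max() + 1, b.max() + 1))
    for x, y in zip(a, b):
        conf[x, y] += 1
    pxy = conf / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    I = np.sum(pxy[mask] * np.log(pxy[mask] / np.outer(px, py)[mask]))
    Ha = -np.sum(px[px > 0] * np.log(px[px > 0]))
    Hb = -np.sum(py[py > 0] * np.log(py[py > 0]))
    return 2 * I / (Ha + Hb)


class TestNMI:
    def test_relabelled_partition_gives_one(self):
        a = Partition(tuple("abcdef"), [0, 0, 1, 1, 2, 2])
        b = Partition(tuple("abcdef"), [2, 2, 0, 0, 1, 1])
        assert normalized_mutual_information(a, b) == pytest.approx(1.0)

    def test_against_trivial_is_zero(self):
        a = Partition(tuple("abcd"), [0, 0, 1, 1])
        b = Partition.trivial(tuple("abcd"))
        assert normalized_mutual_information(a, b) == 0.0

    def test_both_trivial_is_one(self):
        a = Partition.trivial(tuple("abc"))
        assert normalized_mutual_information(a, a) == 1.0

    def test_node_order_independent(self):
        a = Partition(("x", "y", "z"), [0, 0, 1])
        b = Partition(("z", "x", "y"), [1, 0, 0])
        assert normalized_mutual_information(a, b) == pytest.approx(1.0)

    def test_matches_confusion_matrix_reference(self):
        rng = np.random.default_rng(61)
        labels = tuple(str(i) for i in range(60))
        for _ in range(20):
            a = random_partition(rng, labels, 4)
            b = random_partition(rng, labels, 5)
            got = normalized_mutual_information(a, b)
            ref = _nmi_reference(a.assignment, b.assignment)
            assert got == pytest.approx(ref, abs=1e-12)

    def test_independent_partitions_near_zero_mean(self):
        rng = np.random.default_rng(62)
        labels = tuple(str(i) for i in range(200))
        vals = []
        for _ in range(1000):
            a = random_partition(rng, labels, 4)
            b = random_partition(rng, labels, 4)
            vals.append(normalized_mutual_information(a, b))
        assert abs(np.mean(vals)) < 0.02


class TestQualityReport:
    def test_barbell_report(self, barbell, barbell_partition, tmp_path):
        rep = quality_report(barbell, barbell_partition, alpha=0.5)
        assert rep.summary["is_alpha_partition"] is True
        assert rep.summary["q"] == 2
        assert rep.summary["modularity"] == pytest.approx(5 / 14)
        np.testing.assert_allclose(rep.per_cluster["persistence"], 6 / 7)
        assert all(rep.per_cluster["weak_community"])
        rep.to_tsv(tmp_path / "r.tsv")
        rep.to_json(tmp_path / "r.json")
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["summary"]["q"] == 2
        assert len(payload["clusters"]) == 2

    def test_directed_report_has_no_cut_columns(self, cycle3):
        part = Partition.from_clusters(cycle3.node_labels, [["0", "1"], ["2"]])
        rep = quality_report(cycle3, part, alpha=0.9)
        assert "normalized_cut" not in rep.per_cluster.columns
        assert rep.summary["is_alpha_partition"] is False
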