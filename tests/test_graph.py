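"""Graph container, edge-list I/O, module statistics and modularity."""

import io

import numpy as np
import pytest

import imodnet as im
from conftest import edgewise_modularity, random_graph


class TestReadEdgeList:
    def test_triangle(self):
        g = im.read_edge_list(io.StringIO("1 2\n2 3\n1 3\n"))
        assert g.n_nodes == 3 and g.n_edges == 3
        assert list(g.degrees) == [2, 2, 2]

    def test_duplicate_edge_collapsed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = im.read_edge_list(io.StringIO("1 2\n2 1\n"))
        assert g.n_nodes == 2 and g.n_edges == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_self_loop_rejected_naming_line(self):
        with pytest.raises(ValueError, match="line 2.*self-loop"):
            im.read_edge_list(io.StringIO("1 2\n1 1\n"))

    def test_malformed_line_rejected_with_line_number(self):
        with pytest.raises(ValueError, match="line 3"):
            im.read_edge_list(io.StringIO("1 2\n2 3\na b c\n"))

    def test_comments_and_blanks_ignored(self):
        g = im.read_edge_list(io.StringIO("# header\n\n1 2\n"))
        assert g.n_nodes == 2 and g.n_edges == 1

    def test_first_appearance_node_order(self):
        g = im.read_edge_list(io.StringIO("b a\nc a\n"))
        assert g.nodes == ("b", "a", "c")


class TestInducedSubgraph:
    def test_one_clique_of_ring(self, ring):
        g, truth = ring
        sub = im.induced_subgraph(g, [0, 1, 2])
        assert sub.n_nodes == 3 and sub.n_edges == 3

    def test_identity(self, triangle):
        sub = im.induced_subgraph(triangle, triangle.nodes)
        assert sub.n_edges == triangle.n_edges and sub.nodes == triangle.nodes

    def test_two_nodes_of_triangle(self, triangle):
        sub = im.induced_subgraph(triangle, [0, 1])
        assert sub.n_nodes == 2 and sub.n_edges == 1

    def test_unknown_node_rejected(self, triangle):
        with pytest.raises(ValueError, match="not in graph"):
            im.induced_subgraph(triangle, [0, 99])


class TestModuleStats:
    def test_ring_truth_partition(self, ring):
        g, truth = ring
        stats = im.module_stats(g, truth)
        assert np.all(stats.intra_links == 3)
        assert np.all(stats.degree_sum == 8)
        assert stats.degree_sum.sum() == 2 * g.n_edges

    def test_single_module(self, two_triangles):
        stats = im.module_stats(two_triangles, im.Partition.single_module(two_triangles))
        assert stats.intra_links[0] == two_triangles.n_edges
        assert stats.degree_sum[0] == 2 * two_triangles.n_edges

    def test_triangle_split(self, triangle):
        p = im.Partition(triangle, [0, 1, 1])
        stats = im.module_stats(triangle, p)
        assert list(stats.intra_links) == [0, 1]
        assert list(stats.degree_sum) == [2, 4]

    def test_unassigned_node_rejected(self, triangle):
        with pytest.raises(ValueError, match="unassigned"):
            im.Partition.from_assignment(triangle, {0: 0, 1: 0})


class TestModularity:
    def test_ring_truth_is_0_6500(self, ring):
        g, truth = ring
        assert im.modularity(g, truth) == pytest.approx(0.65, abs=1e-12)

    def test_ring_five_module_is_0_6750(self, ring):
        g, _ = ring
        p = im.Partition(g, np.repeat(np.arange(5), 6))
        assert im.modularity(g, p) == pytest.approx(0.675, abs=1e-12)

    def test_single_module_is_zero(self, two_triangles):
        q = im.modularity(two_triangles, im.Partition.single_module(two_triangles))
        assert q == 0.0

    def test_triangle_split_is_minus_two_ninths(self, triangle):
        q = im.modularity(triangle, im.Partition(triangle, [0, 1, 1]))
        assert q == pytest.approx(-2.0 / 9.0, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        g = im.Graph([0, 1], [])
        with pytest.raises(ValueError, match="edgeless"):
            im.modularity(g, im.Partition.single_module(g))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_graph(rng)
            labels = rng.integers(0, 3, size=g.n_nodes)
            p = im.Partition(g, labels)
            perm = rng.permutation(int(labels.max()) + 1)
            q1 = im.modularity(g, p)
            q2 = im.modularity(g, im.Partition(g, perm[labels]))
            assert q1 == pytest.approx(q2, abs=1e-15)

    def test_agrees_with_edgewise_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_graph(rng)
            p = im.Partition(g, rng.integers(0, 3, size=g.n_nodes))
            assert im.modularity(g, p) == pytest.approx(
                edgewise_modularity(g, p), abs=1e-12
            )

    def test_agrees_with_networkx(self):
        import networkx.algorithms.community as nxc

        rng = np.random.default_rng(17)
        for _ in range(10):
            g = random_graph(rng)
            labels = rng.integers(0, 3, size=g.n_nodes)
            p = im.Partition(g, labels)
            comms = [set(np.flatnonzero(labels == m)) for m in np.unique(labels)]
            assert im.modularity(g, p) == pytest.approx(
                nxc.modularity(g.to_networkx(), comms), abs=1e-12
            )


class TestPartitionIO:
    def test_round_trip(self, ring, tmp_path):
        g, truth = ring
        path = tmp_path / "part.tsv"
        im.write_partition(truth, im.modularity(g, truth), path, config="seed=1")
        back = im.read_partition(path, g)
        assert back == truth

    def test_header_and_line_count(self, ring, tmp_path):
        g, truth = ring
        path = tmp_path / "part.tsv"
        im.write_partition(truth, 0.65, path)
        lines = path.read_text().splitlines()
        data = [l for l in lines if not l.startswith("#")]
        assert len(data) == 30
        assert any(l.strip() == "# M=10" for l in lines)

    def test_canonical_labels_by_smallest_member(self):
        g = im.Graph([0, 1, 2, 3], [(0, 1), (2, 3)])
        p = im.Partition(g, [5, 5, 2, 2]).canonicalize()
        assert list(p.labels) == [0, 0, 1, 1]
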