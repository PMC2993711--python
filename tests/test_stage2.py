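"""Stage 2: release caps, batching, reduced solves and refinement."""

import numpy as np
import pytest

import imodnet as im
from conftest import brute_force_best, random_graph
from imodnet.partition import modularity_score


class TestReleaseLimit:
    def test_ring_clique_released_whole(self, ring):
        g, truth = ring
        cap = im.release_limit(g, truth, 0, u=200.0)
        assert cap == 100  # Aver = 2, so floor(200/2)
        batches = im.release_batches(truth, 0, cap)
        assert len(batches) == 1 and len(batches[0]) == 3

    @pytest.mark.parametrize("u,expected", [(200.0, 40), (6.0, 1)])
    def test_divide_operator(self, u, expected):
        # K_6 module: Aver_m = 5
        g = im.Graph(range(6), [(i, j) for i in range(6) for j in range(i + 1, 6)])
        p = im.Partition.single_module(g)
        assert im.release_limit(g, p, 0, u=u) == expected

    def test_u6_aver2_gives_3(self, triangle):
        # triangle has Aver = 2
        p = im.Partition.single_module(triangle)
        assert im.release_limit(triangle, p, 0, u=6.0) == 3

    def test_multiply_operator(self, triangle):
        p = im.Partition.single_module(triangle)
        assert im.release_limit(triangle, p, 0, u=3.0, operator="multiply") == 6

    def test_degree_zero_module_releases_all(self):
        g = im.Graph(range(3), [(0, 1)])
        p = im.Partition(g, [0, 0, 1])
        assert im.release_limit(g, p, 1) == 1

    def test_empty_module_rejected(self, triangle):
        p = im.Partition.single_module(triangle)
        with pytest.raises(ValueError, match="empty"):
            im.release_limit(triangle, p, 5)


class TestReleaseBatches:
    def test_sorted_and_chunked(self):
        g = im.Graph(range(10), [(i, (i + 1) % 10) for i in range(10)])
        labels = np.zeros(10, dtype=np.int64)
        labels[[7, 2, 9, 4]] = 1
        p = im.Partition(g, labels)
        batches = im.release_batches(p, 1, cap=2)
        assert [list(b) for b in batches] == [[2, 4], [7, 9]]

    def test_cap_larger_than_module(self, triangle):
        p = im.Partition.single_module(triangle)
        batches = im.release_batches(p, 0, cap=100)
        assert [list(b) for b in batches] == [[0, 1, 2]]

    def test_uneven_chunks(self):
        g = im.Graph(range(7), [(i, (i + 1) % 7) for i in range(7)])
        p = im.Partition.single_module(g)
        sizes = [len(b) for b in im.release_batches(p, 0, cap=3)]
        assert sizes == [3, 3, 1]


class TestSolveReduced:
    def test_optimal_incumbent_unchanged(self, ring):
        g, _ = ring
        p = im.Partition(g, np.repeat(np.arange(5), 6))  # the global optimum
        out = im.solve_reduced(g, p, p.members(0), im.SolverConfig(seed=0))
        assert im.modularity(g, out) == pytest.approx(0.675, abs=1e-12)

    def test_misplaced_node_returns_home(self, ring):
        g, _ = ring
        labels = np.repeat(np.arange(5), 6)
        labels[0] = 1  # push one clique member into the neighbouring module
        p = im.Partition(g, labels)
        out = im.solve_reduced(g, p, np.array([0]), im.SolverConfig(seed=0))
        assert im.modularity(g, out) == pytest.approx(0.675, abs=1e-12)
        assert out.labels[0] == out.labels[1] == out.labels[2]

    def test_release_all_reaches_global_optimum(self, two_triangles):
        g = two_triangles
        p = im.Partition(g, [0, 0, 0, 1, 1, 1])
        # degrade the start: everything in module 0
        p0 = im.Partition(g, [0, 0, 0, 0, 0, 1])
        out = im.solve_reduced(g, p0, np.arange(6), im.SolverConfig(seed=0))
        assert im.modularity(g, out) == pytest.approx(5 / 14, abs=1e-12)

    def test_never_decreases_q(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            g = random_graph(rng, n_lo=8, n_hi=16)
            labels = rng.integers(0, 4, size=g.n_nodes)
            p = im.Partition(g, labels).canonicalize()
            released = rng.choice(g.n_nodes, size=min(4, g.n_nodes), replace=False)
            out = im.solve_reduced(g, p, released, im.SolverConfig(seed=0))
            assert modularity_score(g, out.labels) >= modularity_score(g, p.labels)


class TestRefine:
    def test_ring_ten_modules_refines_to_five(self, ring):
        g, truth = ring
        refined, info = im.refine(g, truth, im.SolverConfig(seed=0))
        assert im.modularity(g, refined) == pytest.approx(0.675, abs=1e-12)
        assert refined.n_modules == 5

    def test_optimal_start_terminates_after_two_flat_iterations(self, ring):
        g, _ = ring
        p = im.Partition(g, np.repeat(np.arange(5), 6))
        refined, info = im.refine(g, p, im.SolverConfig(seed=0))
        assert refined == p.canonicalize()
        assert info["n_major_iters"] == 2
        assert info["q_history"] == [pytest.approx(0.675)] * 2

    def test_random_start_on_two_triangles(self, two_triangles):
        rng = np.random.default_rng(43)
        for _ in range(5):
            p0 = im.Partition(two_triangles, rng.integers(0, 3, size=6))
            refined, _ = im.refine(two_triangles, p0, im.SolverConfig(seed=1))
            assert im.modularity(two_triangles, refined) == pytest.approx(
                5 / 14, abs=1e-12
            )

    def test_score_trace_monotone_and_q_improves(self):
        rng = np.random.default_rng(47)
        for _ in range(5):
            g = random_graph(rng, n_lo=10, n_hi=20)
            p0 = im.Partition(g, rng.integers(0, 4, size=g.n_nodes)).canonicalize()
            refined, info = im.refine(g, p0, im.SolverConfig(seed=2))
            trace = info["score_trace"]
            assert all(b >= a for a, b in zip(trace, trace[1:]))
            assert modularity_score(g, refined.labels) >= modularity_score(g, p0.labels)

    def test_exact_refinement_reaches_brute_force_optimum(self):
        rng = np.random.default_rng(53)
        for _ in range(5):
            g = random_graph(rng, n_lo=4, n_hi=8)
            p0 = im.Partition(g, rng.integers(0, g.n_nodes, size=g.n_nodes)).canonicalize()
            # use the exact stage-1 result as a start, then refine must hold it
            p1, _ = im.initial_partition(g, im.SolverConfig(seed=0, m_max=g.n_nodes))
            refined, _ = im.refine(g, p1, im.SolverConfig(seed=0))
            assert modularity_score(g, refined.labels) == brute_force_best(g)[0]
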