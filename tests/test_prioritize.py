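"""PC / dPC prioritization and conservation-area gap analysis, with an
exhaustive simple-path oracle for the max-probability paths."""

from itertools import permutations

import numpy as np
import pytest
from shapely.geometry import box

import landconnect as lc


def make_graph(attrs, dists, total_area=1000.0, p_med=0.5, d_med=10_000.0):
    n = len(attrs)
    return lc.PatchGraph(
        ids=list(range(n)),
        attributes=np.asarray(attrs, float),
        distances=np.asarray(dists, float),
        total_area=total_area,
        p_med=p_med,
        d_med=d_med,
    )


def exhaustive_pc(graph):
    """PC by enumerating all simple paths for the max-probability step
    (feasible for n <= 7)."""
    p = graph.direct_p()
    n = graph.n
    a = graph.attributes
    pstar = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = p[i, j]
            inner = [k for k in range(n) if k not in (i, j)]
            for r in range(1, len(inner) + 1):
                for mid in permutations(inner, r):
                    route = (i, *mid, j)
                    prod = np.prod([p[u, v] for u, v in zip(route, route[1:])])
                    best = max(best, prod)
            pstar[i, j] = best
    return float(a @ pstar @ a / graph.total_area ** 2)


def random_graph(rng, n):
    pts = rng.uniform(0, 40_000, size=(n, 2))
    d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    np.fill_diagonal(d, 0.0)
    return make_graph(rng.uniform(1, 50, n), d, total_area=rng.uniform(500, 5000))


class TestPatchGraph:
    def test_dispersal_probability_calibration(self):
        g = make_graph([1.0, 1.0], [[0.0, 10_000.0], [10_000.0, 0.0]], d_med=10_000.0)
        p = g.direct_p()
        assert p[0, 1] == pytest.approx(0.5)  # p(d_med) = p_med
        assert p[0, 0] == 1.0  # p(0) = 1

    def test_touching_patches_distance_is_cell_size(self):
        labels = lc.Grid(np.zeros((4, 4)), 100.0)
        patches = [
            lc.Patch(1, 0.01, 1.0, 1, (150.0, 250.0), np.array([[1, 1]])),
            lc.Patch(2, 0.01, 1.0, 1, (250.0, 250.0), np.array([[1, 2]])),
        ]
        ps = lc.PatchSet(labels=labels, patches=patches)
        g = lc.build_patch_graph(ps, attribute="area")
        assert g.distances[0, 1] == pytest.approx(100.0)

    def test_nonpositive_attribute_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            make_graph([1.0, 0.0], np.zeros((2, 2)))


class TestPcIndex:
    def test_single_patch_covering_landscape_gives_one(self):
        g = make_graph([1000.0], [[0.0]], total_area=1000.0)
        assert lc.pc_index(g) == pytest.approx(1.0)

    def test_isolated_pair(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        g = make_graph([10.0, 10.0], d, total_area=100.0)
        assert lc.pc_index(g) == pytest.approx(2 * 10.0 ** 2 / 100.0 ** 2)

    def test_two_hop_route_beats_weak_direct_link(self):
        # elongated stepping stone: min-distances violate the triangle
        # inequality, so the two-hop product may exceed the direct p
        d = np.array(
            [[0.0, 1000.0, 20_000.0], [1000.0, 0.0, 1000.0], [20_000.0, 1000.0, 0.0]]
        )
        g = make_graph([5.0, 5.0, 5.0], d, d_med=5_000.0)
        p = g.direct_p()
        pstar_02 = p[0, 1] * p[1, 2]
        assert pstar_02 > p[0, 2]
        assert lc.pc_index(g) == pytest.approx(exhaustive_pc(g), rel=1e-9)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for n in (3, 5, 7):
            g = random_graph(rng, n)
            assert lc.pc_index(g) == pytest.approx(exhaustive_pc(g), rel=1e-9)

    def test_removing_a_node_never_increases_pc(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 6)
        pc = lc.pc_index(g)
        for nid in g.ids:
            assert lc.pc_index(g.without(nid)) <= pc + 1e-12


class TestDpc:
    def test_only_patch_total_loss(self):
        g = make_graph([10.0], [[0.0]])
        assert lc.dpc(g, 0) == pytest.approx(100.0)

    def test_two_equal_patches_half_linked(self):
        # hand evaluation: PC_full = (a^2 + a^2 + 2 a^2 p) / A^2 with
        # p = 0.5 -> 3 a^2 / A^2; removing one leaves a^2 / A^2
        d_half = 10_000.0  # p(d_med)=0.5 at d = d_med
        g = make_graph([7.0, 7.0], [[0.0, d_half], [d_half, 0.0]], d_med=d_half)
        assert lc.dpc(g, 0) == pytest.approx(66.67, abs=0.01)

    def test_nonnegative_for_all_nodes(self):
        rng = np.random.default_rng(10)
        g = random_graph(rng, 7)
        for nid in g.ids:
            assert lc.dpc(g, nid) >= -1e-12


class TestDpcFractions:
    def test_isolated_patch_is_pure_intra(self):
        d = np.full((3, 3), np.inf)
        np.fill_diagonal(d, 0.0)
        g = make_graph([4.0, 5.0, 6.0], d)
        dec = lc.dpc_fractions(g, 1)
        assert dec.flux == pytest.approx(0.0, abs=1e-12)
        assert dec.connector == pytest.approx(0.0, abs=1e-9)
        assert dec.dpc == pytest.approx(dec.intra, rel=1e-9)

    def test_stepping_stone_is_pure_connector(self):
        # negligible middle patch on the only route between two big ones
        d = np.array(
            [[0.0, 1000.0, 60_000.0], [1000.0, 0.0, 1000.0], [60_000.0, 1000.0, 0.0]]
        )
        g = make_graph([50.0, 1e-6 * 50.0, 50.0], d, d_med=5_000.0)
        dec = lc.dpc_fractions(g, 1)
        assert dec.intra < 1e-6
        assert dec.flux < 1e-3
        assert dec.connector > 1.0

    def test_fractions_sum_to_dpc_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            g = random_graph(rng, int(rng.integers(2, 11)))
            nid = int(rng.integers(0, g.n))
            dec = lc.dpc_fractions(g, nid)
            assert dec.intra + dec.flux + dec.connector == pytest.approx(
                dec.dpc, rel=1e-9, abs=1e-9
            )


class TestRanking:
    def test_dominant_patch_ranks_first(self):
        rng = np.random.default_rng(13)
        g = random_graph(rng, 5)
        g.attributes[2] = g.attributes.sum()  # overwhelming patch
        table = lc.rank_patches(g)
        assert table.iloc[0]["id"] == 2

    def test_ranking_invariant_under_uniform_attribute_scaling(self):
        rng = np.random.default_rng(14)
        g = random_graph(rng, 6)
        t1 = lc.rank_patches(g)
        g2 = make_graph(
            g.attributes * 37.0, g.distances, total_area=g.total_area,
            p_med=g.p_med, d_med=g.d_med,
        )
        t2 = lc.rank_patches(g2)
        assert list(t1["id"]) == list(t2["id"])
        np.testing.assert_allclose(t1["dpc"], t2["dpc"], rtol=1e-9)

    def test_symmetric_layout_equal_dpc(self):
        d = np.array([[0.0, 5000.0], [5000.0, 0.0]])
        g = make_graph([8.0, 8.0], d)
        t = lc.rank_patches(g)
        assert t["dpc"].iloc[0] == pytest.approx(t["dpc"].iloc[1], rel=1e-9)

    def test_mean_dpc_nondecreasing_in_dispersal_distance(self):
        # fixed layout; longer median dispersal -> better-connected network
        rng = np.random.default_rng(42)
        n = 6
        pts = rng.uniform(0, 50_000, size=(n, 2))
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        np.fill_diagonal(d, 0.0)
        attrs = rng.uniform(5, 50, n)
        means = []
        for d_med in (5000.0, 10_000.0, 15_000.0, 20_000.0, 25_000.0):
            g = make_graph(attrs, d, d_med=d_med)
            table = lc.rank_patches(g)
            means.append(table.iloc[1:]["dpc"].mean())
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestGapAnalysis:
    def _targets(self):
        v = np.zeros((10, 10))
        v[4:6, 0:10] = 1.0  # 20 habitat cells across the middle
        return lc.Grid(v, 100.0, origin=(0.0, 1000.0))

    def test_full_coverage(self):
        cas = lc.ConservationAreas([box(0, 0, 1000, 1000)], ["protected_area"])
        cov = lc.gap_coverage(self._targets(), cas)
        assert cov[cov.kind == "total"]["covered_pct"].iloc[0] == 100.0

    def test_no_overlap(self):
        cas = lc.ConservationAreas([box(0, 900, 1000, 1000)], ["protected_area"])
        cov = lc.gap_coverage(self._targets(), cas)
        assert cov[cov.kind == "total"]["covered_pct"].iloc[0] == 0.0

    def test_half_coverage_by_construction(self):
        # left half of the habitat band inside the CA
        cas = lc.ConservationAreas([box(0, 0, 500, 1000)], ["wildlife_refuge"])
        cov = lc.gap_coverage(self._targets(), cas)
        assert cov[cov.kind == "total"]["covered_pct"].iloc[0] == pytest.approx(50.0)
        wr = cov[(cov.kind == "category") & (cov.name == "wildlife_refuge")]
        assert wr["covered_pct"].iloc[0] == pytest.approx(50.0)

    def test_empty_targets_zero_with_status(self):
        empty = lc.Grid(np.zeros((5, 5)), 100.0, origin=(0.0, 500.0))
        cas = lc.ConservationAreas([box(0, 0, 500, 500)], ["protected_area"])
        cov = lc.gap_coverage(empty, cas)
        assert cov[cov.kind == "total"]["covered_pct"].iloc[0] == 0.0
        assert cov.attrs["status"] == "empty_targets"


class TestCaPrioritization:
    def _suitable(self):
        v = np.ones((10, 10))
        return lc.Grid(v, 100.0, origin=(0.0, 1000.0))

    def test_single_ca_takes_all(self):
        cas = lc.ConservationAreas([box(0, 0, 300, 300)], ["protected_area"])
        table = lc.ca_prioritization(cas, self._suitable())
        assert len(table) == 1
        assert table["dpc"].iloc[0] == pytest.approx(100.0)

    def test_ca_without_suitable_habitat_excluded(self):
        v = np.zeros((10, 10))
        v[0:3, 0:3] = 1.0
        suitable = lc.Grid(v, 100.0, origin=(0.0, 1000.0))
        cas = lc.ConservationAreas(
            [box(0, 700, 300, 1000), box(500, 0, 900, 300)],
            ["wildlife_refuge", "non_hunting_area"],
        )
        with pytest.warns(UserWarning, match="excluded"):
            table = lc.ca_prioritization(cas, suitable)
        assert list(table["id"]) == ["ca_0"]

    def test_symmetric_twin_cas_equal_dpc(self):
        cas = lc.ConservationAreas(
            [box(0, 400, 200, 600), box(800, 400, 1000, 600)],
            ["protected_area", "protected_area"],
        )
        table = lc.ca_prioritization(cas, self._suitable())
        assert table["dpc"].iloc[0] == pytest.approx(table["dpc"].iloc[1], rel=1e-9)
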