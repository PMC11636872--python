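import itertools

import numpy as np
import pytest

from bgsal.abstraction import (
    BoundarySet,
    FeatureMatrix,
    SuperpixelMap,
    boundary_indices,
    extract_features,
    segment_superpixels,
)
from bgsal.bgdict import (
    ConductivityField,
    SuperpixelGraph,
    boundary_conductivity,
    build_graph,
    geodesic_distances,
    refine_dictionary,
)
from bgsal.errors import DisconnectedGraphError
from bgsal.synthetic import ObjectSpec, SceneSpec, make_scene


def strip_spmap_and_features(lab_L=(0.0, 1.0, 3.0)):
    """A 4x9 image of three vertical strips with chosen L values."""
    labels = np.repeat(np.arange(3), 3)[None, :].repeat(4, axis=0)
    sp = SuperpixelMap(labels=labels, k=3)
    F = np.zeros((3, 8))
    F[:, 3] = lab_L  # appearance distance = |delta L|
    return sp, FeatureMatrix(F=F)


def brute_force_apsp(n, edges, weights):
    """Shortest paths by enumerating all simple paths (oracle)."""
    adj = {(p, q): w for (p, q), w in zip(map(tuple, edges), weights)}
    adj.update({(q, p): w for (p, q), w in list(adj.items())})
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for length in range(1, n):
        for path in itertools.permutations(range(n), length + 1):
            pairs = list(zip(path[:-1], path[1:]))
            if all(p in adj for p in pairs):
                cost = sum(adj[p] for p in pairs)
                i, j = path[0], path[-1]
                d[i, j] = min(d[i, j], cost)
    return d


class TestBuildGraph:
    def test_uniform_image_zero_weights(self, uniform_image):
        sp = segment_superpixels(uniform_image, n_segments=16)
        fm = extract_features(uniform_image, sp)
        g = build_graph(sp, fm)
        assert np.allclose(g.weights, 0.0, atol=1e-9)

    def test_strip_adjacency_and_weights(self):
        sp, fm = strip_spmap_and_features()
        g = build_graph(sp, fm)
        edge_map = {tuple(e): w for e, w in zip(g.edges, g.weights)}
        assert set(edge_map) == {(0, 1), (1, 2)}
        assert edge_map[(0, 1)] == pytest.approx(1.0)
        assert edge_map[(1, 2)] == pytest.approx(2.0)

    def test_two_region_cross_edges(self):
        img = np.zeros((32, 32, 3))
        img[:, 16:] = 1.0
        sp = segment_superpixels(img, n_segments=16)
        fm = extract_features(img, sp)
        g = build_graph(sp, fm)
        left = {lab for lab in range(sp.k) if np.nonzero(sp.labels == lab)[1].max() < 16}
        D = np.linalg.norm(fm.lab[list(left)[0]] - fm.lab[(set(range(sp.k)) - left).pop()])
        for (p, q), w in zip(g.edges, g.weights):
            if (p in left) != (q in left):
                assert w == pytest.approx(D, abs=1e-6)
            else:
                assert w == pytest.approx(0.0, abs=1e-6)

    def test_full_subset_uses_all_features(self):
        sp, fm = strip_spmap_and_features()
        F = fm.F.copy()
        F[:, 6] = [0.0, 0.5, 1.0]  # add spatial separation
        g = build_graph(sp, FeatureMatrix(F=F), feature_subset="full")
        edge_map = {tuple(e): w for e, w in zip(g.edges, g.weights)}
        assert edge_map[(0, 1)] == pytest.approx(np.hypot(1.0, 0.5))


class TestGeodesicDistances:
    def test_strip_distances(self):
        sp, fm = strip_spmap_and_features()
        d = geodesic_distances(build_graph(sp, fm))
        assert d[0, 2] == pytest.approx(3.0)
        assert d[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_uniform_zero(self, uniform_image):
        sp = segment_superpixels(uniform_image, n_segments=16)
        fm = extract_features(uniform_image, sp)
        d = geodesic_distances(build_graph(sp, fm))
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_cycle_heavy_edge_bypassed(self):
        g = SuperpixelGraph(
            n_nodes=4,
            edges=np.array([[0, 1], [1, 2], [2, 3], [0, 3]]),
            weights=np.array([1.0, 1.0, 1.0, 10.0]),
        )
        d = geodesic_distances(g)
        assert d[0, 3] == pytest.approx(3.0)
        oracle = brute_force_apsp(4, g.edges, g.weights)
        np.testing.assert_allclose(d, oracle)

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 5
            edges = np.array([[i, i + 1] for i in range(n - 1)] + [[0, n - 1]])
            weights = rng.uniform(0, 5, len(edges))
            g = SuperpixelGraph(n_nodes=n, edges=edges, weights=weights)
            np.testing.assert_allclose(
                geodesic_distances(g), brute_force_apsp(n, edges, weights), atol=1e-9
            )

    def test_disconnected_graph_raises(self):
        g = SuperpixelGraph(
            n_nodes=4, edges=np.array([[0, 1]]), weights=np.array([1.0])
        )
        with pytest.raises(DisconnectedGraphError):
            geodesic_distances(g)

    def test_triangle_inequality(self, suite):
        _, img, _ = suite[10]
        sp = segment_superpixels(img, n_segments=50)
        fm = extract_features(img, sp)
        d = geodesic_distances(build_graph(sp, fm))
        # d[i, j] <= d[i, m] + d[m, j] for every intermediate m
        assert (d[:, :, None] <= d[:, None, :] + d[None, :, :] + 1e-9).all()


class TestBoundaryConductivity:
    def test_uniform_closed_form(self):
        # d_geo == 0 => area = k, length = k', bc = k'/sqrt(k)
        k, kp = 16, 12
        d = np.zeros((k, k))
        boundary = BoundarySet(indices=frozenset(range(kp)))
        fld = boundary_conductivity(d, boundary, sigma=10.0)
        np.testing.assert_allclose(fld.area, 16.0)
        np.testing.assert_allclose(fld.length, 12.0)
        np.testing.assert_allclose(fld.bc, 3.0)
        np.testing.assert_allclose(fld.bc_norm, 1.0)  # degenerate => ones

    def test_two_superpixel_hand_case(self):
        d = np.array([[0.0, 20.0], [20.0, 0.0]])
        boundary = BoundarySet(indices=frozenset({0, 1}))
        fld = boundary_conductivity(d, boundary, sigma=10.0)
        a = np.exp(-2.0)
        np.testing.assert_allclose(fld.A[0, 1], a, atol=1e-9)
        np.testing.assert_allclose(fld.area, 1.0 + a)
        np.testing.assert_allclose(fld.length, 1.0 + a)
        np.testing.assert_allclose(fld.bc, np.sqrt(1.0 + a))
        assert fld.bc[0] == pytest.approx(1.06552, abs=1e-5)

    def test_far_interior_superpixel_bc_vanishes(self):
        k = 5
        d = np.zeros((k, k))
        d[-1, :-1] = d[:-1, -1] = 1e6  # node 4 infinitely far, interior
        boundary = BoundarySet(indices=frozenset({0, 1, 2}))
        fld = boundary_conductivity(d, boundary, sigma=10.0)
        assert fld.length[-1] == pytest.approx(0.0, abs=1e-12)
        assert fld.bc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_affinity_range_and_diagonal(self, suite):
        _, img, _ = suite[2]
        sp = segment_superpixels(img, n_segments=50)
        fm = extract_features(img, sp)
        d = geodesic_distances(build_graph(sp, fm))
        fld = boundary_conductivity(d, boundary_indices(sp))
        assert (fld.A > 0).all() and (fld.A <= 1.0).all()
        np.testing.assert_allclose(np.diag(fld.A), 1.0)
        assert (fld.area >= 1.0).all()
        assert (fld.bc >= 0).all()
        assert fld.bc_norm.min() == pytest.approx(0.0)
        assert fld.bc_norm.max() == pytest.approx(1.0)

    def test_scale_consistency_uniform(self, uniform_image):
        # homogeneous image: bc depends only on (k, k') = k'/sqrt(k)
        for n in (16, 64):
            sp = segment_superpixels(uniform_image, n_segments=n)
            fm = extract_features(uniform_image, sp)
            d = geodesic_distances(build_graph(sp, fm))
            bs = boundary_indices(sp)
            fld = boundary_conductivity(d, bs)
            np.testing.assert_allclose(fld.bc, bs.k_prime / np.sqrt(sp.k), atol=1e-9)

    def test_length_monotone_in_boundary_set(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, (10, 1))
        d = np.abs(pts - pts.T)
        small = BoundarySet(indices=frozenset({0, 1}))
        big = BoundarySet(indices=frozenset({0, 1, 2}))
        f_small = boundary_conductivity(d, small)
        f_big = boundary_conductivity(d, big)
        assert (f_big.length >= f_small.length - 1e-12).all()

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            boundary_conductivity(np.zeros((2, 2)), BoundarySet(frozenset({0})), sigma=0)


def field_from_bc_norm(values):
    k = len(values)
    z = np.zeros((k, k))
    return ConductivityField(
        d_geo=z, A=z, area=np.ones(k), length=np.ones(k),
        bc=np.asarray(values, float), bc_norm=np.asarray(values, float), sigma=10.0,
    )


class TestRefineDictionary:
    def test_ledger_case(self):
        fld = field_from_bc_norm([1.0, 0.9, 0.2])
        boundary = BoundarySet(indices=frozenset({0, 1, 2}))
        ref = refine_dictionary(fld, boundary, K=4.0, min_atoms=0)
        assert ref.tau == pytest.approx(0.49333, abs=1e-5)
        assert set(ref.kept) == {0, 1}

    def test_uniform_all_kept(self):
        fld = field_from_bc_norm([1.0] * 6)
        boundary = BoundarySet(indices=frozenset(range(6)))
        ref = refine_dictionary(fld, boundary, min_atoms=0)
        assert set(ref.kept) == set(range(6))
        assert ref.tau == pytest.approx(1.0)

    def test_negative_tau_keeps_all(self):
        vals = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]  # var = 0.25, tau = 0
        fld = field_from_bc_norm(vals)
        boundary = BoundarySet(indices=frozenset(range(8)))
        ref = refine_dictionary(fld, boundary, K=8.0, min_atoms=0)
        assert ref.tau < 0
        assert set(ref.kept) == set(range(8))

    def test_fallback_minimum_atoms(self):
        vals = [1.0] + [0.01] * 11
        fld = field_from_bc_norm(vals)
        boundary = BoundarySet(indices=frozenset(range(12)))
        ref = refine_dictionary(fld, boundary, K=0.5, min_atoms=8)
        assert len(ref.kept) == 8
        assert 0 in ref.kept

    def test_fallback_small_boundary_keeps_all(self):
        fld = field_from_bc_norm([1.0, 0.2, 0.1])
        boundary = BoundarySet(indices=frozenset({0, 1, 2}))
        ref = refine_dictionary(fld, boundary, K=0.1, min_atoms=8)
        assert set(ref.kept) == {0, 1, 2}

    def test_kept_subset_of_initial(self, suite):
        _, img, _ = suite[16]
        sp = segment_superpixels(img, n_segments=100)
        fm = extract_features(img, sp)
        d = geodesic_distances(build_graph(sp, fm))
        bs = boundary_indices(sp)
        ref = refine_dictionary(boundary_conductivity(d, bs), bs)
        assert set(ref.kept) <= bs.indices


class TestNearBoundaryExclusion:
    @pytest.mark.parametrize("seed", range(10))
    def test_object_border_superpixels_excluded(self, seed):
        spec = SceneSpec(
            size=(128, 128),
            objects=(ObjectSpec(center=(0.5, 0.04), size=(0.2, 0.2),
                                touches_border=True),),
            contrast=65.0,
            seed=seed,
        )
        img, gt = make_scene(spec)
        sp = segment_superpixels(img, n_segments=100)
        fm = extract_features(img, sp)
        d = geodesic_distances(build_graph(sp, fm))
        bs = boundary_indices(sp)
        fld = boundary_conductivity(d, bs)
        ref = refine_dictionary(fld, bs)
        gtb = gt.values.astype(bool)
        object_sps = {
            i for i in bs.indices if gtb[sp.labels == i].mean() > 0.5
        }
        assert object_sps, "scene must place object superpixels on the border"
        assert not (object_sps & set(ref.kept))
        for i in object_sps:
            assert fld.bc_norm[i] < ref.tau


class TestPermutationInvariance:
    def test_bc_invariant_under_label_permutation(self, suite):
        _, img, _ = suite[1]
        sp = segment_superpixels(img, n_segments=50)
        fm = extract_features(img, sp)
        d = geodesic_distances(build_graph(sp, fm))
        bs = boundary_indices(sp)
        bc = boundary_conductivity(d, bs).bc

        rng = np.random.default_rng(0)
        perm = rng.permutation(sp.k)
        sp2 = SuperpixelMap(labels=perm[sp.labels], k=sp.k)
        fm2 = extract_features(img, sp2)
        d2 = geodesic_distances(build_graph(sp2, fm2))
        bs2 = boundary_indices(sp2)
        bc2 = boundary_conductivity(d2, bs2).bc
        np.testing.assert_allclose(bc2[perm], bc, atol=1e-9)
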