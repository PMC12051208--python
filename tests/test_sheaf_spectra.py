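"""Sheaf construction, coboundaries, Laplacian spectra, persistence."""

from itertools import combinations

import numpy as np
import pytest
import scipy.linalg

import pslflex as pf
from pslflex.filtration import FiltrationComplex, Simplex


def sheaf_at_saturation(cloud, radius=100.0):
    cx = pf.build_alpha_complex(cloud, radius)
    return pf.build_sheaf(cx, cloud)


def random_sheaf(seed, n_max=8, constant=True):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    pts = rng.uniform(0, 4, size=(n, 3))
    labels = np.ones(n) if constant else rng.uniform(0.2, 2.0, size=n)
    cloud = pf.LabeledPointCloud(points=pts, labels=labels)
    radius = float(rng.uniform(0.8, 4.0))
    return sheaf_at_saturation(cloud, radius), cloud


class TestBuildSheaf:
    def test_edge_scalars(self, clouds):
        sheaf = sheaf_at_saturation(clouds["two_point"])
        assert sheaf.restriction_scalars[((0,), (0, 1))] == pytest.approx(0.5)
        assert sheaf.restriction_scalars[((1,), (0, 1))] == pytest.approx(0.0)

    def test_triangle_scalars(self, clouds):
        sheaf = sheaf_at_saturation(clouds["right_345"])
        # labels (0,1,1); r01=3, r02=4, r12=5
        assert sheaf.restriction_scalars[((0, 1), (0, 1, 2))] == pytest.approx(1 / 20)
        assert sheaf.restriction_scalars[((0, 2), (0, 1, 2))] == pytest.approx(1 / 15)
        assert sheaf.restriction_scalars[((1, 2), (0, 1, 2))] == pytest.approx(0.0)

    def test_constant_sheaf_unit_distances(self, clouds):
        sheaf = sheaf_at_saturation(clouds["equilateral"])
        assert all(
            v == pytest.approx(1.0) for v in sheaf.restriction_scalars.values()
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_composition_rule(self, seed):
        """F(v <= t) computed through either intermediate edge agrees."""
        sheaf, _ = random_sheaf(seed, constant=False)
        s = sheaf.restriction_scalars
        for tri in sheaf.triangles:
            for v in tri:
                others = [u for u in tri if u != v]
                paths = []
                for mid in others:
                    edge = tuple(sorted((v, mid)))
                    paths.append(s[((v,), edge)] * s[(edge, tri)])
                assert paths[0] == pytest.approx(paths[1], abs=1e-12)

    def test_coincident_points_rejected(self):
        cloud = pf.LabeledPointCloud(
            points=np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]]),
            labels=np.ones(3),
        )
        cx = FiltrationComplex(
            n_points=3,
            simplices=[Simplex((0,), 0.0), Simplex((1,), 0.0), Simplex((0, 1), 0.0)],
        )
        with pytest.raises(pf.PslflexError):
            pf.build_sheaf(cx, cloud)


class TestCoboundaries:
    def test_two_point_d0(self, clouds):
        pair = pf.coboundaries(sheaf_at_saturation(clouds["two_point"]))
        assert pair.d0 == pytest.approx(np.array([[-0.5, 0.0]]))

    def test_right_triangle_d1(self, clouds):
        pair = pf.coboundaries(sheaf_at_saturation(clouds["right_345"]))
        assert pair.d1 == pytest.approx(np.array([[1 / 20, -1 / 15, 0.0]]))

    def test_constant_path_matches_graph_incidence(self):
        cloud = pf.LabeledPointCloud(
            points=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]),
            labels=np.ones(4),
        )
        sheaf = sheaf_at_saturation(cloud, radius=0.6)  # consecutive edges only
        pair = pf.coboundaries(sheaf)
        expected = np.array(
            [[-1.0, 1.0, 0.0, 0.0], [0.0, -1.0, 1.0, 0.0], [0.0, 0.0, -1.0, 1.0]]
        )
        assert pair.d0 == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_d1_d0_vanishes(self, seed):
        sheaf, _ = random_sheaf(seed, constant=False)
        pair = pf.coboundaries(sheaf)
        if pair.d1.size and pair.d0.size:
            assert np.abs(pair.d1 @ pair.d0).max() <= 1e-10


class TestSheafLaplacian:
    def test_two_point_spectrum(self, clouds):
        lap = pf.sheaf_laplacian(sheaf_at_saturation(clouds["two_point"]), 0)
        assert lap == pytest.approx(np.array([[0.25, 0.0], [0.0, 0.0]]))
        assert pf.spectrum(lap) == pytest.approx([0.0, 0.25], abs=1e-9)

    def test_right_triangle_spectrum(self, clouds):
        lap = pf.sheaf_laplacian(sheaf_at_saturation(clouds["right_345"]), 0)
        assert pf.spectrum(lap) == pytest.approx([0.0, 0.08, 25 / 144], abs=1e-9)

    def test_equilateral_l1_spectrum(self, clouds):
        lap = pf.sheaf_laplacian(sheaf_at_saturation(clouds["equilateral"]), 1)
        assert pf.spectrum(lap) == pytest.approx([3.0, 3.0, 3.0], abs=1e-9)

    def test_l1_empty_when_no_edges(self, clouds):
        cx = pf.build_alpha_complex(clouds["two_cluster"], radius=1e-6)
        sheaf = pf.build_sheaf(cx, clouds["two_cluster"])
        assert pf.sheaf_laplacian(sheaf, 1).shape == (0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_constant_sheaf_is_weighted_graph_laplacian(self, seed):
        sheaf, cloud = random_sheaf(seed, constant=True)
        lap = pf.sheaf_laplacian(sheaf, 0)
        n = len(cloud)
        expected = np.zeros((n, n))
        for i, j in sheaf.edges:
            w = 1.0 / np.linalg.norm(cloud.points[i] - cloud.points[j]) ** 2
            expected[i, i] += w
            expected[j, j] += w
            expected[i, j] -= w
            expected[j, i] -= w
        assert lap == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_modes_count_components(self, seed):
        import networkx as nx

        sheaf, cloud = random_sheaf(seed, constant=True)
        g = nx.Graph()
        g.add_nodes_from(range(len(cloud)))
        g.add_edges_from(sheaf.edges)
        eigs = pf.spectrum(pf.sheaf_laplacian(sheaf, 0))
        n_zero = pf.summarize(eigs).n_zero
        assert n_zero == nx.number_connected_components(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_scaling_law_l0(self, seed):
        rng = np.random.default_rng(seed)
        cloud = pf.LabeledPointCloud(
            points=rng.uniform(0, 4, size=(6, 3)),
            labels=rng.uniform(0.2, 2.0, size=6),
        )
        sheaf = sheaf_at_saturation(cloud)
        s = 2.5
        scaled_cloud = pf.LabeledPointCloud(
            points=cloud.points * s, labels=cloud.labels
        )
        scaled = sheaf_at_saturation(scaled_cloud, radius=100.0 * s)
        e1 = pf.spectrum(pf.sheaf_laplacian(sheaf, 0))
        e2 = pf.spectrum(pf.sheaf_laplacian(scaled, 0))
        assert e2 == pytest.approx(e1 / s**2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        cloud = pf.LabeledPointCloud(
            points=rng.uniform(0, 4, size=(6, 3)),
            labels=rng.uniform(0.2, 2.0, size=6),
        )
        sheaf = sheaf_at_saturation(cloud)
        perm = rng.permutation(len(cloud))
        permuted = pf.LabeledPointCloud(
            points=cloud.points[perm], labels=cloud.labels[perm]
        )
        sheaf_p = sheaf_at_saturation(permuted)
        for q in (0, 1):
            e1 = pf.spectrum(pf.sheaf_laplacian(sheaf, q))
            e2 = pf.spectrum(pf.sheaf_laplacian(sheaf_p, q))
            assert e2 == pytest.approx(e1, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_semidefinite(self, seed):
        sheaf, _ = random_sheaf(seed, constant=False)
        for q in (0, 1):
            eigs = np.linalg.eigvalsh(pf.sheaf_laplacian(sheaf, q)) if pf.sheaf_laplacian(sheaf, q).size else np.zeros(0)
            if eigs.size:
                assert eigs.min() >= -1e-10 * max(1.0, eigs.max())


def brute_cohomology_restriction_rank(sheafX, sheafY, q):
    """Rank of H^q(Y) -> H^q(X) by explicit cochain linear algebra."""
    pairY = pf.coboundaries(sheafY)
    dqY = pairY.d1 if q == 1 else pairY.d0
    nY = len(sheafY.edges) if q else len(sheafY.vertices)
    if dqY.size == 0:
        cocycles = np.eye(nY)
    else:
        cocycles = scipy.linalg.null_space(dqY)
        if cocycles.size == 0:
            cocycles = np.zeros((nY, 0))
    sX = sheafX.edges if q else sheafX.vertices
    sY = sheafY.edges if q else sheafY.vertices
    rows = [sY.index(s) for s in sX]
    restricted = cocycles[rows, :] if cocycles.size else np.zeros((len(sX), 0))
    lapX = pf.sheaf_laplacian(sheafX, q)
    if lapX.shape[0] == 0:
        return 0
    w, v = np.linalg.eigh(lapX)
    harmonic = v[:, w < 1e-8 * max(1.0, w[-1])]
    image = harmonic.T @ restricted
    return int(np.linalg.matrix_rank(image, tol=1e-8)) if image.size else 0


def kernel_dim(matrix):
    if matrix.shape[0] == 0:
        return 0
    w = np.linalg.eigvalsh(matrix)
    return int(np.sum(w < 1e-8 * max(1.0, w[-1])))


class TestPersistentSheafLaplacian:
    def test_x_equals_y_reduces_exactly(self, clouds):
        for name in ("two_point", "right_345", "equilateral", "two_cluster"):
            sheaf = sheaf_at_saturation(clouds[name])
            for q in (0, 1):
                pair_op = pf.persistent_sheaf_laplacian(sheaf, sheaf, q)
                plain = pf.sheaf_laplacian(sheaf, q)
                assert np.array_equal(pair_op, plain)  # same assembly path

    def test_merging_components_kernel_dim_one(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        cloud = pf.LabeledPointCloud(points=pts, labels=np.ones(2))
        X = FiltrationComplex(
            n_points=2, simplices=[Simplex((0,), 0.0), Simplex((1,), 0.0)]
        )
        Y = pf.build_alpha_complex(cloud, radius=1.0)
        op = pf.persistent_sheaf_laplacian(
            pf.build_sheaf(X, cloud), pf.build_sheaf(Y, cloud), 0
        )
        assert kernel_dim(op) == 1

    def test_non_subcomplex_rejected(self, clouds):
        a = sheaf_at_saturation(clouds["equilateral"])
        b = sheaf_at_saturation(clouds["two_point"])
        with pytest.raises(pf.PslflexError):
            pf.persistent_sheaf_laplacian(a, b, 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_kernel_matches_brute_force_rank(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(4, 8))
        pts = rng.uniform(0, 4, size=(n, 3))
        labels = np.ones(n) if seed % 2 == 0 else rng.uniform(0.5, 2.0, n)
        cloud = pf.LabeledPointCloud(points=pts, labels=labels)
        r1, r2 = sorted(rng.uniform(0.3, 4.0, size=2))
        shX = pf.build_sheaf(pf.build_alpha_complex(cloud, r1), cloud)
        shY = pf.build_sheaf(pf.build_alpha_complex(cloud, r2), cloud)
        for q in (0, 1):
            op = pf.persistent_sheaf_laplacian(shX, shY, q)
            assert kernel_dim(op) == brute_cohomology_restriction_rank(shX, shY, q)


class TestSpectrumAndSummary:
    def test_spectrum_examples(self):
        assert pf.spectrum(np.array([[0.25, 0.0], [0.0, 0.0]])) == pytest.approx([0.0, 0.25])
        assert pf.spectrum(np.zeros((0, 0))).size == 0
        assert pf.spectrum(np.eye(3)) == pytest.approx([1.0, 1.0, 1.0])

    def test_asymmetry_rejected(self):
        with pytest.raises(pf.PslflexError):
            pf.spectrum(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_summary_median_mode(self):
        s = pf.summarize(np.array([0.0, 0.08, 25 / 144]), "median")
        assert s.n_zero == 1
        assert s.max_nz == pytest.approx(25 / 144)
        assert s.min_nz == pytest.approx(0.08)
        assert s.mean_nz == pytest.approx(0.1268055, abs=1e-6)
        assert s.fourth_stat == pytest.approx(0.1268055, abs=1e-6)

    def test_summary_std_mode(self):
        s = pf.summarize(np.array([0.0, 1.0, 3.0]), "std")
        assert s.fourth_stat == pytest.approx(1.0)

    def test_summary_degenerate_cases(self):
        empty = pf.summarize(np.zeros(0))
        assert (empty.n_zero, empty.max_nz, empty.min_nz, empty.mean_nz, empty.fourth_stat) == (0, 0, 0, 0, 0)
        zeros = pf.summarize(np.zeros(3))
        assert zeros.n_zero == 3
        assert zeros.max_nz == 0.0

    def test_summary_counts_are_consistent(self):
        eigs = np.array([0.0, 0.0, 0.5, 1.5])
        s = pf.summarize(eigs)
        assert s.n_zero + 2 == eigs.size
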