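"""Mesh construction, SPDE precision, projector, ICAR and GMRF sampling."""

import numpy as np
import pytest
import scipy.sparse as sp

from soilrisk.exceptions import MeshError, ValidationError
from soilrisk.spatial import (
    AdjacencyGraph,
    build_mesh,
    icar_precision,
    make_projector,
    matern_correlation,
    read_mesh,
    sample_gmrf,
    spde_precision,
    write_mesh,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


class TestMesh:
    def test_interior_edges_respect_max_edge_and_corners_are_vertices(self):
        mesh = build_mesh(UNIT_SQUARE, max_edge=0.5)
        _, lengths, interior = mesh.edge_lengths()
        assert lengths[interior].max() <= 0.5
        for corner in UNIT_SQUARE:
            d = np.linalg.norm(mesh.vertices - corner, axis=1).min()
            assert d < 1e-9

    def test_extension_ring_is_coarser_but_bounded(self):
        mesh = build_mesh(UNIT_SQUARE, max_edge=0.5, extension_factor=2.0)
        _, lengths, interior = mesh.edge_lengths()
        ext = ~interior
        assert ext.any()
        assert lengths[ext].max() <= 2.0 * 0.5 * 1.2  # slack for bridge edges

    def test_every_input_point_is_covered(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, size=(40, 2))
        mesh = build_mesh(pts, max_edge=1.0)
        idx, w = mesh.locate(pts)
        assert np.all(idx >= 0)
        assert np.allclose(w.sum(axis=1), 1.0)

    def test_refinement_scaling(self):
        # halving the edge budget roughly quadruples the interior triangle
        # count; the lattice covers a fixed box, so endpoint rounding keeps
        # the exact ratio slightly below 4
        coarse = build_mesh(UNIT_SQUARE * 10, max_edge=2.0)
        fine = build_mesh(UNIT_SQUARE * 10, max_edge=1.0)
        n_int_coarse = (~coarse.is_extension[coarse.triangles].any(axis=1)).sum()
        n_int_fine = (~fine.is_extension[fine.triangles].any(axis=1)).sum()
        assert n_int_fine >= 3.2 * n_int_coarse

    def test_collinear_points_error(self):
        with pytest.raises(MeshError, match="collinear"):
            build_mesh(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
                       max_edge=0.5)

    def test_vertex_cap(self):
        with pytest.raises(MeshError, match="max_edge"):
            build_mesh(UNIT_SQUARE * 100, max_edge=0.1, max_vertices=500)

    def test_csv_round_trip(self, tmp_path):
        mesh = build_mesh(UNIT_SQUARE, max_edge=0.5)
        write_mesh(mesh, tmp_path / "v.csv", tmp_path / "t.csv")
        back = read_mesh(tmp_path / "v.csv", tmp_path / "t.csv")
        assert np.allclose(back.vertices, mesh.vertices)
        assert np.array_equal(back.triangles, mesh.triangles)
        assert np.array_equal(back.is_extension, mesh.is_extension)


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(UNIT_SQUARE * 4, max_edge=1.0)


class TestProjector:
    def test_vertex_location_gets_unit_weight(self, mesh):
        v = mesh.vertices[10]
        proj = make_projector(mesh, [v])
        row = proj.matrix.toarray()[0]
        assert row.max() == pytest.approx(1.0)
        assert np.count_nonzero(row > 1e-12) == 1

    def test_centroid_gets_equal_thirds(self, mesh):
        tri = mesh.triangles[5]
        centroid = mesh.vertices[tri].mean(axis=0)
        proj = make_projector(mesh, [centroid])
        weights = np.sort(proj.matrix.toarray()[0][tri])
        assert np.allclose(weights, 1 / 3, atol=1e-9)

    def test_rows_sum_to_one_with_at_most_three_entries(self, mesh):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0.2, 3.8, size=(60, 2))
        proj = make_projector(mesh, pts)
        a = proj.matrix
        assert np.allclose(np.asarray(a.sum(axis=1)).ravel(), 1.0, atol=1e-12)
        assert np.all(np.diff(a.indptr) <= 3)
        assert a.data.min() >= -1e-12

    def test_affine_fields_reproduce_exactly(self, mesh):
        field = 2.0 + 3.0 * mesh.vertices[:, 0] - 1.5 * mesh.vertices[:, 1]
        rng = np.random.default_rng(2)
        pts = rng.uniform(0.3, 3.7, size=(50, 2))
        proj = make_projector(mesh, pts)
        expected = 2.0 + 3.0 * pts[:, 0] - 1.5 * pts[:, 1]
        assert np.allclose(proj.project(field), expected, atol=1e-9)

    def test_outside_point_errors(self, mesh):
        with pytest.raises(MeshError, match="outside"):
            make_projector(mesh, [[1000.0, 1000.0]])


class TestSpde:
    def test_precision_is_symmetric_sparse(self):
        mesh = build_mesh(UNIT_SQUARE * 10, max_edge=1.5)
        field = spde_precision(mesh, range_=3.0, sigma=1.0)
        q = field.precision
        assert (q != q.T).nnz == 0
        # non-zeros only for mesh neighbours up to second order
        assert q.nnz / q.shape[0] < 25

    def test_correlation_and_sd_match_closed_form(self):
        # moderate mesh; the acceptance suite runs the fine-mesh version
        mesh = build_mesh(UNIT_SQUARE * 10, max_edge=0.6,
                          extension_width=6.0)
        field = spde_precision(mesh, range_=3.0, sigma=1.0)
        cov = np.linalg.inv(field.precision.toarray())
        sd = np.sqrt(np.diag(cov))
        v = mesh.vertices
        inner = np.where((v[:, 0] > 2) & (v[:, 0] < 8)
                         & (v[:, 1] > 2) & (v[:, 1] < 8))[0]
        assert np.all(np.abs(sd[inner] - 1.0) < 0.1)
        rng = np.random.default_rng(3)
        pairs = rng.choice(inner, size=(200, 2))
        for a, b in pairs:
            d = np.linalg.norm(v[a] - v[b])
            if 0.5 <= d <= 6.0:
                emp = cov[a, b] / (sd[a] * sd[b])
                assert abs(emp - matern_correlation(d, 3.0)) < 0.07


class TestIcar:
    def test_path_graph_structure_matrix(self):
        g = AdjacencyGraph(["1", "2", "3"], [("1", "2"), ("2", "3")])
        q = icar_precision(g).toarray()
        assert np.array_equal(q, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_row_sums_zero_and_rank(self):
        g = AdjacencyGraph(list("abcde"),
                           [("a", "b"), ("b", "c"), ("d", "e")])
        q = icar_precision(g).toarray()
        assert np.allclose(q.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(q) == 5 - 2
        assert g.n_components == 2

    def test_diagonal_dominance_and_symmetry(self):
        g = AdjacencyGraph(["1", "2", "3", "4"],
                           [("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")])
        q = icar_precision(g).toarray()
        assert np.allclose(q, q.T)
        assert np.all(np.diag(q) >= np.sum(np.abs(q), axis=1) - np.diag(q) - 1e-12)


class TestSampleGmrf:
    def test_identity_precision_reproducible(self):
        x1 = sample_gmrf(np.eye(5), seed=42)
        x2 = sample_gmrf(np.eye(5), seed=42)
        assert np.array_equal(x1, x2)
        assert x1.shape == (5,)

    def test_icar_constraint_sums_to_zero(self):
        g = AdjacencyGraph(list("abcdef"),
                           [("a", "b"), ("b", "c"), ("c", "a"),
                            ("d", "e"), ("e", "f")])
        q = icar_precision(g)
        comps = [np.where(g.component_labels == k)[0] for k in range(2)]
        x = sample_gmrf(q, seed=1, constraint=comps)
        for idx in comps:
            assert abs(x[idx].sum()) < 1e-10

    def test_marginal_sd_matches_precision(self):
        draws = sample_gmrf(sp.diags([4.0] * 3), seed=2, n_draws=10000)
        sds = draws.std(axis=0)
        mc_sd = 0.5 / np.sqrt(2 * (10000 - 1))  # sd of a sample sd
        assert np.all(np.abs(sds - 0.5) < 3 * 0.5 / np.sqrt(2 * 9999) + 3 * mc_sd)

    def test_improper_without_constraint_errors(self):
        g = AdjacencyGraph(["1", "2"], [("1", "2")])
        with pytest.raises(ValidationError, match="constraint"):
            sample_gmrf(icar_precision(g), seed=0)

    def test_indefinite_errors(self):
        with pytest.raises(ValidationError, match="indefinite"):
            sample_gmrf(np.diag([1.0, -1.0]), seed=0)


class TestMaternCorrelation:
    def test_limit_at_zero(self):
        assert matern_correlation(0.0, 2.0) == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20, 200)
        r = matern_correlation(d, 4.0)
        assert np.all(np.diff(r) < 0)

    def test_practical_range_convention(self):
        from scipy.special import k1 as bessel_k1
        expected = np.sqrt(8) * bessel_k1(np.sqrt(8))
        assert matern_correlation(5.0, 5.0) == pytest.approx(expected)
        assert 0.10 < expected < 0.15

    def test_invalid_range(self):
        with pytest.raises(ValidationError):
            matern_correlation(1.0, -1.0)


class TestAdjacencyGraph:
    def test_duplicate_edges_collapse(self):
        g = AdjacencyGraph(["A", "B", "C"],
                           [("A", "B"), ("B", "A"), ("B", "C")])
        assert len(g.edges) == 2
        assert list(g.degrees()) == [1, 2, 1]

    def test_unknown_town_errors(self):
        with pytest.raises(ValidationError, match="Z"):
            AdjacencyGraph(["A", "B"], [("A", "Z")])

    def test_self_loop_errors(self):
        with pytest.raises(ValidationError, match="self-loop"):
            AdjacencyGraph(["A", "B"], [("A", "A")])
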