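"""Mesh construction, stiffness/membrane matrices, load vector, gamma."""

import numpy as np
import pytest
import scipy.linalg
from shapely.geometry import Polygon

from memfem.assembly import (
    BoundaryCondition,
    assemble_laplace,
    assemble_load,
    assemble_membrane_matrix,
    build_system,
    build_uniform_mesh,
    epsilon_of,
    gamma_of,
    membrane_area_fractions,
)
from memfem.geometry import (
    MembraneGeometry,
    exact_membrane_area,
    make_cell,
    membrane_polygon,
    place_cells,
)

BC_FLUX = BoundaryCondition.horizontal_flux_injection()


class TestBoundaryCondition:
    def test_every_edge_must_be_assigned_once(self):
        with pytest.raises(ValueError, match="unassigned"):
            BoundaryCondition(dirichlet={"left": 0.0}, neumann={"top": 0.0})
        with pytest.raises(ValueError, match="both"):
            BoundaryCondition(
                dirichlet={"left": 0.0},
                neumann={"left": 0.0, "right": 0.0, "top": 0.0, "bottom": 0.0},
            )

    def test_pure_neumann_rejected(self):
        with pytest.raises(ValueError, match="Dirichlet"):
            BoundaryCondition(
                dirichlet={},
                neumann={e: 0.0 for e in ("left", "right", "top", "bottom")},
            )


class TestMesh:
    def test_counts_and_mesh_size(self):
        mesh = build_uniform_mesh(2, bc=BC_FLUX)
        assert mesh.nodes.shape == (9, 2)
        assert mesh.triangles.shape == (8, 3)
        assert mesh.h == pytest.approx(0.1)

    def test_dirichlet_right_edge_has_column_of_nodes(self):
        mesh = build_uniform_mesh(4, bc=BC_FLUX)
        assert mesh.dirichlet_nodes.size == 5
        np.testing.assert_allclose(mesh.nodes[mesh.dirichlet_nodes, 0], 0.1)
        assert mesh.free_nodes.size + 5 == 25

    def test_node_partition_is_disjoint_and_complete(self):
        mesh = build_uniform_mesh(6, bc=BoundaryCondition.horizontal_injection())
        both = np.concatenate([mesh.free_nodes, mesh.dirichlet_nodes])
        np.testing.assert_array_equal(np.sort(both), np.arange(49))

    def test_triangles_positively_oriented_with_equal_areas(self):
        mesh = build_uniform_mesh(5, bc=BC_FLUX)
        p = mesh.nodes[mesh.triangles]
        cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        np.testing.assert_allclose(0.5 * cross, mesh.h**2 / 2, rtol=1e-12)

    def test_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="N"):
            build_uniform_mesh(1, bc=BC_FLUX)


class TestLaplace:
    def test_interior_row_is_five_point_stencil(self):
        N = 4
        mesh = build_uniform_mesh(N, bc=BC_FLUX)
        K = assemble_laplace(mesh, full=True).toarray()
        c = 2 * (N + 1) + 2  # node (2, 2), interior
        row = K[c]
        assert row[c] == pytest.approx(4.0)
        for nb in (c - 1, c + 1, c - (N + 1), c + (N + 1)):
            assert row[nb] == pytest.approx(-1.0)
        # couplings along the split diagonal cancel exactly
        assert row[c + (N + 1) + 1] == pytest.approx(0.0, abs=1e-14)
        assert row[c - (N + 1) - 1] == pytest.approx(0.0, abs=1e-14)
        assert abs(row).sum() == pytest.approx(8.0)

    def test_symmetric_with_zero_row_sums(self):
        mesh = build_uniform_mesh(6, bc=BC_FLUX)
        K = assemble_laplace(mesh, full=True)
        assert (K - K.T).nnz == 0 or abs(K - K.T).max() < 1e-14
        np.testing.assert_allclose(np.asarray(K.sum(axis=1)).ravel(), 0.0, atol=1e-13)

    def test_positive_definite_on_free_nodes(self):
        mesh = build_uniform_mesh(4, bc=BC_FLUX)
        K = assemble_laplace(mesh).toarray()
        assert np.linalg.eigvalsh(K).min() > 0


class TestMembraneMatrix:
    def test_degenerate_cases_give_zero_matrix(self, geom1):
        mesh = build_uniform_mesh(8, bc=BC_FLUX)
        assert assemble_membrane_matrix(mesh, geom1, 1.0, 1.0).nnz == 0
        empty = MembraneGeometry(cells=())
        assert assemble_membrane_matrix(mesh, empty, 1.0, 0.001).nnz == 0

    def test_sigma_ordering_enforced(self, geom1):
        mesh = build_uniform_mesh(8, bc=BC_FLUX)
        with pytest.raises(ValueError, match="sigma"):
            assemble_membrane_matrix(mesh, geom1, 0.001, 1.0)

    @pytest.mark.parametrize("n_holes", [0, 2, 4])
    def test_quadrature_area_matches_polygon_oracle(self, n_holes):
        orient = "horizontal" if n_holes == 2 else "compass"
        geom = MembraneGeometry(
            cells=(make_cell((0, 0), n_holes=n_holes, orientation=orient),)
        )
        mesh = build_uniform_mesh(16, bc=BC_FLUX)
        _, fr = membrane_area_fractions(mesh, geom)
        total = float(fr.sum()) * mesh.h**2 / 2
        assert total == pytest.approx(exact_membrane_area(geom), rel=1e-3)

    def test_quadrature_converges_to_clipping_per_triangle(self, geom1, rng):
        """Composite-rule area fractions approach the clipped exact values."""
        mesh = build_uniform_mesh(16, bc=BC_FLUX)
        poly = membrane_polygon(geom1, quad_segs=512)
        idx, _ = membrane_area_fractions(mesh, geom1, 8)
        sel = rng.choice(idx, size=min(50, idx.size), replace=False)
        exact = {}
        for t in sel:
            tri = Polygon(mesh.nodes[mesh.triangles[t]])
            exact[t] = poly.intersection(tri).area / tri.area
        mean_errs = []
        for level in (2, 4, 6, 8):
            i, fr = membrane_area_fractions(mesh, geom1, level)
            fmap = dict(zip(i, fr))
            mean_errs.append(
                np.mean([abs(fmap.get(t, 0.0) - exact[t]) for t in sel])
            )
        assert all(a > b for a, b in zip(mean_errs, mean_errs[1:]))
        assert mean_errs[-1] < 1e-4

    def test_membrane_bounded_by_gamma_times_laplace(self, geom1):
        """Generalised eigenvalues of (K_tilde, K) stay below gamma*(s0-sA)."""
        sigma0, sigmaA = 1.0, 0.001
        for N in (8, 16):
            mesh = build_uniform_mesh(N, bc=BC_FLUX)
            K = assemble_laplace(mesh).toarray()
            Kt = assemble_membrane_matrix(mesh, geom1, sigma0, sigmaA).toarray()
            ev = scipy.linalg.eigh(Kt, K, eigvals_only=True)
            gamma = gamma_of(mesh, geom1)
            assert ev.min() >= -1e-10
            assert ev.max() <= gamma * (sigma0 - sigmaA) * (1 + 1e-8)

    def test_assembly_deterministic(self, geom1, bc_h):
        a = build_system(geom1, bc_h, 16)
        b = build_system(geom1, bc_h, 16)
        assert (a.K != b.K).nnz == 0
        assert (a.K_tilde != b.K_tilde).nnz == 0
        np.testing.assert_array_equal(a.g, b.g)


class TestLoad:
    def test_zero_data_gives_zero_vector(self):
        bc = BoundaryCondition(
            dirichlet={"right": 0.0}, neumann={"left": 0.0, "top": 0.0, "bottom": 0.0}
        )
        sys_ = build_system(MembraneGeometry(cells=()), bc, 8)
        np.testing.assert_array_equal(sys_.g, 0.0)

    def test_unit_flux_entries_are_hat_integrals(self):
        """g_N = 1 on the left edge: h per edge node, h/2 at its corners."""
        N = 8
        sys_ = build_system(MembraneGeometry(cells=()), BC_FLUX, N)
        mesh = sys_.mesh
        h = mesh.h
        g_full = np.zeros(mesh.n_nodes)
        g_full[mesh.free_nodes] = sys_.g
        left = mesh.edge_nodes("left")
        np.testing.assert_allclose(g_full[left[1:-1]], h, rtol=1e-12)
        np.testing.assert_allclose(g_full[[left[0], left[-1]]], h / 2, rtol=1e-12)
        mask = np.ones(mesh.n_nodes, bool)
        mask[left] = False
        np.testing.assert_allclose(g_full[mask], 0.0, atol=1e-15)

    def test_linear_dirichlet_data_reproduced_exactly(self):
        """P1 exactness: pure Dirichlet g_D = x yields U_j = x_j."""
        lin = lambda x, y: x
        bc = BoundaryCondition(
            dirichlet={e: lin for e in ("left", "right", "top", "bottom")},
            neumann={},
        )
        sys_ = build_system(MembraneGeometry(cells=()), bc, 12)
        U = np.linalg.solve(sys_.K.toarray(), sys_.g)
        np.testing.assert_allclose(
            U, sys_.mesh.nodes[sys_.mesh.free_nodes, 0], atol=1e-13
        )


class TestGammaEpsilon:
    def test_gamma_empty_geometry_is_zero(self):
        mesh = build_uniform_mesh(8, bc=BC_FLUX)
        assert gamma_of(mesh, MembraneGeometry(cells=())) == 0.0

    def test_gamma_scale_at_coarse_mesh(self, geom1):
        """At N=16 gamma sits at the thickness-to-mesh ratio scale."""
        mesh = build_uniform_mesh(16, bc=BC_FLUX)
        g = gamma_of(mesh, geom1)
        assert 0.04 <= g <= 0.3

    @pytest.mark.parametrize("N", [8, 16, 32, 64])
    def test_gamma_bounded_by_one_and_grows_with_refinement(self, N, geom1):
        mesh = build_uniform_mesh(N, bc=BC_FLUX)
        g = gamma_of(mesh, geom1)
        assert 0.0 < g <= 1.0
        if N > 8:
            coarse = gamma_of(build_uniform_mesh(N // 2, bc=BC_FLUX), geom1)
            assert g > coarse

    def test_epsilon_examples(self):
        assert epsilon_of(1.0, 0.001) == pytest.approx(0.001)
        assert epsilon_of(5.0, 5.0) == 1.0
        assert epsilon_of(2.0, 1.0) == 0.5
        with pytest.raises(ValueError):
            epsilon_of(0.0, 1.0)
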