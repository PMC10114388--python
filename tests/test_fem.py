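"""Element stiffness, assembly, solve, and stress recovery."""

import numpy as np
import pytest
import scipy.sparse as sp

import ligafem as lf
from ligafem.fem import elastic_moduli, strain_displacement
from ligafem.mesh import UM

from conftest import make_bar

COLLAGEN = lf.TABLE_MATERIALS["collagen"]


def element_stiffness_oracle(material, h, order=5):
    """Independent brute-force B' D B quadrature using symbolic gradients.

    Shape functions are rebuilt from scratch with sympy and differentiated
    exactly; the integral is evaluated with a high-order Gauss-Legendre rule.
    """
    import sympy as sym

    xi, eta, zeta = sym.symbols("xi eta zeta")
    signs = [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ]
    shapes = [
        (1 + sx * xi) * (1 + sy * eta) * (1 + sz * zeta) / 8
        for sx, sy, sz in signs
    ]
    grads = sym.lambdify(
        (xi, eta, zeta),
        [[sym.diff(n, v) for v in (xi, eta, zeta)] for n in shapes],
    )
    hx, hy, hz = np.broadcast_to(np.asarray(h, dtype=float), (3,))
    d = elastic_moduli(material)
    pts, wts = np.polynomial.legendre.leggauss(order)
    ke = np.zeros((24, 24))
    detj = hx * hy * hz / 8.0
    for px, wx in zip(pts, wts):
        for py, wy in zip(pts, wts):
            for pz, wz in zip(pts, wts):
                g = np.array(grads(px, py, pz)) * (2.0 / np.array([hx, hy, hz]))
                b = np.zeros((6, 24))
                for a in range(8):
                    dx, dy, dz = g[a]
                    c = 3 * a
                    b[0, c] = dx
                    b[1, c + 1] = dy
                    b[2, c + 2] = dz
                    b[3, c] = dy
                    b[3, c + 1] = dx
                    b[4, c + 1] = dz
                    b[4, c + 2] = dy
                    b[5, c] = dz
                    b[5, c + 2] = dx
                ke += wx * wy * wz * detj * (b.T @ d @ b)
    return ke


class TestElementStiffness:
    def test_symmetry_and_psd(self):
        ke = lf.element_stiffness(COLLAGEN, 4e-6)
        assert np.allclose(ke, ke.T, rtol=0, atol=1e-18 * np.abs(ke).max())
        assert np.linalg.eigvalsh(ke).min() > -1e-10 * np.abs(ke).max()

    def test_rigid_body_nullspace_is_six_dimensional(self):
        ke = lf.element_stiffness(lf.Material("m", 1.0, 0.0), 1.0)
        w = np.linalg.eigvalsh(ke)
        assert np.count_nonzero(w < 1e-10 * w.max()) == 6

    def test_translations_map_to_zero(self):
        ke = lf.element_stiffness(lf.Material("m", 1.0, 0.0), 1.0)
        for comp in range(3):
            t = np.zeros(24)
            t[comp::3] = 1.0
            assert np.abs(ke @ t).max() < 1e-14 * np.abs(ke).max()

    def test_linearized_rotations_map_to_zero(self):
        h = (2e-6, 3e-6, 4e-6)
        ke = lf.element_stiffness(COLLAGEN, h)
        corners = np.array(
            [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
             (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
            dtype=float,
        ) * np.asarray(h)
        rot = np.stack(
            [np.zeros(8), -corners[:, 2], corners[:, 1]], axis=1
        ).ravel()  # u = (0, -z, y)
        assert np.abs(ke @ rot).max() < 1e-10 * np.abs(ke).max() * np.abs(rot).max()

    @pytest.mark.parametrize("h", [4e-6, (4e-6, 3.875e-6, 4e-6)])
    def test_matches_brute_force_quadrature_oracle(self, h):
        ke = lf.element_stiffness(COLLAGEN, h)
        oracle = element_stiffness_oracle(COLLAGEN, h)
        scale = np.abs(oracle).max()
        assert np.abs(ke - oracle).max() < 1e-12 * scale

    def test_incompressible_limit_rejected(self):
        with pytest.raises(lf.MaterialError):
            lf.Material("water", 1.0, 0.5)
        m = lf.Material("ok", 1.0, 0.49)
        object.__setattr__(m, "poisson_ratio", 0.5)  # bypass the dataclass guard
        with pytest.raises(lf.MaterialError):
            elastic_moduli(m)


class TestAssembly:
    def test_single_element_equals_element_stiffness(self):
        mesh = make_bar(n=(1, 1, 1))
        k = lf.assemble(mesh, lf.TABLE_MATERIALS).toarray()
        ke = lf.element_stiffness(COLLAGEN, mesh.spacing)
        # map element dof order to global: single element, nodes 0..7
        edof = (3 * mesh.elements[0][:, None] + np.arange(3)).ravel()
        assert np.allclose(k[np.ix_(edof, edof)], ke, rtol=1e-14)

    def test_two_material_bar_matches_series_springs(self):
        """End-to-end stiffness of a two-element bimaterial bar equals the
        series-spring value E1*A/L1 in series with E2*A/L2 (nu = 0)."""
        m1 = lf.Material("collagen", 8.9e6, 0.0)
        m2 = lf.Material("elastin", 4.0e6, 0.0)
        g = lf.ModelGeometry(
            [
                lf.Prism("collagen", (0, 0, 0), (4.0, 4.0, 4.0)),
                lf.Prism("elastin", (4.0, 0, 0), (4.0, 4.0, 4.0)),
            ],
            "fibre",
            0,
            materials={"collagen": m1, "elastin": m2},
        )
        mesh = lf.voxelize(g, 4.0)
        k = lf.assemble(mesh, g.materials)
        ndof = 3 * mesh.n_nodes
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        right = np.nonzero(np.isclose(mesh.nodes[:, 0], 8e-6))[0]
        bcs = lf.BoundaryConditions(ndof)
        bcs.fix(left, [0, 1, 2])
        bcs.fix(np.setdiff1d(np.arange(mesh.n_nodes), left), [1, 2])
        force = 1e-9
        bcs.add_nodal_forces(right, np.tile([force / 4, 0, 0], (4, 1)))
        u, _ = lf.solve(k, bcs)
        a = (4e-6) ** 2
        l = 4e-6
        k_series = 1.0 / (l / (m1.young_modulus * a) + l / (m2.young_modulus * a))
        assert u[right, 0].mean() == pytest.approx(force / k_series, rel=1e-10)

    def test_assembly_permutation_invariant(self):
        mesh = make_bar(n=(3, 1, 1))
        k1 = lf.assemble(mesh, lf.TABLE_MATERIALS)
        perm = np.array([2, 0, 1])
        from dataclasses import replace

        mesh2 = replace(
            mesh,
            elements=mesh.elements[perm],
            element_material=mesh.element_material[perm],
            elem_ijk=mesh.elem_ijk[perm],
        )
        k2 = lf.assemble(mesh2, lf.TABLE_MATERIALS)
        assert abs(k1 - k2).max() < 1e-12 * abs(k1).max()

    def test_unknown_material_label_rejected(self):
        mesh = make_bar(n=(1, 1, 1))
        with pytest.raises(KeyError):
            lf.assemble(mesh, {"bone": lf.TABLE_MATERIALS["bone"]})


def _uniaxial_bar_solution(mesh, t=0.15, material=COLLAGEN, materials=None):
    """Symmetric-BC uniaxial traction solve on a single-material bar."""
    materials = materials or {material.name: material, "collagen": material}
    k = lf.assemble(mesh, materials)
    ndof = 3 * mesh.n_nodes
    bcs = lf.BoundaryConditions(ndof)
    x, y, z = mesh.nodes.T
    bcs.fix(np.nonzero(np.isclose(x, 0.0))[0], [0])
    bcs.fix(np.nonzero(np.isclose(y, 0.0))[0], [1])
    bcs.fix(np.nonzero(np.isclose(z, 0.0))[0], [2])
    xmax = x.max()
    face = np.nonzero(np.isclose(x, xmax))[0]
    hy, hz = mesh.spacing[1], mesh.spacing[2]
    area = (y.max() - y.min()) * (z.max() - z.min())
    # consistent quarter-split of the uniform traction over the face quads
    quads = mesh.elements[
        np.nonzero(np.isclose(mesh.nodes[mesh.elements[:, 1], 0], xmax))[0]
    ][:, [1, 2, 5, 6]]
    f = np.zeros(ndof)
    np.add.at(f, 3 * quads.ravel(), t * hy * hz / 4.0)
    bcs.f = f
    u, r = lf.solve(k, bcs)
    return k, bcs, u, r, face, area


class TestSolve:
    def test_uniaxial_bar_strain_is_stress_over_modulus(self, bar_mesh):
        t = 0.15
        _, _, u, _, face, _ = _uniaxial_bar_solution(bar_mesh, t)
        length = bar_mesh.nodes[:, 0].max()
        strain = u[face, 0].mean() / length
        assert strain == pytest.approx(t / COLLAGEN.young_modulus, rel=1e-9)
        # 0.15 Pa on collagen: 1.685e-8, as a printed cross-check
        assert strain == pytest.approx(1.685e-8, rel=1e-3)

    def test_linear_patch_test(self):
        """An affine field prescribed on the whole boundary is reproduced
        exactly at interior nodes."""
        mesh = make_bar(n=(3, 3, 3))
        k = lf.assemble(mesh, lf.TABLE_MATERIALS)
        a = np.array([[2.0, 0.5, -0.3], [0.1, -1.0, 0.7], [0.4, 0.2, 1.5]]) * 1e-3
        b = np.array([1.0, -2.0, 0.5]) * 1e-9
        exact = mesh.nodes @ a.T + b
        x, y, z = mesh.nodes.T
        boundary = (
            np.isclose(x, x.min()) | np.isclose(x, x.max())
            | np.isclose(y, y.min()) | np.isclose(y, y.max())
            | np.isclose(z, z.min()) | np.isclose(z, z.max())
        )
        bnodes = np.nonzero(boundary)[0]
        bcs = lf.BoundaryConditions(3 * mesh.n_nodes)
        for comp in range(3):
            bcs.fix(bnodes, [comp], exact[bnodes, comp])
        u, _ = lf.solve(k, bcs)
        assert np.abs(u - exact).max() < 1e-10 * np.abs(exact).max()

    def test_linearity_in_load(self, bar_mesh):
        _, bcs, u1, _, _, _ = _uniaxial_bar_solution(bar_mesh, 0.15)
        _, _, u2, _, _, _ = _uniaxial_bar_solution(bar_mesh, 0.30)
        assert np.allclose(2 * u1, u2, rtol=1e-12, atol=1e-25)

    def test_force_balance(self, bar_mesh):
        t = 0.15
        _, bcs, u, r, _, area = _uniaxial_bar_solution(bar_mesh, t)
        applied = bcs.f.reshape(-1, 3).sum(axis=0)
        total = r.sum(axis=0) + applied
        assert np.abs(total).max() < 1e-8 * np.abs(applied).max()

    def test_energy_consistency(self, bar_mesh):
        k, bcs, u, _, _, _ = _uniaxial_bar_solution(bar_mesh)
        uf = u.ravel()
        strain_energy = 0.5 * uf @ (k @ uf)
        external_work = 0.5 * bcs.f @ uf
        assert strain_energy == pytest.approx(external_work, rel=1e-9)

    def test_under_constrained_system_rejected(self, bar_mesh):
        k = lf.assemble(bar_mesh, lf.TABLE_MATERIALS)
        bcs = lf.BoundaryConditions(3 * bar_mesh.n_nodes)
        bcs.fix(np.array([0]), [0])  # one dof: five rigid modes remain
        bcs.f[-1] = 1.0
        with pytest.raises(lf.UnderConstrainedError):
            lf.solve(k, bcs)


class TestStressRecovery:
    def test_uniform_bar_stress_equals_traction(self, bar_mesh):
        t = 0.15
        _, _, u, _, _, _ = _uniaxial_bar_solution(bar_mesh, t)
        stress = lf.recover_stress(bar_mesh, lf.TABLE_MATERIALS, u)
        assert np.allclose(stress["sigma"][:, 0], t, rtol=1e-9)
        assert np.allclose(stress["von_mises"], t, rtol=1e-9)
        assert np.abs(stress["sigma"][:, 1:]).max() < 1e-9 * t

    def test_hydrostatic_field_has_zero_von_mises(self, bar_mesh):
        alpha = 1e-4
        u = alpha * bar_mesh.nodes  # pure dilation
        stress = lf.recover_stress(bar_mesh, lf.TABLE_MATERIALS, u)
        assert np.abs(stress["von_mises"]).max() < 1e-12 * np.abs(
            stress["sigma"][:, 0]
        ).max()

    def test_rigid_rotation_has_exactly_zero_stress(self, bar_mesh):
        theta = 1e-3
        y, z = bar_mesh.nodes[:, 1], bar_mesh.nodes[:, 2]
        u = np.stack([np.zeros_like(y), -theta * z, theta * y], axis=1)
        stress = lf.recover_stress(bar_mesh, lf.TABLE_MATERIALS, u)
        scale = COLLAGEN.young_modulus * theta
        assert np.abs(stress["sigma"]).max() < 1e-14 * scale

    def test_von_mises_invariants(self):
        assert lf.von_mises(np.array([[5.0, 5.0, 5.0, 0, 0, 0]]))[0] == 0.0
        assert lf.von_mises(np.array([[3.0, 0, 0, 0, 0, 0]]))[0] == pytest.approx(3.0)
        assert lf.von_mises(np.array([[0, 0, 0, 2.0, 0, 0]]))[0] == pytest.approx(
            2.0 * np.sqrt(3)
        )


class TestFrameBehaviour:
    def test_quarter_turn_about_x_permutes_solution(self):
        """A bar with a 2x1 cross-section loaded in +Y behaves like the
        90-degree-rotated bar (1x2 cross-section) loaded in +Z."""

        def solve_cantilever(ny, nz, direction):
            mesh = make_bar(n=(6, ny, nz))
            k = lf.assemble(mesh, lf.TABLE_MATERIALS)
            x = mesh.nodes[:, 0]
            bcs = lf.BoundaryConditions(3 * mesh.n_nodes)
            bcs.fix(np.nonzero(np.isclose(x, 0.0))[0], [0, 1, 2])
            tip = np.nonzero(np.isclose(x, x.max()))[0]
            fvec = np.zeros(3)
            fvec[direction] = 1e-12 / tip.size
            bcs.add_nodal_forces(tip, np.tile(fvec, (tip.size, 1)))
            u, _ = lf.solve(k, bcs)
            stress = lf.recover_stress(mesh, lf.TABLE_MATERIALS, u)
            return u[tip, direction].mean(), np.sort(stress["von_mises"])

        tip_y, vm_y = solve_cantilever(2, 1, 1)
        tip_z, vm_z = solve_cantilever(1, 2, 2)
        assert tip_y == pytest.approx(tip_z, rel=1e-9)
        assert np.allclose(vm_y, vm_z, rtol=1e-8)


class TestMultigridPath:
    def test_large_system_matches_direct_solver(self):
        """The multigrid-CG route reproduces the direct solution."""
        g = lf.build_fibre_model(
            rows=2, cols=2, fibre_dims=(100.0, 20.0, 20.0),
            n_elastin=8, bone_thickness=8.0,
        )
        mesh = lf.voxelize(g, 4.0)
        k = lf.assemble(mesh, lf.TABLE_MATERIALS)
        fixed = (3 * mesh.nodes_of("bone_fixed")[:, None] + np.arange(3)).ravel()
        xmax = mesh.nodes[:, 0].max()
        face = np.nonzero(np.isclose(mesh.nodes[:, 0], xmax))[0]
        f = np.zeros(k.shape[0])
        f[3 * face + 1] = 1e-12
        direct = lf.DirichletSystem(k, fixed, node_ijk=mesh.node_ijk())
        assert direct.lu is not None
        u1, _ = direct.solve(f)
        # force the iterative route by lowering the size threshold
        old = lf.DirichletSystem.DIRECT_LIMIT
        lf.DirichletSystem.DIRECT_LIMIT = 1
        try:
            itsys = lf.DirichletSystem(k, fixed, node_ijk=mesh.node_ijk())
            assert itsys.mg is not None
            u2, _ = itsys.solve(f)
        finally:
            lf.DirichletSystem.DIRECT_LIMIT = old
        assert np.abs(u2 - u1).max() < 1e-8 * np.abs(u1).max()
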