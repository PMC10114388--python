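"""Small-strain linear elastostatics on voxel hexahedral meshes.

Standard isotropic trilinear (8-node) hexahedra with full 2x2x2 Gauss
integration, sparse assembly, Dirichlet elimination (direct factorization
for small systems, multigrid-preconditioned CG beyond ~70k DOF), and
centroid stress recovery (Cauchy stress in Voigt order xx, yy, zz, xy, yz,
zx, engineering shear strains).

Displacement DOFs are node-major: dof = 3 * node + component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import MaterialError, UnderConstrainedError
from .geometry import Material
from .mesh import HexMesh

__all__ = [
    "BoundaryConditions",
    "DisplacementField",
    "StressField",
    "element_stiffness",
    "assemble",
    "solve",
    "DirichletSystem",
    "recover_stress",
    "von_mises",
]

# corner signs matching the VTK hexahedron node order of ligafem.mesh
_XI = np.array(
    [
        (-1, -1, -1),
        (1, -1, -1),
        (1, 1, -1),
        (-1, 1, -1),
        (-1, -1, 1),
        (1, -1, 1),
        (1, 1, 1),
        (-1, 1, 1),
    ],
    dtype=float,
)


def elastic_moduli(material: Material) -> np.ndarray:
    """6x6 isotropic elasticity matrix D (Voigt, engineering shear)."""
    e, nu = material.young_modulus, material.poisson_ratio
    if nu >= 0.5:
        raise MaterialError("Poisson ratio must be < 0.5 for a compressible solid")
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = lam + 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


def _shape_gradients(xi: np.ndarray, h: np.ndarray) -> np.ndarray:
    """(8, 3) physical gradients dN_a/dx at a parent point xi in [-1,1]^3."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _XI[a]
        g[a, 0] = sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8.0
        g[a, 1] = sy * (1 + sx * xi[0]) * (1 + sz * xi[2]) / 8.0
        g[a, 2] = sz * (1 + sx * xi[0]) * (1 + sy * xi[1]) / 8.0
    return g * (2.0 / h)  # chain rule for the box element


def strain_displacement(xi: np.ndarray, h: np.ndarray) -> np.ndarray:
    """6x24 B matrix at parent point ``xi`` for a box element of size ``h`` (m)."""
    g = _shape_gradients(np.asarray(xi, dtype=float), np.asarray(h, dtype=float))
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
    return b


def element_stiffness(material: Material, h) -> np.ndarray:
    """24x24 stiffness of one axis-aligned box element (edge lengths ``h``, m).

    Full 2x2x2 Gauss quadrature, which integrates the trilinear stiffness
    exactly for a constant-Jacobian box.  The matrix is symmetric positive
    semi-definite with a 6-dimensional rigid-body nullspace.
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if h.size == 1:
        h = np.repeat(h, 3)
    if np.any(h <= 0):
        raise MaterialError("element edge lengths must be positive")
    d = elastic_moduli(material)
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    detj = np.prod(h) / 8.0
    ke = np.zeros((24, 24))
    for x in gp:
        for y in gp:
            for z in gp:
                b = strain_displacement((x, y, z), h)
                ke += b.T @ d @ b * detj  # unit Gauss weights
    return 0.5 * (ke + ke.T)


def assemble(mesh: HexMesh, materials: dict[str, Material]) -> sp.csr_matrix:
    """Assemble the global sparse stiffness matrix (3N x 3N, CSR)."""
    for lab in mesh.labels:
        if lab not in materials and _strip(lab) not in materials:
            raise KeyError(f"no material defined for mesh label {lab!r}")
    ndof = 3 * mesh.n_nodes
    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
    edof = edof.astype(np.int32)  # halves COO index memory; ndof << 2^31
    rows_parts, cols_parts, data_parts = [], [], []
    for code, lab in enumerate(mesh.labels):
        els = np.nonzero(mesh.element_material == code)[0]
        if els.size == 0:
            continue
        mat = materials.get(lab) or materials[_strip(lab)]
        ke = element_stiffness(mat, mesh.spacing)
        ed = edof[els]
        rows_parts.append(np.repeat(ed, 24, axis=1).ravel())
        cols_parts.append(np.tile(ed, (1, 24)).ravel())
        data_parts.append(np.tile(ke.ravel(), els.size))
    k = sp.coo_matrix(
        (np.concatenate(data_parts), (np.concatenate(rows_parts), np.concatenate(cols_parts))),
        shape=(ndof, ndof),
    ).tocsr()
    return k


def _strip(label: str) -> str:
    """Map bone_fixed/bone_free to the shared 'bone' material key."""
    return "bone" if label.startswith("bone") else label


@dataclass
class BoundaryConditions:
    """Dirichlet constraints plus an assembled external nodal force vector."""

    ndof: int
    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fixed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    f: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.f is None:
            self.f = np.zeros(self.ndof)

    def fix(self, nodes: np.ndarray, components, values=0.0) -> "BoundaryConditions":
        """Prescribe displacement ``values`` on (nodes x components)."""
        nodes = np.asarray(nodes, dtype=np.int64)
        comps = np.atleast_1d(np.asarray(components, dtype=np.int64))
        dofs = (3 * nodes[:, None] + comps[None, :]).ravel()
        vals = np.broadcast_to(np.asarray(values, dtype=float), dofs.shape).ravel()
        dofs = np.concatenate([self.fixed_dofs, dofs])
        vals = np.concatenate([self.fixed_values, vals])
        # keep first occurrence only; a dof may be prescribed at most once
        _, keep = np.unique(dofs, return_index=True)
        self.fixed_dofs = dofs[keep]
        self.fixed_values = vals[keep]
        return self

    def add_nodal_forces(self, nodes: np.ndarray, forces: np.ndarray) -> None:
        """Accumulate per-node force 3-vectors into the global load vector."""
        np.add.at(self.f.reshape(-1, 3), np.asarray(nodes, dtype=np.int64), forces)


DisplacementField = np.ndarray  # (N, 3) nodal displacements, metres
StressField = np.ndarray


class DirichletSystem:
    """Reduced (Dirichlet-eliminated) system with a reusable solver.

    Small systems are factorized directly (SuperLU); larger ones switch to a
    geometric-multigrid-preconditioned conjugate-gradient solver, which
    needs the mesh node grid (``node_ijk``) and whole-node constraints.
    Either way the setup is reused across right-hand sides, so load
    scalings and same-constraint protocols (tensile + shear) are cheap.
    """

    #: above this many DOFs a direct factorization risks exhausting memory
    DIRECT_LIMIT = 70_000

    def __init__(
        self,
        k: sp.csr_matrix,
        fixed_dofs: np.ndarray,
        node_ijk: np.ndarray | None = None,
        rtol: float = 1e-10,  # margin under the 1e-9 residual contract
    ):
        self.k = k
        self.rtol = rtol
        self.fixed = np.unique(np.asarray(fixed_dofs, dtype=np.int64))
        mask = np.ones(k.shape[0], dtype=bool)
        mask[self.fixed] = False
        self.free = np.nonzero(mask)[0]
        kcsc = k.tocsc()
        self.k_ff = kcsc[self.free][:, self.free].tocsc()
        self.k_fc = kcsc[self.free][:, self.fixed]
        self.lu = None
        self.mg = None

        whole_nodes = (
            self.fixed.size % 3 == 0
            and self.fixed.size > 0
            and np.array_equal(
                self.fixed,
                (3 * np.unique(self.fixed // 3)[:, None] + np.arange(3)).ravel(),
            )
        )
        use_mg = (
            self.free.size > self.DIRECT_LIMIT
            and node_ijk is not None
            and whole_nodes
        )
        if use_mg:
            free_nodes = np.nonzero(mask.reshape(-1, 3).all(axis=1))[0]
            from .multigrid import MultigridPreconditioner

            self.mg = MultigridPreconditioner(
                self.k_ff.tocsr(), np.asarray(node_ijk)[free_nodes]
            )
        else:
            try:
                self.lu = spla.splu(self.k_ff)
            except RuntimeError as err:  # exactly singular factor
                raise UnderConstrainedError(
                    f"constrained stiffness is singular: {err}"
                ) from err

    def solve(self, f: np.ndarray, fixed_values: np.ndarray | float = 0.0):
        """Return (u, reactions), both (ndof,) vectors.

        ``fixed_values`` is either a scalar or a *full-length* (ndof,) array
        from which the prescribed entries are taken, which avoids alignment
        bugs with the internally sorted constraint order.
        """
        fixed_values = np.asarray(fixed_values, dtype=float)
        if fixed_values.ndim == 0:
            vals = np.broadcast_to(fixed_values, self.fixed.shape)
        else:
            vals = fixed_values[self.fixed]
        rhs = f[self.free] - self.k_fc @ vals
        if self.lu is not None:
            u_f = self.lu.solve(rhs)
        else:
            u_f = self.mg.cg_solve(self.k_ff, rhs, rtol=self.rtol)
        res = np.linalg.norm(self.k_ff @ u_f - rhs)
        scale = max(np.linalg.norm(rhs), 1e-300)
        if not np.isfinite(u_f).all() or res / scale > 1e-9:
            raise UnderConstrainedError(
                f"reduced solve failed (relative residual {res / scale:.2e}); "
                "the constraints probably leave rigid-body modes"
            )
        u = np.zeros(self.k.shape[0])
        u[self.free] = u_f
        u[self.fixed] = vals
        reactions = self.k @ u - f
        reactions[self.free] = 0.0
        return u, reactions


def solve(
    k: sp.csr_matrix,
    bcs: BoundaryConditions,
    node_ijk: np.ndarray | None = None,
) -> tuple[DisplacementField, np.ndarray]:
    """Solve K u = f under the given constraints.

    Returns nodal displacements (N, 3) and reaction forces (N, 3); reactions
    are nonzero only on constrained DOFs and balance the applied loads.
    """
    system = DirichletSystem(k, bcs.fixed_dofs, node_ijk=node_ijk)
    vals_full = np.zeros(k.shape[0])
    vals_full[bcs.fixed_dofs] = bcs.fixed_values
    u, r = system.solve(bcs.f, vals_full)
    return u.reshape(-1, 3), r.reshape(-1, 3)


def recover_stress(
    mesh: HexMesh, materials: dict[str, Material], u: DisplacementField
) -> dict[str, np.ndarray]:
    """Element-centroid Cauchy stress and von Mises scalar from nodal u.

    Stress is evaluated once per element at the parent-space centre (the
    optimal stress point of the trilinear hexahedron); no nodal
    extrapolation is performed.
    """
    uf = np.asarray(u, dtype=float).reshape(-1, 3)
    b0 = strain_displacement((0.0, 0.0, 0.0), mesh.spacing)
    ue = uf[mesh.elements].reshape(mesh.n_elements, 24)
    eps = ue @ b0.T  # (E, 6) centroid strains
    sigma = np.empty_like(eps)
    for code, lab in enumerate(mesh.labels):
        els = mesh.element_material == code
        if not els.any():
            continue
        mat = materials.get(lab) or materials[_strip(lab)]
        sigma[els] = eps[els] @ elastic_moduli(mat).T
    return {"sigma": sigma, "von_mises": von_mises(sigma)}


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt components (xx,yy,zz,xy,yz,zx)."""
    s = np.asarray(sigma)
    sxx, syy, szz, sxy, syz, szx = s.T
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
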