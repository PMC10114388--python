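"""The three loading protocols: tensile, shear, and 30-degree bone rotation.

All protocols clamp the fixed bone completely.  Tensile and shear apply a
uniform traction on the free bone's outer X face (+X and +Y respectively);
rotation prescribes a linearized rigid rotation of that face about the X
axis through its centroid and recovers the required stresses from the
reaction couple.

Because the reactions of a centroidal rotation form a pure couple (their
net force vanishes by symmetry), the "stress required to rotate" is
expressed as the uniform antisymmetric half-face traction pair that carries
the same torque: sigma_Y = |T_Y| / (A Lz / 4) where T_Y is the part of the
reaction torque about X carried by Y-forces, and likewise sigma_Z with Ly.
Both scale exactly linearly with the prescribed angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError
from .fem import DirichletSystem, assemble, recover_stress
from .geometry import Material, ModelGeometry
from .mesh import HexMesh, UM

__all__ = [
    "LoadCase",
    "LoadResult",
    "LoadRunner",
    "tensile_case",
    "shear_case",
    "rotation_case",
    "DEFAULT_MAGNITUDES",
]

#: nominal protocol magnitudes: tractions in Pa, rotation in degrees
DEFAULT_MAGNITUDES = {"tensile": 0.15, "shear": 0.90e-3, "rotation": 30.0}

# +X face of the VTK hexahedron
_XFACE_CORNERS = np.array([1, 2, 5, 6])


@dataclass(frozen=True)
class LoadCase:
    """One loading protocol: kind and magnitude (Pa, or degrees for rotation)."""

    kind: str
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_MAGNITUDES:
            raise ProtocolError(f"unknown load case kind {self.kind!r}")
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", DEFAULT_MAGNITUDES[self.kind])


@dataclass
class LoadResult:
    """Solved fields and protocol-specific scalars for one load case."""

    case: LoadCase
    mesh: HexMesh
    displacement: np.ndarray  # (N, 3) m
    stress: dict  # {"sigma": (E, 6) Pa, "von_mises": (E,) Pa}
    reactions: np.ndarray  # (N, 3) N
    face_nodes: np.ndarray  # nodes of the loaded/rotated outer face
    applied_force: np.ndarray  # (3,) N, total external load
    global_strain: float | None = None
    sigma_y: float | None = None  # Pa, rotation only
    sigma_z: float | None = None  # Pa, rotation only

    @property
    def balance_residual(self) -> float:
        """Relative force-balance defect |sum reactions + applied| / |applied|."""
        total = self.reactions.sum(axis=0) + self.applied_force
        scale = max(
            float(np.linalg.norm(self.applied_force)),
            float(np.abs(self.reactions).sum(axis=0).max()),
            1e-300,
        )
        return float(np.linalg.norm(total)) / scale


class LoadRunner:
    """Applies the protocols to one meshed model, reusing solver setup.

    The stiffness matrix is assembled once; Dirichlet systems are cached per
    constraint signature, so tensile + shear share one factorization and
    repeated load scalings are nearly free.
    """

    def __init__(
        self,
        geometry: ModelGeometry,
        mesh: HexMesh,
        materials: dict[str, Material] | None = None,
    ):
        for comp in ("bone_fixed", "bone_free"):
            if comp not in mesh.labels or mesh.elements_of(comp).size == 0:
                raise ProtocolError(f"model has no {comp} component to load")
        self.geometry = geometry
        self.mesh = mesh
        self.materials = materials if materials is not None else geometry.materials
        self._k = None
        self._systems: dict[bytes, DirichletSystem] = {}
        self._face = self._outer_face()

    # -- plumbing ----------------------------------------------------------

    @property
    def k(self):
        if self._k is None:
            self._k = assemble(self.mesh, self.materials)
        return self._k

    def _outer_face(self):
        """Face quads (element ids + node ids) of the free bone's outer X face."""
        mesh = self.mesh
        xmax = mesh.nodes[:, 0].max()
        els = mesh.elements_of("bone_free")
        face_nodes_per_el = mesh.elements[els][:, _XFACE_CORNERS]
        on_face = np.all(
            np.abs(mesh.nodes[face_nodes_per_el, 0] - xmax) < 1e-12, axis=1
        )
        quads = face_nodes_per_el[on_face]
        if quads.size == 0:
            raise ProtocolError("free bone has no outer X face on the boundary")
        nodes = np.unique(quads)
        hy, hz = mesh.spacing[1], mesh.spacing[2]
        return {"quads": quads, "nodes": nodes, "area": quads.shape[0] * hy * hz}

    def _system(self, fixed_dofs: np.ndarray) -> DirichletSystem:
        key = np.unique(fixed_dofs).tobytes()
        if key not in self._systems:
            self._systems[key] = DirichletSystem(
                self.k, fixed_dofs, node_ijk=self.mesh.node_ijk()
            )
        return self._systems[key]

    def _clamp_dofs(self) -> np.ndarray:
        nodes = self.mesh.nodes_of("bone_fixed")
        return (3 * nodes[:, None] + np.arange(3)).ravel()

    # -- protocols ---------------------------------------------------------

    def traction_case(self, kind: str, magnitude: float | None = None) -> LoadResult:
        """Uniform traction on the free bone's outer X face (+X or +Y)."""
        case = LoadCase(kind, magnitude)
        direction = {"tensile": 0, "shear": 1}[kind]
        face = self._face
        ndof = 3 * self.mesh.n_nodes
        f = np.zeros(ndof)
        per_node = case.magnitude * face["area"] / face["quads"].shape[0] / 4.0
        np.add.at(f, 3 * face["quads"].ravel() + direction, per_node)

        system = self._system(self._clamp_dofs())
        u, r = system.solve(f)
        u = u.reshape(-1, 3)
        stress = recover_stress(self.mesh, self.materials, u)
        length_m = self.geometry.ligament_length_um * UM
        strain = float(u[face["nodes"], direction].mean() / length_m)
        applied = np.zeros(3)
        applied[direction] = case.magnitude * face["area"]
        return LoadResult(
            case=case,
            mesh=self.mesh,
            displacement=u,
            stress=stress,
            reactions=r.reshape(-1, 3),
            face_nodes=face["nodes"],
            applied_force=applied,
            global_strain=strain,
        )

    def tensile(self, magnitude: float | None = None) -> LoadResult:
        return self.traction_case("tensile", magnitude)

    def shear(self, magnitude: float | None = None) -> LoadResult:
        return self.traction_case("shear", magnitude)

    def rotation(self, angle_deg: float | None = None) -> LoadResult:
        """Prescribed linearized rotation of the outer face about its X axis."""
        case = LoadCase("rotation", angle_deg)
        face = self._face
        if face["area"] <= 0:
            raise ProtocolError("rotated face has zero area")
        mesh = self.mesh
        theta = np.deg2rad(case.magnitude)
        y = mesh.nodes[face["nodes"], 1]
        z = mesh.nodes[face["nodes"], 2]
        yc, zc = 0.5 * (y.min() + y.max()), 0.5 * (z.min() + z.max())

        ndof = 3 * mesh.n_nodes
        vals = np.zeros(ndof)
        vals[3 * face["nodes"] + 1] = -theta * (z - zc)
        vals[3 * face["nodes"] + 2] = theta * (y - yc)
        fixed = np.concatenate(
            [self._clamp_dofs(), (3 * face["nodes"][:, None] + np.arange(3)).ravel()]
        )
        system = self._system(fixed)
        u, r = system.solve(np.zeros(ndof), vals)
        u = u.reshape(-1, 3)
        r = r.reshape(-1, 3)
        stress = recover_stress(self.mesh, self.materials, u)

        # reaction torque about X through the face centroid, split by force axis
        fy = r[face["nodes"], 1]
        fz = r[face["nodes"], 2]
        t_y = float(np.sum(-(z - zc) * fy))  # torque carried by Y-forces
        t_z = float(np.sum((y - yc) * fz))  # torque carried by Z-forces
        ly = (y.max() - y.min())
        lz = (z.max() - z.min())
        sigma_y = abs(t_y) / (face["area"] * lz / 4.0)
        sigma_z = abs(t_z) / (face["area"] * ly / 4.0)
        return LoadResult(
            case=case,
            mesh=mesh,
            displacement=u,
            stress=stress,
            reactions=r,
            face_nodes=face["nodes"],
            applied_force=np.zeros(3),
            sigma_y=sigma_y,
            sigma_z=sigma_z,
        )

    def run(self, case: LoadCase) -> LoadResult:
        if case.kind == "rotation":
            return self.rotation(case.magnitude)
        return self.traction_case(case.kind, case.magnitude)


def tensile_case(
    geometry: ModelGeometry, mesh: HexMesh, magnitude: float | None = None
) -> LoadResult:
    """Tensile traction (+X, default 0.15 Pa) on the free bone's outer face."""
    return LoadRunner(geometry, mesh).tensile(magnitude)


def shear_case(
    geometry: ModelGeometry, mesh: HexMesh, magnitude: float | None = None
) -> LoadResult:
    """Shear traction (+Y, default 0.90e-3 Pa) on the free bone's outer face."""
    return LoadRunner(geometry, mesh).shear(magnitude)


def rotation_case(
    geometry: ModelGeometry, mesh: HexMesh, angle_deg: float | None = None
) -> LoadResult:
    """Linearized rigid rotation (default 30 degrees) of the free bone's face."""
    return LoadRunner(geometry, mesh).rotation(angle_deg)
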