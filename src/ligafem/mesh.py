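"""Structured voxel hexahedral meshing of prism geometries.

Voxels are axis-aligned rectangular boxes on a regular grid with a uniform
per-axis spacing (cubes in the default fibre-model configuration).  Every
prism boundary must fall on grid planes, so each element carries exactly one
material label and the mesh volume equals the prism volume exactly.  Empty
grid cells are omitted; node/element ordering is canonical (C-order over the
grid) so identical inputs produce byte-identical meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MeshingError
from .geometry import ModelGeometry

__all__ = ["HexMesh", "voxelize", "remove_component"]

UM = 1e-6  # metres per micrometre

# VTK_HEXAHEDRON corner order as (di, dj, dk) grid offsets
_CORNERS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass
class HexMesh:
    """Conforming voxel hexahedral mesh in SI units (metres)."""

    nodes: np.ndarray  # (N, 3) float64, m
    elements: np.ndarray  # (E, 8) int64, VTK hexahedron node order
    element_material: np.ndarray  # (E,) int8 codes into `labels`
    labels: list[str]  # code -> component label
    spacing: np.ndarray  # (3,) float64, m
    elem_ijk: np.ndarray  # (E, 3) int64 grid indices
    grid_shape: tuple[int, int, int]
    origin: np.ndarray  # (3,) float64, m
    _elem_grid: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def element_volume(self) -> float:
        return float(np.prod(self.spacing))

    def material_names(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)[self.element_material]

    def elements_of(self, component: str) -> np.ndarray:
        """Indices of elements carrying ``component`` (exact label match)."""
        if component not in self.labels:
            return np.empty(0, dtype=np.int64)
        code = self.labels.index(component)
        return np.nonzero(self.element_material == code)[0]

    def nodes_of(self, component: str) -> np.ndarray:
        """Unique node ids touched by elements of ``component``."""
        els = self.elements_of(component)
        return np.unique(self.elements[els])

    def node_ijk(self) -> np.ndarray:
        """Integer grid indices of every node (for the multigrid hierarchy)."""
        idx = (self.nodes - self.origin) / self.spacing
        return np.round(idx).astype(np.int64)

    def element_index_grid(self) -> np.ndarray:
        """Dense (nx, ny, nz) grid mapping cells to element ids (-1 = empty)."""
        if self._elem_grid is None:
            grid = np.full(self.grid_shape, -1, dtype=np.int64)
            grid[self.elem_ijk[:, 0], self.elem_ijk[:, 1], self.elem_ijk[:, 2]] = (
                np.arange(self.n_elements)
            )
            self._elem_grid = grid
        return self._elem_grid

    def face_neighbors(self, e: int) -> np.ndarray:
        """Element ids sharing a face with element ``e`` (up to 6)."""
        return self._neighbors(e, _FACE_OFFSETS)

    def edge_neighbors(self, e: int) -> np.ndarray:
        """Element ids sharing exactly an edge with element ``e`` (up to 12)."""
        return self._neighbors(e, _EDGE_OFFSETS)

    def _neighbors(self, e: int, offsets: np.ndarray) -> np.ndarray:
        grid = self.element_index_grid()
        ijk = self.elem_ijk[e] + offsets
        ok = np.all((ijk >= 0) & (ijk < np.array(self.grid_shape)), axis=1)
        ids = grid[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
        return ids[ids >= 0]

    def canonical_bytes(self) -> bytes:
        """Byte-for-byte canonical serialization (for determinism checks)."""
        parts = [
            self.nodes.tobytes(),
            self.elements.astype(np.int64).tobytes(),
            self.element_material.tobytes(),
            ",".join(self.labels).encode(),
            self.spacing.tobytes(),
        ]
        return b"|".join(parts)


_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)
_EDGE_OFFSETS = np.array(
    [
        (s1 * a + s2 * b).tolist()
        for a, b in [
            (np.array([1, 0, 0]), np.array([0, 1, 0])),
            (np.array([1, 0, 0]), np.array([0, 0, 1])),
            (np.array([0, 1, 0]), np.array([0, 0, 1])),
        ]
        for s1 in (1, -1)
        for s2 in (1, -1)
    ]
)


def _as_spacing(h) -> np.ndarray:
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if h.size == 1:
        h = np.repeat(h, 3)
    if h.size != 3 or np.any(h <= 0):
        raise MeshingError(f"voxel spacing must be a positive scalar or 3-vector")
    return h


def _to_index(x: np.ndarray, h: np.ndarray, what: str) -> np.ndarray:
    idx = x / h
    rounded = np.round(idx)
    if np.any(np.abs(idx - rounded) > 1e-6):
        raise MeshingError(
            f"{what} {x} is not an integer multiple of the voxel spacing {h}"
        )
    return rounded.astype(np.int64)


def remove_component(mesh: HexMesh, component: str) -> HexMesh:
    """New mesh with every element of ``component`` voided (nodes compressed)."""
    if component not in mesh.labels:
        raise GeometryError(f"mesh has no component {component!r}")
    code = mesh.labels.index(component)
    keep = mesh.element_material != code
    elements = mesh.elements[keep]
    used, remapped = np.unique(elements, return_inverse=True)
    return HexMesh(
        nodes=np.ascontiguousarray(mesh.nodes[used]),
        elements=remapped.reshape(elements.shape).astype(np.int64),
        element_material=mesh.element_material[keep],
        labels=list(mesh.labels),
        spacing=mesh.spacing.copy(),
        elem_ijk=mesh.elem_ijk[keep],
        grid_shape=mesh.grid_shape,
        origin=mesh.origin.copy(),
    )


def voxelize(g: ModelGeometry, h=4.0) -> HexMesh:
    """Voxelize a prism geometry at spacing ``h`` (um; scalar or per-axis).

    Every prism origin and extent must be an integer multiple of the spacing
    on each axis, so the voxel mesh represents the geometry exactly.
    """
    h_um = _as_spacing(h)
    lo, hi = g.bounding_box()
    lo_i = _to_index(lo, h_um, "bounding box origin")
    hi_i = _to_index(hi, h_um, "bounding box corner")
    shape = tuple((hi_i - lo_i).tolist())

    codes = np.full(shape, -1, dtype=np.int8)
    labels = g.components()
    for p in g.prisms:
        a = _to_index(np.asarray(p.origin), h_um, f"{p.component} prism origin") - lo_i
        b = a + _to_index(np.asarray(p.dims), h_um, f"{p.component} prism dims")
        region = codes[a[0] : b[0], a[1] : b[1], a[2] : b[2]]
        if np.any(region != -1):
            raise GeometryError(f"prism {p.component} overlaps an earlier prism")
        region[...] = labels.index(p.component)

    ii, jj, kk = np.nonzero(codes >= 0)
    elem_ijk = np.stack([ii, jj, kk], axis=1)
    elem_codes = codes[ii, jj, kk]

    # node linear ids on the (nx+1, ny+1, nz+1) grid, then compress to used nodes
    nyn, nzn = shape[1] + 1, shape[2] + 1
    corner_ijk = elem_ijk[:, None, :] + _CORNERS[None, :, :]
    lin = (corner_ijk[..., 0] * nyn + corner_ijk[..., 1]) * nzn + corner_ijk[..., 2]
    used, elements = np.unique(lin, return_inverse=True)
    elements = elements.reshape(lin.shape).astype(np.int64)

    node_k = used % nzn
    node_j = (used // nzn) % nyn
    node_i = used // (nzn * nyn)
    node_ijk = np.stack([node_i, node_j, node_k], axis=1)
    nodes = (lo_i + node_ijk) * h_um * UM

    return HexMesh(
        nodes=np.ascontiguousarray(nodes, dtype=np.float64),
        elements=elements,
        element_material=elem_codes,
        labels=labels,
        spacing=h_um * UM,
        elem_ijk=elem_ijk,
        grid_shape=shape,
        origin=lo_i * h_um * UM,
    )
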