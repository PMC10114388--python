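"""Parametric ligament geometry: collagen fibres, elastin bridges, bone caps.

The fibre model is a 3 x 5 lattice of square collagen prisms (20 x 20 x 300 um)
capped by two bone blocks, with 12 x 12 x 20 um elastin blocks bridging the
20 um gaps between adjacent fibres.  The sheet model is a single homogeneous
prism (62 x 128 x 300 um) with the same bone caps.  All coordinates are in
micrometres; the X axis is the fibre long axis (tensile direction), Y the
shear direction (5 fibre columns), Z the remaining axis (3 fibre rows).

Elastin content is the volume fraction Ve / (Ve + Vc); bone is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CapacityError,
    ContentUndefinedError,
    GeometryError,
    MaterialError,
)

__all__ = [
    "Material",
    "Prism",
    "ModelGeometry",
    "TABLE_MATERIALS",
    "build_fibre_model",
    "build_sheet_model",
    "elastin_fraction",
    "n_for_content",
    "lattice_capacity",
]


@dataclass(frozen=True)
class Material:
    """Linear isotropic elastic material (E in Pa, dimensionless Poisson ratio)."""

    name: str
    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise MaterialError(f"{self.name}: Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise MaterialError(
                f"{self.name}: Poisson ratio must lie in [0, 0.5), got "
                f"{self.poisson_ratio}"
            )


#: Material constants of the study: collagen and elastin from tendon/ligament
#: micromechanics literature, homogenised sheet ligament, and cortical bone.
TABLE_MATERIALS: dict[str, Material] = {
    "collagen": Material("collagen", 8.9e6, 0.48),
    "elastin": Material("elastin", 4.0e6, 0.48),
    "sheet": Material("sheet", 12.7e6, 0.48),
    "bone": Material("bone", 17.0e6, 0.30),
}

COMPONENTS = ("collagen", "elastin", "bone_fixed", "bone_free", "sheet")


@dataclass(frozen=True)
class Prism:
    """Axis-aligned rectangular prism of a single model component (um units)."""

    component: str
    origin: tuple[float, float, float]
    dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise GeometryError(f"unknown component label {self.component!r}")
        if not all(d > 0 for d in self.dims):
            raise GeometryError(
                f"{self.component}: prism dims must be strictly positive, got "
                f"{self.dims}"
            )

    @property
    def volume(self) -> float:
        dx, dy, dz = self.dims
        return dx * dy * dz

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(o + d for o, d in zip(self.origin, self.dims))

    def overlaps(self, other: "Prism", tol: float = 1e-9) -> bool:
        """True if the two prisms share interior volume (face contact is fine)."""
        for a0, a1, b0, b1 in zip(self.origin, self.upper, other.origin, other.upper):
            if a1 <= b0 + tol or b1 <= a0 + tol:
                return False
        return True


@dataclass
class ModelGeometry:
    """A labelled collection of prisms plus content bookkeeping."""

    prisms: list[Prism]
    model_kind: str  # "fibre" | "sheet"
    n_elastin: int
    lattice: dict = field(default_factory=dict)
    materials: dict[str, Material] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in ("fibre", "sheet"):
            raise GeometryError(f"unknown model kind {self.model_kind!r}")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        # pairwise AABB interval test; vectorised to keep 330+ prisms cheap
        lo = np.array([p.origin for p in self.prisms])
        hi = np.array([p.upper for p in self.prisms])
        n = len(self.prisms)
        for i in range(n):
            sep = (hi[i] <= lo[i + 1 :] + 1e-9) | (hi[i + 1 :] <= lo[i] + 1e-9)
            bad = ~sep.any(axis=1)
            if bad.any():
                j = i + 1 + int(np.nonzero(bad)[0][0])
                raise GeometryError(
                    f"prisms {i} ({self.prisms[i].component}) and {j} "
                    f"({self.prisms[j].component}) overlap in volume"
                )

    def component_volume(self, component: str) -> float:
        return sum(p.volume for p in self.prisms if p.component == component)

    def components(self) -> list[str]:
        return list(dict.fromkeys(p.component for p in self.prisms))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.min([p.origin for p in self.prisms], axis=0)
        hi = np.max([p.upper for p in self.prisms], axis=0)
        return lo, hi

    @property
    def ligament_length_um(self) -> float:
        """Axial (X) span of the ligament between the two bone caps."""
        kinds = ("collagen", "sheet")
        xs = [p.origin[0] for p in self.prisms if p.component in kinds]
        xe = [p.upper[0] for p in self.prisms if p.component in kinds]
        return max(xe) - min(xs)


# --- fibre model -----------------------------------------------------------


def _gap_lines(rows: int, cols: int) -> list[tuple[str, int, int]]:
    """Deterministic ordering of adjacent-fibre gap lines.

    Y-neighbour pairs first (same row, adjacent columns), row-major, then
    Z-neighbour pairs (same column, adjacent rows).  For 3 x 5 this yields
    the 22 bridging lines of the default lattice.
    """
    pairs = [("y", i, j) for i in range(rows) for j in range(cols - 1)]
    pairs += [("z", i, j) for i in range(rows - 1) for j in range(cols)]
    return pairs


def lattice_capacity(
    rows: int = 3,
    cols: int = 5,
    fibre_len: float = 300.0,
    gap: float = 20.0,
) -> int:
    """Maximum number of elastin blocks the placement lattice can hold."""
    n_stations = int(fibre_len // gap)
    return n_stations * len(_gap_lines(rows, cols))


def build_fibre_model(
    rows: int = 3,
    cols: int = 5,
    fibre_dims: tuple[float, float, float] = (300.0, 20.0, 20.0),
    elastin_dims: tuple[float, float, float] = (20.0, 12.0, 12.0),
    gap: float = 20.0,
    n_elastin: int = 0,
    bone_thickness: float = 40.0,
    materials: dict[str, Material] | None = None,
) -> ModelGeometry:
    """Build the multi-fibre collagen + elastin ligament model.

    ``fibre_dims`` is (length, width, height) of one collagen prism;
    ``elastin_dims`` is (span, width, width) of one elastin block, the span
    being the 20 um bridging direction across the inter-fibre gap.  Elastin
    blocks are placed at equally spaced axial stations (pitch = gap), cycling
    round-robin over the adjacent-fibre gap lines: Y-neighbour pairs
    row-major first, then Z-neighbour pairs, advancing one axial station
    after each full cycle.
    """
    if materials is None:
        materials = TABLE_MATERIALS
    L, fw, fh = fibre_dims
    span, ew, eh = elastin_dims
    if ew != eh:
        raise GeometryError("elastin cross-section must be square")
    if abs(gap - span) > 1e-9:
        raise GeometryError(
            f"inter-fibre gap ({gap}) must equal the elastin span ({span}) so "
            "bridges exactly span the gaps"
        )
    if ew > fw or ew > fh or ew > gap:
        raise GeometryError("elastin cross-section too large for the lattice")
    cap = lattice_capacity(rows, cols, L, gap)
    if n_elastin > cap:
        raise CapacityError(
            f"n_elastin={n_elastin} exceeds lattice capacity {cap} "
            f"({int(L // gap)} stations x {len(_gap_lines(rows, cols))} gap lines)"
        )

    Ly = cols * fw + (cols - 1) * gap
    Lz = rows * fh + (rows - 1) * gap

    prisms: list[Prism] = []
    for i in range(rows):
        for j in range(cols):
            prisms.append(
                Prism(
                    "collagen",
                    (bone_thickness, j * (fw + gap), i * (fh + gap)),
                    (L, fw, fh),
                )
            )
    prisms.append(Prism("bone_fixed", (0.0, 0.0, 0.0), (bone_thickness, Ly, Lz)))
    prisms.append(
        Prism("bone_free", (bone_thickness + L, 0.0, 0.0), (bone_thickness, Ly, Lz))
    )

    # axial stations: pitch = gap, block centred within each pitch cell
    n_stations = int(L // gap)
    pitch = L / n_stations
    margin_x = (pitch - ew) / 2.0
    my = (fw - ew) / 2.0  # centring margin on a fibre face
    mz = (fh - ew) / 2.0
    pairs = _gap_lines(rows, cols)
    placed = 0
    for k in range(n_stations):
        if placed >= n_elastin:
            break
        x0 = bone_thickness + k * pitch + margin_x
        for axis, i, j in pairs:
            if placed >= n_elastin:
                break
            if axis == "y":
                # bridge along Y between columns j and j+1 in row i
                origin = (x0, j * (fw + gap) + fw, i * (fh + gap) + mz)
                dims = (ew, gap, eh)
            else:
                # bridge along Z between rows i and i+1 in column j
                origin = (x0, j * (fw + gap) + my, i * (fh + gap) + fh)
                dims = (ew, eh, gap)
            prisms.append(Prism("elastin", origin, dims))
            placed += 1

    lattice = {
        "rows": rows,
        "cols": cols,
        "gap_um": gap,
        "n_stations": n_stations,
        "capacity": cap,
        "fibre_dims_um": tuple(fibre_dims),
        "elastin_dims_um": tuple(elastin_dims),
        "bone_thickness_um": bone_thickness,
    }
    return ModelGeometry(prisms, "fibre", n_elastin, lattice, dict(materials))


def build_sheet_model(
    dims: tuple[float, float, float] = (300.0, 62.0, 128.0),
    bone_thickness: float = 40.0,
    materials: dict[str, Material] | None = None,
) -> ModelGeometry:
    """Build the homogeneous single-sheet ligament model with bone caps."""
    if materials is None:
        materials = TABLE_MATERIALS
    L, W, H = dims
    prisms = [
        Prism("sheet", (bone_thickness, 0.0, 0.0), (L, W, H)),
        Prism("bone_fixed", (0.0, 0.0, 0.0), (bone_thickness, W, H)),
        Prism("bone_free", (bone_thickness + L, 0.0, 0.0), (bone_thickness, W, H)),
    ]
    lattice = {"sheet_dims_um": tuple(dims), "bone_thickness_um": bone_thickness}
    return ModelGeometry(prisms, "sheet", 0, lattice, dict(materials))


# --- content arithmetic ----------------------------------------------------


def elastin_fraction(g: ModelGeometry) -> float:
    """Elastin volume fraction Ve / (Ve + Vc) of a fibre model (bone excluded)."""
    if g.model_kind != "fibre":
        raise ContentUndefinedError(
            "elastin content is undefined for the sheet model"
        )
    ve = g.component_volume("elastin")
    vc = g.component_volume("collagen")
    return ve / (ve + vc)


def _fraction_for_n(
    n: int,
    rows: int,
    cols: int,
    fibre_dims: tuple[float, float, float],
    elastin_dims: tuple[float, float, float],
) -> float:
    vc = rows * cols * np.prod(fibre_dims)
    ve = n * np.prod(elastin_dims)
    return float(ve / (ve + vc))


def n_for_content(
    target: float,
    rows: int = 3,
    cols: int = 5,
    fibre_dims: tuple[float, float, float] = (300.0, 20.0, 20.0),
    elastin_dims: tuple[float, float, float] = (20.0, 12.0, 12.0),
    gap: float = 20.0,
) -> int:
    """Block count whose content is closest to ``target`` (ties -> smaller n)."""
    if not 0.0 <= target < 1.0:
        raise CapacityError(f"target content must lie in [0, 1), got {target}")
    cap = lattice_capacity(rows, cols, fibre_dims[0], gap)
    f_max = _fraction_for_n(cap, rows, cols, fibre_dims, elastin_dims)
    if target > f_max:
        raise CapacityError(
            f"target content {target} exceeds the lattice maximum {f_max:.4f}"
        )
    # fraction is strictly increasing in n: invert and take the closer neighbour
    vc = float(np.prod(fibre_dims)) * rows * cols
    vb = float(np.prod(elastin_dims))
    n_star = target * vc / ((1.0 - target) * vb)
    lo = int(np.floor(n_star))
    hi = min(lo + 1, cap)
    err_lo = abs(_fraction_for_n(lo, rows, cols, fibre_dims, elastin_dims) - target)
    err_hi = abs(_fraction_for_n(hi, rows, cols, fibre_dims, elastin_dims) - target)
    return lo if err_lo <= err_hi else hi
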