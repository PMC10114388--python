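"""Serialization: VTU field export and YAML geometry/study configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .geometry import (
    Material,
    ModelGeometry,
    build_fibre_model,
    build_sheet_model,
    n_for_content,
)
from .mesh import HexMesh

__all__ = ["write_vtu", "geometry_to_config", "geometry_from_config"]


def _ascii(a: np.ndarray, fmt: str = "%.10g") -> str:
    return "\n".join(" ".join(fmt % v for v in row) for row in np.atleast_2d(a))


def write_vtu(
    mesh: HexMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh (plus optional fields) as an ASCII XML VTU file.

    Point data arrays are (N,) or (N, 3); cell data arrays are (E,).  The
    integer cell field "material" is always included.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("material", mesh.element_material.astype(np.int32))

    n, e = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.elements, "%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(8 * (i + 1)) for i in range(e)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("12" for _ in range(e)),  # VTK_HEXAHEDRON
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        parts += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _ascii(arr.reshape(n, ncomp)),
            "</DataArray>",
        ]
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        vtype = "Int32" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        fmt = "%d" if vtype == "Int32" else "%.10g"
        parts += [
            f'<DataArray type="{vtype}" Name="{name}" format="ascii">',
            _ascii(arr.reshape(e, 1), fmt),
            "</DataArray>",
        ]
    parts += ["</CellData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(parts))
    return path


def geometry_to_config(g: ModelGeometry, voxel_um=4.0) -> dict:
    """Structured config dict describing a model geometry."""
    cfg: dict = {
        "model_kind": g.model_kind,
        "voxel_um": voxel_um,
        "materials": {
            name: {"E_Pa": m.young_modulus, "nu": m.poisson_ratio}
            for name, m in g.materials.items()
        },
    }
    lat = g.lattice
    if g.model_kind == "fibre":
        cfg.update(
            rows=lat["rows"],
            cols=lat["cols"],
            fibre_dims_um=list(lat["fibre_dims_um"]),
            elastin_dims_um=list(lat["elastin_dims_um"]),
            gap_um=lat["gap_um"],
            n_elastin=g.n_elastin,
            bone_thickness_um=lat["bone_thickness_um"],
        )
    else:
        cfg.update(
            sheet_dims_um=list(lat["sheet_dims_um"]),
            bone_thickness_um=lat["bone_thickness_um"],
        )
    return cfg


def geometry_from_config(cfg: dict) -> ModelGeometry:
    """Inverse of :func:`geometry_to_config`; accepts ``target_content`` too."""
    materials = None
    if "materials" in cfg:
        materials = {
            name: Material(name, spec["E_Pa"], spec["nu"])
            for name, spec in cfg["materials"].items()
        }
    if cfg["model_kind"] == "sheet":
        return build_sheet_model(
            dims=tuple(cfg["sheet_dims_um"]),
            bone_thickness=cfg.get("bone_thickness_um", 40.0),
            materials=materials,
        )
    kwargs = dict(
        rows=cfg.get("rows", 3),
        cols=cfg.get("cols", 5),
        fibre_dims=tuple(cfg.get("fibre_dims_um", (300.0, 20.0, 20.0))),
        elastin_dims=tuple(cfg.get("elastin_dims_um", (20.0, 12.0, 12.0))),
        gap=cfg.get("gap_um", 20.0),
        bone_thickness=cfg.get("bone_thickness_um", 40.0),
    )
    if "n_elastin" in cfg:
        n = cfg["n_elastin"]
    elif "target_content" in cfg:
        n = n_for_content(
            cfg["target_content"],
            rows=kwargs["rows"],
            cols=kwargs["cols"],
            fibre_dims=kwargs["fibre_dims"],
            elastin_dims=kwargs["elastin_dims"],
            gap=kwargs["gap"],
        )
    else:
        n = 0
    return build_fibre_model(n_elastin=n, materials=materials, **kwargs)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
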