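"""Component-wise summaries, stress-strain slopes, and localization queries.

These produce the per-component statistics behind the study's comparisons:
mean/max von Mises stress over element centroids, mean/max displacement
magnitude over component nodes, least-squares stress-strain slopes, and the
interface classification of the maximum-stress element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import QueryError
from .geometry import ModelGeometry
from .loads import DEFAULT_MAGNITUDES, LoadResult, LoadRunner
from .mesh import HexMesh

__all__ = [
    "ComponentSummary",
    "SlopeEstimate",
    "summarize",
    "stress_strain_slope",
    "percent_change",
    "locate_max_stress",
]


@dataclass(frozen=True)
class ComponentSummary:
    """Stress/displacement statistics of one model component."""

    component: str
    mean_vm: float  # Pa, over element centroids
    max_vm: float  # Pa
    mean_disp: float  # m, displacement magnitude over component nodes
    max_disp: float  # m
    n_elements: int


@dataclass(frozen=True)
class SlopeEstimate:
    """Origin-constrained least-squares slope of applied stress on strain."""

    case_kind: str
    content: float | None
    slope: float  # Pa
    linear: bool


def summarize(result: LoadResult, component: str) -> ComponentSummary:
    """Mean/max von Mises and displacement statistics for one component."""
    mesh = result.mesh
    els = mesh.elements_of(component)
    if els.size == 0:
        raise QueryError(f"component {component!r} has no elements in this mesh")
    vm = result.stress["von_mises"][els]
    nodes = np.unique(mesh.elements[els])
    disp = np.linalg.norm(result.displacement[nodes], axis=1)
    return ComponentSummary(
        component=component,
        mean_vm=float(vm.mean()),
        max_vm=float(vm.max()),
        mean_disp=float(disp.mean()),
        max_disp=float(disp.max()),
        n_elements=int(els.size),
    )


def stress_strain_slope(
    geometry: ModelGeometry,
    mesh: HexMesh,
    case_kind: str,
    scalings=(0.5, 1.0, 1.5, 2.0),
    runner: LoadRunner | None = None,
    content: float | None = None,
) -> SlopeEstimate:
    """Slope of the (global strain, applied traction) line through the origin.

    The rotation protocol has no scalar stress-strain pair and is excluded.
    """
    if case_kind not in ("tensile", "shear"):
        raise QueryError(f"stress-strain slope is undefined for {case_kind!r}")
    scalings = list(scalings)
    if len(scalings) < 2:
        raise QueryError("need at least two load scalings for a slope")
    if runner is None:
        runner = LoadRunner(geometry, mesh)
    base = DEFAULT_MAGNITUDES[case_kind]
    stresses, strains = [], []
    for s in scalings:
        res = runner.traction_case(case_kind, s * base)
        stresses.append(res.case.magnitude)
        strains.append(res.global_strain)
    stresses = np.asarray(stresses)
    strains = np.asarray(strains)
    if np.allclose(strains, 0.0):
        raise QueryError("degenerate (zero) strains; cannot fit a slope")
    slope = float(np.sum(strains * stresses) / np.sum(strains**2))
    resid = np.linalg.norm(stresses - slope * strains) / np.linalg.norm(stresses)
    return SlopeEstimate(case_kind, content, slope, linear=bool(resid < 1e-8))


def percent_change(a: float, b: float) -> float:
    """Relative change 100 * (a - b) / a from reference a to value b."""
    if a == 0:
        raise ZeroDivisionError("percent change is undefined for a zero reference")
    return 100.0 * (a - b) / a


def locate_max_stress(result: LoadResult, component: str) -> dict:
    """Element with the largest von Mises stress in ``component``.

    Returns the element id and an interface classification: which other
    materials (if any) share a face or an edge with that element.
    """
    mesh = result.mesh
    els = mesh.elements_of(component)
    if els.size == 0:
        raise QueryError(f"component {component!r} has no elements in this mesh")
    vm = result.stress["von_mises"][els]
    e = int(els[np.argmax(vm)])
    names = mesh.material_names()
    own = names[e]
    touching = set()
    for nb in np.concatenate([mesh.face_neighbors(e), mesh.edge_neighbors(e)]):
        if names[nb] != own:
            touching.add(str(names[nb]))
    return {
        "element": e,
        "max_vm": float(vm.max()),
        "component": str(own),
        "junction": sorted(touching),
        "at_junction": bool(touching),
    }
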