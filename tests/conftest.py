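"""Shared fixtures: small, fast model geometries and meshes.

The reduced fibre/sheet models keep every structural feature of the default
study (bone caps, inter-fibre gaps, elastin bridges) at a fraction of the
DOF count so the whole unit suite solves with the direct factorization.
"""

import numpy as np
import pytest

import ligafem as lf


@pytest.fixture(scope="session")
def small_fibre():
    """2 x 2 fibre model, 100 um fibres, 8 elastin bridges, 8 um bones."""
    g = lf.build_fibre_model(
        rows=2,
        cols=2,
        fibre_dims=(100.0, 20.0, 20.0),
        n_elastin=8,
        bone_thickness=8.0,
    )
    mesh = lf.voxelize(g, 4.0)
    return g, mesh


@pytest.fixture(scope="session")
def small_fibre_runner(small_fibre):
    g, mesh = small_fibre
    return lf.LoadRunner(g, mesh)


@pytest.fixture(scope="session")
def small_fibre_bare():
    """Same reduced lattice without elastin."""
    g = lf.build_fibre_model(
        rows=2,
        cols=2,
        fibre_dims=(100.0, 20.0, 20.0),
        n_elastin=0,
        bone_thickness=8.0,
    )
    mesh = lf.voxelize(g, 4.0)
    return g, mesh


@pytest.fixture(scope="session")
def small_sheet():
    """Reduced homogeneous sheet: 100 x 20 x 24 um ligament, 8 um bones."""
    g = lf.build_sheet_model(dims=(100.0, 20.0, 24.0), bone_thickness=8.0)
    mesh = lf.voxelize(g, 4.0)
    return g, mesh


def make_bar(
    n=(5, 1, 1), h_um=4.0, material=None, component="collagen"
) -> lf.HexMesh:
    """Single-prism bar mesh of n voxels per axis (no bone caps)."""
    material = material or lf.TABLE_MATERIALS["collagen"]
    dims = tuple(ni * h_um for ni in n)
    g = lf.ModelGeometry(
        [lf.Prism(component, (0.0, 0.0, 0.0), dims)],
        "fibre",
        0,
        materials={component: material, "bone": lf.TABLE_MATERIALS["bone"]},
    )
    return lf.voxelize(g, h_um)


@pytest.fixture
def bar_mesh():
    return make_bar()
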