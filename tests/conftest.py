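"""Shared fixtures: structured box meshes, generated beaks, solved cases.

The box-mesh builder here is an independent construction (plain grid +
6-tet split) used for analytic FE verification problems; it does not go
through the beak generator.
"""

import numpy as np
import pytest

from finchbeak.beak_geometry import TetMesh, boundary_faces, make_shape_params, \
    generate_beak_mesh
from finchbeak.fe_core import DEFAULT_MATERIALS, LoadCase, solve_static
from finchbeak.load_cases import ScenarioSpec, build_case
from finchbeak.musculature import (BeakLoads, DEFAULT_JUGAL_DIR,
                                   DEFAULT_PALATINE_DIR)

_HEX_TETS = np.array([
    [0, 1, 2, 6], [0, 2, 3, 6], [0, 1, 6, 5],
    [0, 5, 6, 4], [0, 3, 7, 6], [0, 7, 4, 6]])


def box_mesh(nx, ny, nz, lx, ly, lz, material="bone"):
    """Structured box of hexes split into 6 tets each."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nid = np.arange(len(nodes)).reshape(nx + 1, ny + 1, nz + 1)
    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    hexes = np.stack([
        nid[I, J, K], nid[I + 1, J, K], nid[I + 1, J + 1, K], nid[I, J + 1, K],
        nid[I, J, K + 1], nid[I + 1, J, K + 1], nid[I + 1, J + 1, K + 1],
        nid[I, J + 1, K + 1]], axis=1)
    tets = hexes[:, _HEX_TETS].reshape(-1, 4)
    return TetMesh(nodes=nodes, tets=tets,
                   material=np.array([material] * len(tets)),
                   metadata=dict(length=lx))


def end_face_loads(mesh, x_end, total_force):
    """Consistent (tributary-area) nodal loads for uniform traction on
    the boundary face at x = x_end.  Returns (point_loads, face_area)."""
    faces = boundary_faces(mesh)
    on = np.isclose(mesh.nodes[:, 0], x_end)
    faces = faces[on[faces].all(axis=1)]
    p = mesh.nodes[faces]
    areas = np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                           axis=1) / 2
    A = areas.sum()
    per_node: dict[int, float] = {}
    for tri, ar in zip(faces, areas):
        for n in tri:
            per_node[n] = per_node.get(n, 0.0) + ar / 3
    loads = [(f"n{n}", np.array([n]), np.asarray(total_force, float) * w / A)
             for n, w in sorted(per_node.items())]
    return loads, A


def clamped_case(mesh, point_loads, x_fix=0.0):
    fixed = np.flatnonzero(np.isclose(mesh.nodes[:, 0], x_fix))
    return LoadCase(fixed_nodes=fixed, bite_nodes=np.array([], dtype=int),
                    point_loads=point_loads)


@pytest.fixture(scope="session")
def reference_loads():
    """Jugal/palatine loads with the reference magnitudes (11.9, 10.9 N)."""
    return BeakLoads(F_jugal=11.9 * DEFAULT_JUGAL_DIR,
                     F_palatine=10.9 * DEFAULT_PALATINE_DIR,
                     jugal_angle=0.0,
                     palatine_direction=DEFAULT_PALATINE_DIR)


@pytest.fixture(scope="session")
def crush_params():
    return make_shape_params("crush", {"length": 13.0})


@pytest.fixture(scope="session")
def crush_mesh(crush_params):
    return generate_beak_mesh(crush_params, resolution=5000, seed=1)


@pytest.fixture(scope="session")
def crush_solutions(crush_mesh, reference_loads):
    """Solved base and tip physiological cases on the crush beak."""
    out = {}
    for mode in ("base", "tip"):
        case = build_case(crush_mesh, ScenarioSpec("physiological", mode),
                          reference_loads)
        out[mode] = (case, solve_static(crush_mesh, DEFAULT_MATERIALS, case))
    return out
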