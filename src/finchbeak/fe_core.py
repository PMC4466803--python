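"""Small-strain linear-elastic FE solver for 4-node tetrahedra.

Constant-strain tetrahedra with two isotropic materials (bone and
keratin), translational point/patch loads and fully-fixed node patches.
The consistent N-mm-MPa unit system is used throughout: coordinates in
mm, moduli in MPa, forces in N, stresses in MPa.

Stress is constant per element (evaluated at the centroid); no nodal
averaging is performed before any percentile extraction downstream.
Reaction forces at the bite constraint give the model bite force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .beak_geometry import TetMesh, tet_volumes

__all__ = [
    "Material", "LoadCase", "SolutionField",
    "DEFAULT_MATERIALS", "elasticity_matrix", "element_stiffness",
    "assemble", "assemble_load_vector", "solve_static", "von_mises",
    "reaction_force", "convergence_check",
]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (E in MPa)."""
    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")


# Measured moduli for finch beak tissue: E_bone = 7.3 GPa, E_keratin =
# 1.7 GPa.  Poisson ratios are not part of the measured dataset; 0.30
# (cortical bone) and 0.40 (beta-keratin) are the values commonly used
# in the beak-modelling literature and are exposed in the run config.
DEFAULT_MATERIALS = {
    "bone": Material(E=7300.0, nu=0.30),
    "keratin": Material(E=1700.0, nu=0.40),
}


@dataclass
class LoadCase:
    """Constraints and loads for one solve.

    ``point_loads`` holds (name, node indices, total force vector in N)
    triples; each total force is distributed equally over its node patch
    (statically equivalent loading of a rigid attachment).
    """
    fixed_nodes: np.ndarray
    bite_nodes: np.ndarray
    point_loads: list[tuple[str, np.ndarray, np.ndarray]]
    bite_mode: str = "base"

    def __post_init__(self) -> None:
        if self.bite_mode not in ("tip", "base"):
            raise ValueError(f"bite_mode must be tip|base, got {self.bite_mode!r}")
        fixed = set(np.asarray(self.fixed_nodes).tolist())
        bite = set(np.asarray(self.bite_nodes).tolist())
        if fixed & bite:
            raise ValueError("fixed and bite node sets overlap")
        constrained = fixed | bite
        for name, idx, _ in self.point_loads:
            if set(np.asarray(idx).tolist()) & constrained:
                raise ValueError(f"load patch {name!r} touches constrained nodes")

    @property
    def constrained_nodes(self) -> np.ndarray:
        return np.union1d(self.fixed_nodes, self.bite_nodes)


@dataclass
class SolutionField:
    """Result of one static solve."""
    displacement: np.ndarray     # (n, 3) mm
    stress: np.ndarray           # (m, 6) MPa, Voigt [xx yy zz xy yz zx]
    von_mises: np.ndarray        # (m,) MPa
    reactions: np.ndarray        # (n, 3) N, nonzero only on constrained nodes
    constrained: np.ndarray      # (n,) bool
    residual: float              # relative residual on free DOFs
    applied: np.ndarray = field(default=None)  # (n, 3) N applied loads


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt form (engineering shear)."""
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (m, 4, 3) and volumes (m,) for tet batches."""
    e = coords[:, 1:] - coords[:, :1]          # (m, 3, 3) rows are edges
    det = np.linalg.det(e)
    vol = det / 6.0
    if (vol <= 0).any():
        raise ValueError(
            f"{int((vol <= 0).sum())} degenerate tetrahedra "
            "(non-positive signed volume)")
    inv = np.linalg.inv(e)                     # e = J^T, so inv = J^{-T}
    g = np.empty(coords.shape[:1] + (4, 3))
    g[:, 1:] = inv.transpose(0, 2, 1)          # grad N_i = row i-1 of J^{-1}
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def _b_matrices(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 12) from gradients (m, 4, 3)."""
    m = g.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 stiffness of a single tet: V * B^T D B (N/mm)."""
    coords = np.asarray(coords, dtype=float).reshape(1, 4, 3)
    g, vol = _gradients(coords)
    if vol[0] <= 0:
        raise ValueError(f"degenerate tetrahedron (signed volume {vol[0]:g})")
    B = _b_matrices(g)[0]
    D = elasticity_matrix(material)
    return vol[0] * B.T @ D @ B


def assemble(mesh: TetMesh, materials: dict[str, Material]) -> sp.csr_matrix:
    """Global sparse stiffness matrix (3 DOF per node)."""
    missing = set(np.unique(mesh.material)) - set(materials)
    if missing:
        raise KeyError(f"no material for labels {sorted(missing)}")
    coords = mesh.nodes[mesh.tets]
    g, vol = _gradients(coords)
    if (vol <= 0).any():
        raise ValueError("mesh contains non-positive-volume elements")
    B = _b_matrices(g)
    Ke = np.zeros((mesh.n_tets, 12, 12))
    for label, mat in materials.items():
        idx = mesh.material == label
        if not idx.any():
            continue
        D = elasticity_matrix(mat)
        DB = np.einsum("ab,mbj->maj", D, B[idx])
        Ke[idx] = vol[idx, None, None] * np.einsum("mai,maj->mij", B[idx], DB)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_tets, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))
    return K.tocsr()


def assemble_load_vector(n_nodes: int,
                         point_loads: list[tuple[str, np.ndarray, np.ndarray]]
                         ) -> np.ndarray:
    """Global load vector; each patch total is split equally over its nodes."""
    f = np.zeros(3 * n_nodes)
    for _, idx, force in point_loads:
        idx = np.asarray(idx)
        if len(idx) == 0:
            raise ValueError("empty load patch")
        per = np.asarray(force, dtype=float) / len(idx)
        for d in range(3):
            np.add.at(f, 3 * idx + d, per[d])
    return f


def solve_static(mesh: TetMesh, materials: dict[str, Material],
                 loadcase: LoadCase, rtol: float = 1e-8) -> SolutionField:
    """Solve K u = f with all translations fixed on the constrained sets.

    Uses a direct sparse factorisation on the free DOFs.  Raises if the
    relative residual exceeds ``rtol`` or the system is singular
    (insufficient constraints).
    """
    K = assemble(mesh, materials)
    f = assemble_load_vector(mesh.n_nodes, loadcase.point_loads)

    n = 3 * mesh.n_nodes
    con_nodes = loadcase.constrained_nodes
    if len(con_nodes) == 0:
        raise ValueError("no constraints: rigid-body modes present")
    con = np.zeros(n, dtype=bool)
    con[(3 * con_nodes[:, None] + np.arange(3)).ravel()] = True
    free = ~con

    Kff = K[free][:, free]
    u = np.zeros(n)
    try:
        u_f = spla.spsolve(Kff.tocsc(), f[free])
    except Exception as exc:     # pragma: no cover - solver backend detail
        raise RuntimeError(f"linear solve failed: {exc}") from exc
    if not np.isfinite(u_f).all():
        raise RuntimeError("singular system: insufficient constraints")
    u[free] = u_f

    fnorm = np.linalg.norm(f[free])
    res = np.linalg.norm(Kff @ u_f - f[free]) / max(fnorm, 1e-300)
    if fnorm > 0 and res > rtol:
        raise RuntimeError(f"linear solver residual {res:.2e} exceeds {rtol:g}")

    # Element stresses from constant-strain kinematics.
    coords = mesh.nodes[mesh.tets]
    g, _ = _gradients(coords)
    B = _b_matrices(g)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(mesh.n_tets, 12)
    eps = np.einsum("mij,mj->mi", B, ue)
    stress = np.zeros_like(eps)
    for label, mat in materials.items():
        idx = mesh.material == label
        if idx.any():
            stress[idx] = eps[idx] @ elasticity_matrix(mat).T
    vm = von_mises(stress)

    r = K @ u - f
    reactions = np.zeros((mesh.n_nodes, 3))
    reactions.reshape(-1)[con] = r[con]

    con_node_mask = np.zeros(mesh.n_nodes, dtype=bool)
    con_node_mask[con_nodes] = True
    return SolutionField(
        displacement=u.reshape(-1, 3), stress=stress, von_mises=vm,
        reactions=reactions, constrained=con_node_mask,
        residual=float(res) if fnorm > 0 else 0.0,
        applied=f.reshape(-1, 3))


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt tensors [xx yy zz xy yz zx]."""
    s = np.atleast_2d(np.asarray(stress, dtype=float))
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                 + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))
    return vm if stress.ndim > 1 else float(vm[0])


def reaction_force(solution: SolutionField, node_set: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """Net reaction (vector, magnitude) summed over a constrained node set.

    At the bite constraint the magnitude is the model bite force (equal
    and opposite to the force on the food item).
    """
    node_set = np.asarray(node_set)
    if not solution.constrained[node_set].all():
        raise ValueError("node set contains unconstrained nodes")
    vec = solution.reactions[node_set].sum(axis=0)
    return vec, float(np.linalg.norm(vec))


def convergence_check(params, scenario_loads, materials=None,
                      resolutions=(1000, 2000, 4000, 8000),
                      bite_mode: str = "base", seed: int = 0,
                      threshold: float = 0.05) -> dict:
    """Mesh-refinement study: peak regional vM stress and bite force.

    Generates the beak at each target resolution, solves the given load
    case, and reports the relative change of both quantities per
    refinement level.  Passes when the final doubling changes both by
    less than ``threshold`` (default 5%).
    """
    from .beak_geometry import generate_beak_mesh
    from .load_cases import build_case, ScenarioSpec
    from .stress_report import summarize

    if len(resolutions) < 2:
        raise ValueError("need at least two resolutions")
    if materials is None:
        materials = DEFAULT_MATERIALS

    peaks, forces, sizes = [], [], []
    for res in resolutions:
        mesh = generate_beak_mesh(params, resolution=res, seed=seed)
        case = build_case(mesh, ScenarioSpec(scenario="physiological",
                                             bite_mode=bite_mode),
                          scenario_loads)
        sol = solve_static(mesh, materials, case)
        summ = summarize(sol, mesh, scenario="physiological",
                         bite_mode=bite_mode)
        peaks.append(summ.vM1)
        forces.append(summ.bite_force)
        sizes.append(mesh.n_tets)

    peaks, forces = np.array(peaks), np.array(forces)
    dpeak = np.abs(np.diff(peaks)) / peaks[:-1]
    dforce = np.abs(np.diff(forces)) / forces[:-1]
    return dict(
        resolutions=list(resolutions), n_tets=sizes,
        peak_vm=peaks.tolist(), bite_force=forces.tolist(),
        peak_vm_change=dpeak.tolist(), bite_force_change=dforce.tolist(),
        passed=bool(dpeak[-1] < threshold and dforce[-1] < threshold),
        threshold=threshold)
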