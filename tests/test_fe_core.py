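"""FE solver verification: element oracle, patch test, beam, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from finchbeak.beak_geometry import TetMesh
from finchbeak.fe_core import (DEFAULT_MATERIALS, LoadCase, Material,
                               assemble, assemble_load_vector,
                               convergence_check, element_stiffness,
                               reaction_force, solve_static, von_mises)
from conftest import box_mesh, clamped_case, end_face_loads

MAT = Material(E=1000.0, nu=0.0)
MAT_NU = Material(E=1000.0, nu=0.3)


def _hand_element_stiffness(coords, material):
    """Independent oracle: shape-function coefficients from the 4x4
    Vandermonde inverse, explicit B assembly, K = V B^T D B."""
    coords = np.asarray(coords, float)
    A = np.hstack([np.ones((4, 1)), coords])
    V = abs(np.linalg.det(A)) / 6.0
    C = np.linalg.inv(A)            # row 1..3 of column i = grad N_i
    B = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = C[1, i], C[2, i], C[3, i]
        B[0, 3 * i] = bx
        B[1, 3 * i + 1] = by
        B[2, 3 * i + 2] = bz
        B[3, 3 * i], B[3, 3 * i + 1] = by, bx
        B[4, 3 * i + 1], B[4, 3 * i + 2] = bz, by
        B[5, 3 * i], B[5, 3 * i + 2] = bz, bx
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.diag([2 * mu] * 3 + [mu] * 3).astype(float)
    D[:3, :3] += lam
    return V * B.T @ D @ B


REF_TET = np.array([[0., 0., 0.], [1., 0., 0.], [0., 1., 0.], [0., 0., 1.]])


class TestElementStiffness:
    def test_matches_hand_assembly_on_reference_tet(self):
        K = element_stiffness(REF_TET, Material(E=1.0, nu=0.0))
        K_ref = _hand_element_stiffness(REF_TET, Material(E=1.0, nu=0.0))
        assert np.allclose(K, K_ref, atol=1e-14)

    def test_matches_hand_assembly_general(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            coords = REF_TET + 0.2 * rng.standard_normal((4, 3))
            if np.linalg.det(coords[1:] - coords[0]) <= 0:
                continue
            K = element_stiffness(coords, MAT_NU)
            assert np.allclose(K, _hand_element_stiffness(coords, MAT_NU),
                               rtol=1e-12, atol=1e-10)

    def test_symmetry(self):
        K = element_stiffness(REF_TET, MAT_NU)
        assert np.allclose(K, K.T, atol=1e-12)

    def test_rigid_body_modes(self):
        """Translations and linearised rotations produce zero force."""
        K = element_stiffness(REF_TET, MAT_NU)
        for t in np.eye(3):
            u = np.tile(t, 4)
            assert np.allclose(K @ u, 0.0, atol=1e-12)
        for axis in np.eye(3):
            u = np.cross(axis, REF_TET).ravel()
            assert np.allclose(K @ u, 0.0, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6

    def test_degenerate_rejected(self):
        flat = REF_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="degenerate"):
            element_stiffness(flat, MAT)


class TestAssemble:
    def test_matches_dense_scatter_oracle(self):
        mesh = box_mesh(1, 1, 1, 1, 1, 1)
        K = assemble(mesh, {"bone": MAT_NU}).toarray()
        dense = np.zeros_like(K)
        for tet in mesh.tets:
            Ke = element_stiffness(mesh.nodes[tet], MAT_NU)
            dof = (3 * tet[:, None] + np.arange(3)).ravel()
            dense[np.ix_(dof, dof)] += Ke
        assert np.allclose(K, dense, rtol=1e-12, atol=1e-9)

    def test_linearity_in_modulus(self):
        mesh = box_mesh(2, 1, 1, 2, 1, 1)
        K1 = assemble(mesh, {"bone": Material(E=500.0, nu=0.25)})
        K2 = assemble(mesh, {"bone": Material(E=1000.0, nu=0.25)})
        assert np.allclose(K2.toarray(), 2 * K1.toarray(), rtol=1e-12)

    def test_disconnected_node_has_zero_row(self):
        nodes = np.vstack([REF_TET, [5.0, 5.0, 5.0]])
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]),
                       material=np.array(["bone"]))
        K = assemble(mesh, {"bone": MAT}).toarray()
        assert np.all(K[12:, :] == 0) and np.all(K[:, 12:] == 0)

    def test_missing_material_rejected(self):
        mesh = box_mesh(1, 1, 1, 1, 1, 1)
        with pytest.raises(KeyError):
            assemble(mesh, {"keratin": MAT})


class TestSolve:
    def test_zero_loads_zero_everything(self):
        mesh = box_mesh(2, 2, 2, 1, 1, 1)
        case = clamped_case(mesh, [("p", np.array([mesh.n_nodes - 1]),
                                    np.zeros(3))])
        sol = solve_static(mesh, {"bone": MAT}, case)
        assert np.allclose(sol.displacement, 0)
        assert np.allclose(sol.stress, 0)
        assert np.allclose(sol.reactions, 0)

    def test_patch_test_exact(self):
        """Uniform end traction on a bar gives exactly uniform F/A axial
        stress: constant-strain tets pass the patch test."""
        mesh = box_mesh(4, 2, 2, 4.0, 1.0, 1.0)
        loads, A = end_face_loads(mesh, 4.0, [2.0, 0.0, 0.0])
        sol = solve_static(mesh, {"bone": MAT}, clamped_case(mesh, loads))
        assert np.allclose(sol.stress[:, 0], 2.0 / A, rtol=1e-10)
        assert np.abs(sol.stress[:, 1:]).max() < 1e-10

    def test_bar_reaction_balances_load(self):
        mesh = box_mesh(4, 2, 2, 4.0, 1.0, 1.0)
        loads, _ = end_face_loads(mesh, 4.0, [2.0, 0.0, 0.0])
        case = clamped_case(mesh, loads)
        sol = solve_static(mesh, {"bone": MAT}, case)
        vec, mag = reaction_force(sol, case.fixed_nodes)
        assert np.allclose(vec, [-2.0, 0.0, 0.0], atol=1e-10)

    def test_cantilever_matches_beam_theory(self):
        """Tip deflection of a slender cantilever (L/h = 10) within 10%
        of Euler-Bernoulli P L^3 / (3 E I) at the reference resolution,
        improving under refinement."""
        L, h, P = 20.0, 2.0, 1.0
        I = h ** 4 / 12
        euler = -P * L ** 3 / (3 * MAT.E * I)
        defl = []
        for dims in ((40, 4, 4), (60, 6, 6)):
            mesh = box_mesh(*dims, L, h, h)
            loads, _ = end_face_loads(mesh, L, [0.0, 0.0, -P])
            sol = solve_static(mesh, {"bone": MAT}, clamped_case(mesh, loads))
            tip = np.flatnonzero(np.isclose(mesh.nodes[:, 0], L))
            defl.append(sol.displacement[tip, 2].mean())
        assert abs(defl[-1] - euler) / abs(euler) < 0.10
        assert abs(defl[1] - euler) < abs(defl[0] - euler)   # refining helps

    def test_dense_oracle_equivalence_small_mesh(self):
        """Sparse path matches a brute-force dense solve to 1e-10 on a
        <= 200-DOF mesh."""
        mesh = box_mesh(2, 2, 1, 2.0, 1.0, 0.5)       # 27 nodes, 81 DOF
        loads, _ = end_face_loads(mesh, 2.0, [0.3, -0.2, 0.5])
        case = clamped_case(mesh, loads)
        sol = solve_static(mesh, {"bone": MAT_NU}, case)

        K = np.zeros((3 * mesh.n_nodes, 3 * mesh.n_nodes))
        for tet in mesh.tets:
            Ke = _hand_element_stiffness(mesh.nodes[tet], MAT_NU)
            dof = (3 * tet[:, None] + np.arange(3)).ravel()
            K[np.ix_(dof, dof)] += Ke
        f = assemble_load_vector(mesh.n_nodes, case.point_loads)
        fix = np.zeros(3 * mesh.n_nodes, bool)
        fix[(3 * case.fixed_nodes[:, None] + np.arange(3)).ravel()] = True
        u = np.zeros(3 * mesh.n_nodes)
        u[~fix] = np.linalg.solve(K[np.ix_(~fix, ~fix)], f[~fix])
        assert np.allclose(sol.displacement.ravel(), u, rtol=1e-10,
                           atol=1e-14)

    def test_linearity_in_load(self, crush_mesh, crush_solutions):
        case, sol = crush_solutions["base"]
        scaled = LoadCase(fixed_nodes=case.fixed_nodes,
                          bite_nodes=case.bite_nodes,
                          point_loads=[(n, i, 3.0 * f)
                                       for n, i, f in case.point_loads],
                          bite_mode=case.bite_mode)
        sol3 = solve_static(crush_mesh, DEFAULT_MATERIALS, scaled)
        assert np.allclose(sol3.displacement, 3 * sol.displacement,
                           rtol=1e-8, atol=1e-12)
        _, F1 = reaction_force(sol, case.bite_nodes)
        _, F3 = reaction_force(sol3, case.bite_nodes)
        assert F3 == pytest.approx(3 * F1, rel=1e-8)

    def test_equilibrium_residual(self, crush_solutions):
        for _, sol in crush_solutions.values():
            total = sol.reactions.sum(0) + sol.applied.sum(0)
            scale = max(1.0, np.linalg.norm(sol.applied.sum(0)))
            assert np.linalg.norm(total) / scale < 1e-8
            assert sol.residual < 1e-8

    def test_frame_invariance(self):
        """Rigid rotation of mesh and loads leaves von Mises unchanged."""
        mesh = box_mesh(3, 2, 2, 3.0, 1.0, 1.0)
        loads, _ = end_face_loads(mesh, 3.0, [0.1, -0.4, 0.25])
        sol = solve_static(mesh, {"bone": MAT_NU}, clamped_case(mesh, loads))

        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        rmesh = mesh.copy()
        rmesh.nodes = mesh.nodes @ R.T
        rloads = [(n, i, R @ f) for n, i, f in loads]
        fixed = np.flatnonzero(np.isclose(mesh.nodes[:, 0], 0.0))
        rcase = LoadCase(fixed_nodes=fixed, bite_nodes=np.array([], int),
                         point_loads=rloads)
        rsol = solve_static(rmesh, {"bone": MAT_NU}, rcase)
        assert np.allclose(rsol.von_mises, sol.von_mises, rtol=1e-8)

    def test_stress_scaling_law(self):
        """Uniform geometric scaling by s under identical loads scales
        stresses by 1/s^2 and displacements by 1/s."""
        mesh = box_mesh(3, 2, 2, 3.0, 1.0, 1.0)
        loads, _ = end_face_loads(mesh, 3.0, [0.2, -0.1, 0.3])
        sol = solve_static(mesh, {"bone": MAT_NU}, clamped_case(mesh, loads))

        s = 2.0
        big = mesh.copy()
        big.nodes = mesh.nodes * s
        bloads, _ = end_face_loads(big, 3.0 * s, [0.2, -0.1, 0.3])
        bsol = solve_static(big, {"bone": MAT_NU}, clamped_case(big, bloads))
        assert np.allclose(bsol.von_mises, sol.von_mises / s ** 2, rtol=1e-9)
        assert np.allclose(bsol.displacement, sol.displacement / s,
                           rtol=1e-9, atol=1e-15)

    def test_insufficient_constraints_detected(self):
        mesh = box_mesh(1, 1, 1, 1, 1, 1)
        case = LoadCase(fixed_nodes=np.array([0]),   # one node: rotations free
                        bite_nodes=np.array([], int),
                        point_loads=[("p", np.array([mesh.n_nodes - 1]),
                                      np.array([0.0, 1.0, 0.0]))])
        with pytest.raises(RuntimeError):
            solve_static(mesh, {"bone": MAT}, case)


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises(np.array([7.0, 0, 0, 0, 0, 0])) == pytest.approx(7.0)

    def test_pure_shear(self):
        assert von_mises(np.array([0, 0, 0, 3.0, 0, 0])) == pytest.approx(
            3.0 * np.sqrt(3.0))

    def test_hydrostatic(self):
        assert von_mises(np.array([-5.0, -5.0, -5.0, 0, 0, 0])) == \
            pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(s=st.lists(st.floats(-100, 100), min_size=6, max_size=6),
           p=st.floats(-50, 50))
    def test_nonnegative_and_pressure_invariant(self, s, p):
        s = np.array(s)
        vm = von_mises(s)
        assert vm >= 0
        shifted = s + np.array([p, p, p, 0, 0, 0])
        assert von_mises(shifted) == pytest.approx(vm, rel=1e-9, abs=1e-9)


class TestReactionForce:
    def test_unconstrained_set_rejected(self, crush_mesh, crush_solutions):
        case, sol = crush_solutions["base"]
        free = np.setdiff1d(np.arange(crush_mesh.n_nodes),
                            case.constrained_nodes)[:3]
        with pytest.raises(ValueError, match="unconstrained"):
            reaction_force(sol, free)

    def test_tip_bite_force_below_base(self, crush_mesh, crush_solutions):
        """Out-lever effect: identical muscle loads produce a smaller
        bite force at the tip than at the base."""
        _, F_base = reaction_force(crush_solutions["base"][1],
                                   crush_solutions["base"][0].bite_nodes)
        _, F_tip = reaction_force(crush_solutions["tip"][1],
                                  crush_solutions["tip"][0].bite_nodes)
        assert F_tip < F_base


class TestConvergenceCheck:
    def test_same_resolution_zero_change(self, crush_params,
                                         reference_loads):
        rep = convergence_check(crush_params, reference_loads,
                                resolutions=(2000, 2000))
        assert rep["peak_vm_change"][-1] == pytest.approx(0.0, abs=1e-12)
        assert rep["bite_force_change"][-1] == pytest.approx(0.0, abs=1e-12)
        assert rep["passed"]

    def test_needs_two_levels(self, crush_params, reference_loads):
        with pytest.raises(ValueError):
            convergence_check(crush_params, reference_loads,
                              resolutions=(2000,))
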