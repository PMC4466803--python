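"""Parametric beak generator: shape defaults, mesh contracts, measurement."""

import numpy as np
import pytest

from finchbeak.beak_geometry import (TetMesh, boundary_faces,
                                     generate_beak_mesh, make_shape_params,
                                     measure_shape, mesh_quality,
                                     surface_area, tet_volumes)
from conftest import box_mesh


class TestShapeParams:
    @pytest.mark.parametrize("group,field,value", [
        ("crush", "depth_ratio", 0.22),
        ("crush", "width_ratio", 0.406),
        ("crush", "ker_bottom_ratio", 0.095),
        ("crush", "ker_top_ratio", 0.023),
        ("probe", "depth_ratio", 0.120),
        ("probe", "ker_bottom_ratio", 0.029),
    ])
    def test_group_defaults(self, group, field, value):
        assert getattr(make_shape_params(group), field) == value

    def test_override_passthrough(self):
        p = make_shape_params("crush", {"depth_ratio": 0.30})
        assert p.depth_ratio == 0.30
        assert p.width_ratio == 0.406        # untouched default

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown functional group"):
            make_shape_params("gulp")

    @pytest.mark.parametrize("bad", [
        {"depth_ratio": -0.1},
        {"curvature": 1.2},
        {"ker_bottom_ratio": 0.2, "ker_top_ratio": 0.1, "depth_ratio": 0.25},
        {"length": 0.0},
    ])
    def test_invariant_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            make_shape_params("crush", bad)


class TestGeneratedMesh:
    def test_contract(self, crush_mesh):
        assert crush_mesh.n_tets >= 5000
        assert set(np.unique(crush_mesh.material)) == {"bone", "keratin"}
        for name in ("back_fixed", "bite_tip", "bite_base_unilateral",
                     "jugal_attach_left", "jugal_attach_right",
                     "palatine_attach"):
            assert len(crush_mesh.node_sets[name]) > 0
        for name in ("region_bite_tip", "region_bite_base",
                     "region_nasal_hinge", "region_nasal_left",
                     "region_nasal_right", "bending_area"):
            assert len(crush_mesh.element_regions[name]) > 0

    def test_determinism(self, crush_params, crush_mesh):
        again = generate_beak_mesh(crush_params, resolution=5000, seed=1)
        assert again.content_hash() == crush_mesh.content_hash()

    def test_material_labels_partition(self, crush_mesh):
        bone = crush_mesh.material == "bone"
        ker = crush_mesh.material == "keratin"
        assert (bone ^ ker).all()

    def test_positive_volumes(self, crush_mesh):
        assert (tet_volumes(crush_mesh.nodes, crush_mesh.tets) > 0).all()

    def test_bite_nodes_on_ventral_keratin_surface(self, crush_mesh):
        outer = set(crush_mesh.node_sets["outer_surface"].tolist())
        L = crush_mesh.metadata["length"]
        for name in ("bite_tip", "bite_base_unilateral"):
            sel = crush_mesh.node_sets[name]
            assert set(sel.tolist()) <= outer
            zf = crush_mesh.nodes[sel, 2] / L
            yc = -crush_mesh.metadata["params"].curvature * L * zf ** 2
            assert (crush_mesh.nodes[sel, 1] < yc).all()   # below axis

    def test_probe_smaller_than_crush(self):
        """At equal length, a probing beak encloses less volume and has a
        thinner ventral keratin layer than a crushing beak (measured from
        the meshes, not from the input parameters)."""
        crush = generate_beak_mesh(make_shape_params("crush",
                                                     {"length": 12.0}),
                                   resolution=4000, seed=0)
        probe = generate_beak_mesh(make_shape_params("probe",
                                                     {"length": 12.0}),
                                   resolution=4000, seed=0)
        vc = tet_volumes(crush.nodes, crush.tets).sum()
        vp = tet_volumes(probe.nodes, probe.tets).sum()
        assert vp < vc
        kc = measure_shape(crush, n_samples=2500)["ker_bottom_ratio"]
        kp = measure_shape(probe, n_samples=2500)["ker_bottom_ratio"]
        assert kp < kc

    def test_geometric_fidelity_within_5pct(self, crush_mesh, crush_params):
        meas = measure_shape(crush_mesh)
        for f in ("depth_ratio", "width_ratio", "ker_bottom_ratio",
                  "ker_top_ratio"):
            want = getattr(crush_params, f)
            assert abs(meas[f] - want) / want < 0.05, f

    def test_resolution_floor(self, crush_params):
        with pytest.raises(ValueError, match="resolution"):
            generate_beak_mesh(crush_params, resolution=100)


class TestSurfaceArea:
    def test_unit_cube(self):
        mesh = box_mesh(1, 1, 1, 1.0, 1.0, 1.0)
        assert surface_area(mesh) == pytest.approx(6.0)

    def test_similarity_scaling(self, crush_mesh):
        scaled = crush_mesh.copy()
        scaled.nodes = scaled.nodes * 2.0
        assert surface_area(scaled) == pytest.approx(
            4.0 * surface_area(crush_mesh), rel=1e-12)

    def test_matches_bruteforce_boundary_walk(self, crush_mesh):
        """Independent oracle: count faces by a dict-based face walk and
        sum triangle areas over outer-surface faces."""
        from collections import Counter
        counts = Counter()
        store = {}
        for tet in crush_mesh.tets:
            a, b, c, d = (int(v) for v in tet)
            for tri in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                key = tuple(sorted(tri))
                counts[key] += 1
                store[key] = tri
        on = np.zeros(crush_mesh.n_nodes, bool)
        on[crush_mesh.node_sets["outer_surface"]] = True
        total = 0.0
        for key, cnt in counts.items():
            if cnt == 1 and all(on[list(key)]):
                p0, p1, p2 = crush_mesh.nodes[list(store[key])]
                total += np.linalg.norm(np.cross(p1 - p0, p2 - p0)) / 2
        assert surface_area(crush_mesh) == pytest.approx(total, rel=1e-12)

    def test_refinement_stability(self, crush_params):
        a1 = surface_area(generate_beak_mesh(crush_params, 4000, seed=0))
        a2 = surface_area(generate_beak_mesh(crush_params, 8000, seed=0))
        assert abs(a2 - a1) / a1 < 0.02

    def test_no_boundary_error(self):
        mesh = TetMesh(nodes=np.zeros((0, 3)),
                       tets=np.zeros((0, 4), dtype=int),
                       material=np.array([], dtype="U7"))
        with pytest.raises(ValueError):
            surface_area(mesh)


class TestMeshQuality:
    def test_regular_tet_aspect_one(self):
        # circumradius/(3*inradius) = 1 for the regular tetrahedron
        nodes = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float)
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 3, 2]]),
                       material=np.array(["bone"]))
        q = mesh_quality(mesh)
        assert q["max_aspect_ratio"] == pytest.approx(1.0)
        assert q["inverted_count"] == 0

    def test_sliver_flagged(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                          [0.5, 0.5, 1e-4]])
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]),
                       material=np.array(["bone"]))
        q = mesh_quality(mesh, aspect_threshold=25.0)
        assert q["n_above_threshold"] == 1

    def test_generated_beaks_never_inverted(self):
        for group in ("crush", "probe", "tip"):
            mesh = generate_beak_mesh(make_shape_params(group), 1500, seed=3)
            assert mesh_quality(mesh)["inverted_count"] == 0
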