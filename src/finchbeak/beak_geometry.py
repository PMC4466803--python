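"""Parametric two-material beak meshes.

The upper beak of a finch is idealised as a superelliptical cross-section
lofted along a curved axis with power-law taper: a thin-walled bony core
(the bone shell) wrapped in a keratin sheath (the rhamphotheca).  A dorsal
band of thinned bone near the base provides the compliant nasal hinge that
lets the upper beak flex against the neurocranium.

The four functional beak types (crush, probe-and-base-crush, probe,
tip-bite) are parameterised by their group-mean shape ratios: beak depth,
beak width, and dorsal/ventral keratin thickness, all relative to beak
length.  Meshes carry every named node set and element region the
downstream load cases and stress reports need.

Coordinate convention: z runs from the beak base (z = 0, at the
neurocranium) to the tip (z = length); +y is dorsal; x is lateral, with
the bilateral symmetry plane at x = 0.  Units are millimetres.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeakShapeParams",
    "TetMesh",
    "FUNCTIONAL_GROUPS",
    "GROUP_SPECIES",
    "make_shape_params",
    "generate_beak_mesh",
    "surface_area",
    "mesh_quality",
    "measure_shape",
    "tet_volumes",
    "boundary_faces",
]

# Group-mean shape ratios (relative to beak length) for the four
# functional beak types, and the species conventionally assigned to each.
FUNCTIONAL_GROUPS = {
    "crush": dict(
        depth_ratio=0.22, width_ratio=0.406,
        ker_bottom_ratio=0.095, ker_top_ratio=0.023,
    ),
    "probe_and_base": dict(
        depth_ratio=0.161, width_ratio=0.35,
        ker_bottom_ratio=0.067, ker_top_ratio=0.0205,
    ),
    "probe": dict(
        depth_ratio=0.120, width_ratio=0.304,
        ker_bottom_ratio=0.029, ker_top_ratio=0.018,
    ),
    "tip": dict(
        depth_ratio=0.22, width_ratio=0.44,
        ker_bottom_ratio=0.08, ker_top_ratio=0.035,
    ),
}

GROUP_SPECIES = {
    "crush": ["G. fortis", "G. fuliginosa", "G. magnirostris"],
    "probe_and_base": ["G. scandens", "G. difficilis", "G. conirostris"],
    "probe": ["C. olivacea", "P. inornata"],
    "tip": ["C. parvulus", "C. pauper", "C. psittacula", "C. pallida",
            "P. crassirostris"],
}


@dataclass(frozen=True)
class BeakShapeParams:
    """Shape descriptors of a parametric beak.

    All ``*_ratio`` fields are dimensionless fractions of beak length.
    ``curvature`` is the ventral drop of the tip divided by length;
    ``taper_exponent`` controls how fast the cross-section shrinks
    towards the tip.
    """

    length: float = 15.0                 # mm
    depth_ratio: float = 0.22
    width_ratio: float = 0.406
    ker_bottom_ratio: float = 0.095
    ker_top_ratio: float = 0.023
    bone_wall_ratio: float = 0.02
    curvature: float = 0.10
    taper_exponent: float = 1.5
    group: str = "crush"

    def __post_init__(self) -> None:
        ratios = dict(
            depth_ratio=self.depth_ratio, width_ratio=self.width_ratio,
            ker_bottom_ratio=self.ker_bottom_ratio,
            ker_top_ratio=self.ker_top_ratio,
            bone_wall_ratio=self.bone_wall_ratio,
        )
        for name, v in ratios.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if not 0 <= self.curvature < 1:
            raise ValueError(f"curvature must be in [0, 1), got {self.curvature}")
        if self.taper_exponent <= 0:
            raise ValueError("taper_exponent must be > 0")
        if self.ker_bottom_ratio + self.ker_top_ratio >= self.depth_ratio:
            raise ValueError(
                "keratin thicknesses exceed beak depth: "
                f"{self.ker_bottom_ratio} + {self.ker_top_ratio} >= "
                f"{self.depth_ratio}")
        if self.group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"unknown functional group {self.group!r}")


def make_shape_params(group: str, overrides: dict | None = None) -> BeakShapeParams:
    """Shape parameters for a functional group, with optional overrides.

    Defaults are the group-mean ratios of the reference morphometric
    dataset; any field of :class:`BeakShapeParams` can be overridden.
    """
    if group not in FUNCTIONAL_GROUPS:
        raise ValueError(
            f"unknown functional group {group!r}; "
            f"expected one of {sorted(FUNCTIONAL_GROUPS)}")
    params = BeakShapeParams(group=group, **FUNCTIONAL_GROUPS[group])
    if overrides:
        params = replace(params, **overrides)
    return params


@dataclass
class TetMesh:
    """Tetrahedral mesh with two material labels and named sets.

    ``nodes`` is (n, 3) float64 in mm; ``tets`` is (m, 4) int with
    positive signed volume; ``material`` is an (m,) array of ``"bone"`` /
    ``"keratin"`` labels.  ``node_sets`` and ``element_regions`` hold the
    named index sets downstream load cases and stress reports rely on.
    """

    nodes: np.ndarray
    tets: np.ndarray
    material: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_regions: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(), tets=self.tets.copy(),
            material=self.material.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_regions={k: v.copy() for k, v in self.element_regions.items()},
            metadata=dict(self.metadata))

    def validate(self) -> None:
        vols = tet_volumes(self.nodes, self.tets)
        if not (vols > 0).all():
            bad = int((vols <= 0).sum())
            raise ValueError(f"{bad} tetrahedra have non-positive volume")
        for name, idx in self.node_sets.items():
            if len(idx) == 0:
                raise ValueError(f"empty node set {name!r}")
            if idx.min() < 0 or idx.max() >= self.n_nodes:
                raise ValueError(f"node set {name!r} out of bounds")
        for name, idx in self.element_regions.items():
            if len(idx) == 0:
                raise ValueError(f"empty element region {name!r}")
            if idx.min() < 0 or idx.max() >= self.n_tets:
                raise ValueError(f"element region {name!r} out of bounds")
        labels = set(np.unique(self.material))
        if not labels <= {"bone", "keratin"}:
            raise ValueError(f"unexpected material labels {labels}")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.nodes.tobytes())
        h.update(self.tets.astype(np.int64).tobytes())
        h.update("".join(self.material).encode())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.sort(self.node_sets[name]).astype(np.int64).tobytes())
        for name in sorted(self.element_regions):
            h.update(name.encode())
            h.update(np.sort(self.element_regions[name]).astype(np.int64).tobytes())
        return h.hexdigest()


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    x = nodes[tets]
    e = x[:, 1:] - x[:, :1]
    return np.linalg.det(e) / 6.0


# --- structured generator -------------------------------------------------

# Six-tet decomposition of a hexahedron around the 0-6 diagonal.  Applied
# uniformly over a structured grid this triangulates every interior quad
# face compatibly (shared faces get the same diagonal from both sides).
_HEX_TETS = np.array([
    [0, 1, 2, 6],
    [0, 2, 3, 6],
    [0, 1, 6, 5],
    [0, 5, 6, 4],
    [0, 3, 7, 6],
    [0, 7, 4, 6],
])

_SECTION_EXPONENT = 2.5     # superellipse exponent of the cross-section
_TIP_SCALE = 0.18           # residual cross-section scale at the tip
_BONE_TIP_FRACTION = 0.90   # axial extent of the bony core
_HINGE_CENTER = 0.065       # axial centre of the nasal-hinge band
_HINGE_SIGMA = 0.030        # axial half-width of the band (Gaussian)
_HINGE_FACTOR = 0.45        # bone-wall thinning factor at the hinge
_N_BONE_LAYERS = 2
_N_KER_LAYERS = 2


def _grid_dims(resolution: int) -> tuple[int, int]:
    """Axial and half-circumferential segment counts for a target tet count."""
    n_rad = _N_BONE_LAYERS + _N_KER_LAYERS
    # tets = 6 * n_ax * (2 m) * n_rad; keep axial cells ~2.5x denser than
    # circumferential ones so elements stay reasonably shaped.
    cells = resolution / (6 * 2 * n_rad)
    n_ax = max(12, int(np.ceil(np.sqrt(2.5 * cells))))
    n_ax = 4 * int(np.ceil(n_ax / 4))   # keep a station exactly at 1/4 length
    m = max(6, int(np.ceil(cells / n_ax)))
    return n_ax, m


def generate_beak_mesh(params: BeakShapeParams, resolution: int = 5000,
                       seed: int = 0, jitter: float = 0.0) -> TetMesh:
    """Build a layered tetrahedral beak mesh.

    The mesh is a closed annular shell: a hollow bony core (two element
    layers) sheathed in keratin (two element layers), lofted from the
    fixed back rim to an open tapered tip.  Node positions are fully
    deterministic unless ``jitter`` > 0, in which case interior nodes are
    perturbed by seeded uniform noise of that fraction of the local
    element size.

    Parameters
    ----------
    params : BeakShapeParams
    resolution : target (minimum) number of tetrahedra, >= 500
    seed : RNG seed, used only when ``jitter`` > 0
    jitter : interior-node perturbation as a fraction of element size
    """
    if resolution < 500:
        raise ValueError("resolution must be >= 500 elements")
    L = params.length
    n_ax, m = _grid_dims(resolution)
    n_rad = _N_BONE_LAYERS + _N_KER_LAYERS

    u = np.linspace(0.0, 1.0, n_ax + 1)                 # axial stations
    phi = np.linspace(-np.pi / 2, np.pi / 2, m + 1)     # ventral -> dorsal

    D, W = params.depth_ratio * L, params.width_ratio * L
    t_kb, t_kt = params.ker_bottom_ratio * L, params.ker_top_ratio * L
    t_bone = params.bone_wall_ratio * L
    # Asymmetric semi-depths: leave room ventrally for the thick bottom
    # keratin plus the bone wall plus a minimal cavity.
    b_v = max(D / 2, t_kb + t_bone + 0.03 * D)
    b_d = D - b_v
    if b_d <= t_kt + t_bone * 0.2:
        raise ValueError(
            "degenerate cross-section: dorsal semi-depth too small for the "
            f"requested keratin/bone thicknesses (params={params})")
    a = W / 2

    p = _SECTION_EXPONENT
    s_ax = 1.0 - (1.0 - _TIP_SCALE) * u ** params.taper_exponent
    y_center = -params.curvature * L * u ** 2

    cphi, sphi = np.cos(phi), np.sin(phi)
    ex = np.sign(cphi) * np.abs(cphi) ** (2 / p)
    ey = np.sign(sphi) * np.abs(sphi) ** (2 / p)
    b_phi = np.where(sphi >= 0, b_d, b_v)
    ker_phi = t_kb + (t_kt - t_kb) * (sphi + 1) / 2

    # Outer boundary of each (station, column): (n_ax+1, m+1, 2) in (x, y).
    rx = s_ax[:, None] * a * ex[None, :]
    ry = s_ax[:, None] * b_phi[None, :] * ey[None, :]
    rho_out = np.hypot(rx, ry)
    with np.errstate(invalid="ignore"):
        edir = np.stack([rx, ry], axis=-1) / rho_out[..., None]

    # Bone-wall thinning at the dorsal nasal hinge, smooth in u and phi so
    # the geometry refines consistently across resolutions.
    hinge_w = np.exp(-((u - _HINGE_CENTER) / _HINGE_SIGMA) ** 2)
    dorsal_w = np.clip(sphi, 0.0, 1.0) ** 2
    t_b = t_bone * (1.0 - (1.0 - _HINGE_FACTOR) * hinge_w[:, None] * dorsal_w[None, :])

    # Layer interfaces, clamped so the cavity never inverts near the tip
    # (there the section compresses to mostly keratin around a sliver core);
    # the floors are small fractions of the local outer radius so they
    # never bind at the base, where the requested thicknesses must hold.
    # Layer thicknesses shrink partially with the taper (real beak walls
    # thin distally); the factor is 1 at the base so the requested
    # ratios hold where they are measured.
    th_scale = (0.35 + 0.65 * s_ax)[:, None]
    rho1 = np.maximum(rho_out - ker_phi[None, :] * th_scale, 0.15 * rho_out)
    rho0 = np.maximum(rho1 - t_b * th_scale, 0.05 * rho_out)
    rho0 = np.minimum(rho0, rho1 - 0.03 * rho_out)

    # Radial node fractions: _N_BONE_LAYERS between rho0..rho1, then
    # _N_KER_LAYERS between rho1..rho2.
    radii = np.empty(rho_out.shape + (n_rad + 1,))
    for k in range(_N_BONE_LAYERS + 1):
        radii[..., k] = rho0 + (rho1 - rho0) * k / _N_BONE_LAYERS
    for k in range(1, _N_KER_LAYERS + 1):
        radii[..., _N_BONE_LAYERS + k] = rho1 + (rho_out - rho1) * k / _N_KER_LAYERS

    # Half-grid nodes, index (i, j, k).
    nid = np.arange((n_ax + 1) * (m + 1) * (n_rad + 1)).reshape(
        n_ax + 1, m + 1, n_rad + 1)
    half = np.empty(((n_ax + 1) * (m + 1) * (n_rad + 1), 3))
    X = edir[..., 0:1] * radii        # (n_ax+1, m+1, n_rad+1)
    Y = y_center[:, None, None] + edir[..., 1:2] * radii
    Z = np.broadcast_to((u * L)[:, None, None], X.shape)
    half[:, 0] = X.reshape(-1)
    half[:, 1] = Y.reshape(-1)
    half[:, 2] = Z.reshape(-1)
    # Seam columns (phi = +-pi/2) sit exactly on the symmetry plane.
    seam = np.zeros((n_ax + 1, m + 1, n_rad + 1), dtype=bool)
    seam[:, 0, :] = True
    seam[:, -1, :] = True
    half[seam.reshape(-1), 0] = 0.0

    if jitter > 0:
        rng = np.random.default_rng(seed)
        interior = np.ones(len(half), dtype=bool)
        bnd = np.zeros_like(seam)
        bnd[0], bnd[-1] = True, True
        bnd[:, :, 0], bnd[:, :, -1] = True, True
        interior &= ~(seam | bnd).reshape(-1)
        h = L / n_ax * jitter
        half[interior] += rng.uniform(-h, h, (int(interior.sum()), 3))

    # Mirror across x = 0; seam nodes are shared.
    mirror_id = np.empty_like(nid)
    keep = ~seam
    n_half = len(half)
    extra = half[keep.reshape(-1)].copy()
    extra[:, 0] *= -1.0
    mirror_id[keep] = n_half + np.arange(len(extra))
    mirror_id[seam] = nid[seam]
    nodes = np.vstack([half, extra])

    # Hexes of the half grid: local frame (j, i, k) is right-handed here.
    I, J, K = np.meshgrid(np.arange(n_ax), np.arange(m), np.arange(n_rad),
                          indexing="ij")
    I, J, K = I.reshape(-1), J.reshape(-1), K.reshape(-1)
    hexes = np.stack([
        nid[I, J, K], nid[I, J + 1, K], nid[I + 1, J + 1, K], nid[I + 1, J, K],
        nid[I, J, K + 1], nid[I, J + 1, K + 1], nid[I + 1, J + 1, K + 1],
        nid[I + 1, J, K + 1],
    ], axis=1)
    hexes_m = np.stack([
        mirror_id[I, J, K], mirror_id[I, J + 1, K], mirror_id[I + 1, J + 1, K],
        mirror_id[I + 1, J, K], mirror_id[I, J, K + 1], mirror_id[I, J + 1, K + 1],
        mirror_id[I + 1, J + 1, K + 1], mirror_id[I + 1, J, K + 1],
    ], axis=1)

    tets_half = hexes[:, _HEX_TETS].reshape(-1, 4)
    tets_mir = hexes_m[:, _HEX_TETS].reshape(-1, 4)
    tets_mir = tets_mir[:, [0, 1, 3, 2]]          # restore orientation
    tets = np.vstack([tets_half, tets_mir])

    # Per-tet provenance: (i, j, k) of the parent hex, side flag.
    hex_i = np.repeat(I, 6)
    hex_j = np.repeat(J, 6)
    hex_k = np.repeat(K, 6)
    side = np.concatenate([np.ones(len(tets_half)), -np.ones(len(tets_mir))])
    hex_i = np.concatenate([hex_i, hex_i])
    hex_j = np.concatenate([hex_j, hex_j])
    hex_k = np.concatenate([hex_k, hex_k])

    u_mid = (u[hex_i] + u[hex_i + 1]) / 2
    phi_mid = (phi[hex_j] + phi[hex_j + 1]) / 2
    is_bone = (hex_k < _N_BONE_LAYERS) & (u_mid <= _BONE_TIP_FRACTION)
    material = np.where(is_bone, "bone", "keratin")

    vols = tet_volumes(nodes, tets)
    if not (vols > 0).all():
        raise ValueError(
            f"meshing failure: {(vols <= 0).sum()} degenerate elements for "
            f"params={params}, resolution={resolution}")

    # --- named node sets ---------------------------------------------------
    i_of = np.repeat(np.arange(n_ax + 1), (m + 1) * (n_rad + 1))
    j_of = np.tile(np.repeat(np.arange(m + 1), n_rad + 1), n_ax + 1)
    k_of = np.tile(np.arange(n_rad + 1), (n_ax + 1) * (m + 1))
    i_full = np.concatenate([i_of, i_of[keep.reshape(-1)]])
    j_full = np.concatenate([j_of, j_of[keep.reshape(-1)]])
    k_full = np.concatenate([k_of, k_of[keep.reshape(-1)]])

    node_sets: dict[str, np.ndarray] = {}
    # The upper beak contacts the neurocranium only dorsally (the
    # frontal/nasal region); the ventral back rim opens into the mouth.
    # Fixing the whole rim would short-circuit the hinge load path.
    node_sets["back_fixed"] = np.flatnonzero(
        (i_full == 0) & (sphi[j_full] >= 0.25))
    node_sets["outer_surface"] = np.flatnonzero(k_full == n_rad)

    outer = node_sets["outer_surface"]
    xyz = nodes[outer]
    yc_node = -params.curvature * L * (xyz[:, 2] / L) ** 2
    rel_y = xyz[:, 1] - yc_node
    r_patch = 0.02 * L    # bite patch radius: diameter 4% of beak length

    def _patch(anchor: np.ndarray, mask: np.ndarray) -> np.ndarray:
        cand = outer[mask]
        d = np.linalg.norm(nodes[cand] - anchor, axis=1)
        sel = cand[d <= r_patch]
        if len(sel) == 0:
            sel = cand[[np.argmin(d)]]
        return np.sort(sel)

    # Central tip bite: ventral midline patch at the bony-core tip station.
    z_tip = _BONE_TIP_FRACTION * L
    ventral = rel_y < 0
    mid_v = ventral & (np.abs(xyz[:, 0]) < 0.25 * a * _TIP_SCALE + 1e-9)
    anchor_rows = outer[mid_v]
    az = nodes[anchor_rows, 2]
    anchor = nodes[anchor_rows[np.argmin(np.abs(az - z_tip))]]
    node_sets["bite_tip"] = _patch(anchor, ventral)

    # Unilateral base bite: left ventral patch at 1/4 length, near the
    # lateral edge of the bony core.
    z_base = 0.25 * L
    phi_target = -np.pi / 9     # 20 degrees below the lateral edge
    sb = 1.0 - (1.0 - _TIP_SCALE) * 0.25 ** params.taper_exponent
    ax_b = -a * sb * np.abs(np.cos(phi_target)) ** (2 / p)   # left: x < 0
    ay_b = (-params.curvature * L * 0.25 ** 2
            - b_v * sb * np.abs(np.sin(phi_target)) ** (2 / p))
    anchor_b = np.array([ax_b, ay_b, z_base])
    left_ventral = ventral & (xyz[:, 0] < -1e-12)
    node_sets["bite_base_unilateral"] = _patch(anchor_b, left_ventral)

    # Jugal / palatine attachments on the bony core at the beak base,
    # distal to the nasal hinge so muscle moments load the hinge.
    inner = k_full <= _N_BONE_LAYERS
    zf = nodes[:, 2] / L
    att_band = inner & (zf >= 0.10) & (zf <= 0.18)
    # Lateral (tomial-edge) columns for the jugal, ventral columns for
    # the palatine; selection by grid column is robust to how far the
    # bony core reaches ventrally for thick-keratin shapes.
    lateral_col = np.abs(j_full - m / 2) <= max(1, m // 6)
    ventral_col = j_full <= max(1, m // 6)
    node_sets["jugal_attach_left"] = np.flatnonzero(
        att_band & lateral_col & (nodes[:, 0] < -1e-12))
    node_sets["jugal_attach_right"] = np.flatnonzero(
        att_band & lateral_col & (nodes[:, 0] > 1e-12))
    node_sets["palatine_attach"] = np.flatnonzero(att_band & ventral_col)

    # --- named element regions (bone recording sites + hinge) -------------
    bone = is_bone
    dorsal = np.sin(phi_mid) > 0.5
    left = side < 0
    lateral_e = np.abs(np.sin(phi_mid)) < 0.5

    def _region(mask: np.ndarray, name: str) -> None:
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(
                f"empty element region {name!r}: resolution too coarse")
        regions[name] = idx

    regions: dict[str, np.ndarray] = {}
    _region(bone & dorsal & (u_mid >= 0.18) & (u_mid <= 0.33), "region_bite_base")
    _region(bone & dorsal & (u_mid >= 0.70) & (u_mid <= _BONE_TIP_FRACTION),
            "region_bite_tip")
    _region(bone & dorsal & (u_mid >= 0.02) & (u_mid <= 0.14), "region_nasal_hinge")
    _region(bone & lateral_e & (u_mid >= 0.05) & (u_mid <= 0.20) & left,
            "region_nasal_left")
    _region(bone & lateral_e & (u_mid >= 0.05) & (u_mid <= 0.20) & ~left,
            "region_nasal_right")
    _region(bone & dorsal
            & (np.abs(u_mid - _HINGE_CENTER) <= 1.5 * _HINGE_SIGMA),
            "bending_area")

    mesh = TetMesh(
        nodes=nodes, tets=tets.astype(np.int64), material=material,
        node_sets=node_sets, element_regions=regions,
        metadata=dict(
            length=L, group=params.group, params=params,
            resolution=resolution, seed=seed, n_ax=n_ax, m=m,
            bone_tip_fraction=_BONE_TIP_FRACTION,
            axis="z", up="y", bite_side="left",
        ))
    mesh.validate()
    return mesh


# --- measurement ----------------------------------------------------------

def boundary_faces(mesh: TetMesh) -> np.ndarray:
    """Triangular faces that belong to exactly one tetrahedron.

    Returned with outward orientation (node order as stored on the tet).
    """
    t = mesh.tets
    # Faces opposite each vertex, oriented outward for positive tets.
    faces = np.vstack([
        t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]],
    ])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def surface_area(mesh: TetMesh) -> float:
    """Area of the outer boundary surface, in mm^2.

    If the mesh carries an ``outer_surface`` node set (generated beaks
    do), only boundary triangles lying entirely on it are counted — the
    external keratin surface, excluding the cavity wall and the cut ends.
    Otherwise all boundary triangles count.
    """
    faces = boundary_faces(mesh)
    if len(faces) == 0:
        raise ValueError("mesh has no boundary")
    if "outer_surface" in mesh.node_sets:
        on = np.zeros(mesh.n_nodes, dtype=bool)
        on[mesh.node_sets["outer_surface"]] = True
        faces = faces[on[faces].all(axis=1)]
    p = mesh.nodes[faces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return float(np.linalg.norm(cross, axis=1).sum() / 2)


def mesh_quality(mesh: TetMesh, aspect_threshold: float = 25.0) -> dict:
    """Element-quality report.

    Aspect ratio metric: circumradius / (3 * inradius), which equals 1
    for a regular tetrahedron and grows without bound for slivers.
    """
    vols = tet_volumes(mesh.nodes, mesh.tets)
    x = mesh.nodes[mesh.tets]
    # Total face area per tet.
    pairs = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    area = np.zeros(len(x))
    for i, j, k in pairs:
        c = np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i])
        area += np.linalg.norm(c, axis=1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = 3 * np.abs(vols) / area
        # circumradius via the Cayley-Menger-free formula
        a1 = x[:, 1] - x[:, 0]
        a2 = x[:, 2] - x[:, 0]
        a3 = x[:, 3] - x[:, 0]
        sq = np.stack([(a1 ** 2).sum(1), (a2 ** 2).sum(1), (a3 ** 2).sum(1)], axis=1)
        M = np.stack([a1, a2, a3], axis=1)
        circ = np.linalg.solve(M, (sq / 2)[..., None])[..., 0]
        r_circ = np.linalg.norm(circ, axis=1)
        aspect = r_circ / (3 * r_in)
    return dict(
        min_signed_volume=float(vols.min()),
        inverted_count=int((vols <= 0).sum()),
        max_aspect_ratio=float(np.nanmax(aspect)),
        n_above_threshold=int(np.nansum(aspect > aspect_threshold)),
        aspect_threshold=aspect_threshold,
    )


def measure_shape(mesh: TetMesh, n_samples: int = 4000) -> dict:
    """Measure shape ratios from the mesh itself by vertical/lateral probing.

    A dense line of sample points is classified (outside / bone / keratin)
    by point-in-tet location near the beak base, independently of the
    construction formulas, yielding depth, width and keratin thicknesses.
    """
    L = mesh.metadata["length"]
    curvature = mesh.metadata["params"].curvature
    z0 = 0.01 * L
    eps = 1e-6 * L
    yc = -curvature * L * (z0 / L) ** 2

    # Restrict to tets near the probed station for speed.
    zmid = mesh.nodes[mesh.tets][:, :, 2].mean(axis=1)
    near = np.abs(zmid - z0) < 3 * L / mesh.metadata["n_ax"]
    cand = np.flatnonzero(near)

    def classify(points: np.ndarray) -> np.ndarray:
        lab = np.full(len(points), "", dtype=object)
        x = mesh.nodes[mesh.tets[cand]]
        v0 = x[:, 0]
        T = np.stack([x[:, 1] - v0, x[:, 2] - v0, x[:, 3] - v0], axis=2)
        Tinv = np.linalg.inv(T)
        for qi, q in enumerate(points):
            lam = Tinv @ (q - v0)[..., None]
            lam = lam[..., 0]
            inside = (lam >= -1e-9).all(axis=1) & (lam.sum(axis=1) <= 1 + 1e-9)
            hit = np.flatnonzero(inside)
            if len(hit):
                lab[qi] = mesh.material[cand[hit[0]]]
        return lab

    span = 0.6 * L
    ys = np.linspace(yc - span / 2, yc + span / 2, n_samples)
    vert = np.column_stack([np.full(n_samples, eps), ys,
                            np.full(n_samples, z0)])
    lab_v = classify(vert)
    solid = np.flatnonzero(lab_v != "")
    if len(solid) == 0:
        raise ValueError("probe line missed the mesh")
    depth = ys[solid[-1]] - ys[solid[0]]
    dy = ys[1] - ys[0]
    # keratin thickness = contiguous keratin run inward from each surface
    run = 0
    for lb in lab_v[solid[0]:]:
        if lb == "keratin":
            run += 1
        else:
            break
    ker_bottom = run * dy
    run = 0
    for lb in lab_v[solid[-1]::-1]:
        if lb == "keratin":
            run += 1
        else:
            break
    ker_top = run * dy

    xs = np.linspace(-0.6 * L, 0.6 * L, n_samples)
    horiz = np.column_stack([xs, np.full(n_samples, yc + eps),
                             np.full(n_samples, z0)])
    lab_h = classify(horiz)
    solid_h = np.flatnonzero(lab_h != "")
    width = xs[solid_h[-1]] - xs[solid_h[0]]

    return dict(
        depth_ratio=depth / L, width_ratio=width / L,
        ker_bottom_ratio=ker_bottom / L, ker_top_ratio=ker_top / L,
    )
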