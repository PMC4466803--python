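"""Post-processing into the reported quantities.

Regional 98th-percentile von Mises stresses at the three recording
sites (vM1: on top of the bone near the bite position; vM2: on top of
the nasal hinge; vM3: nasal bone — ipsilateral side only under base
biting, both sides under tip biting), model bite force, bone strength
from the linear strength-modulus relation, and the engineering safety
factor strength / peak stress.

Keratin stresses are never pooled: the failure-relevant material is the
bony core, so percentile pools are restricted to bone elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beak_geometry import TetMesh, tet_volumes
from .fe_core import SolutionField, reaction_force
from .load_cases import locate_bite_nodes

__all__ = [
    "StressSummary", "region_peak_vm", "summarize", "bone_strength",
    "safety_factor", "round_half_up", "normalize_gray",
    "STRENGTH_COEFFICIENT",
]

# Linear bone strength-modulus relation: strength = 0.0061 * E.
STRENGTH_COEFFICIENT = 0.0061


@dataclass
class StressSummary:
    """One row of the stress/safety report (one model, one load case)."""
    model: str
    scenario: str
    bite_mode: str
    vM1: float           # MPa, near the bite position
    vM2: float           # MPa, on top of the nasal hinge
    vM3: float           # MPa, nasal bone
    peak_vm: float       # MPa, max of the three recording sites
    bite_force: float    # N
    strength: float      # MPa
    safety_factor: float
    safety_factor_rounded: float
    V_bone: float        # mm^3
    V_ker: float         # mm^3


def region_peak_vm(solution: SolutionField, region: np.ndarray,
                   material: np.ndarray | None = None,
                   pct: float = 0.98) -> float:
    """Percentile of element von Mises values over a recording region.

    Convention: linear interpolation at rank 1 + pct*(n-1) over the
    sorted values (numpy's ``linear`` percentile).  ``pct = 1`` gives
    the true maximum.  If ``material`` is passed, keratin elements are
    excluded from the pool.
    """
    region = np.asarray(region)
    if len(region) == 0:
        raise ValueError("empty recording region")
    if material is not None:
        region = region[material[region] == "bone"]
        if len(region) == 0:
            raise ValueError("recording region contains no bone elements")
    if not 0 <= pct <= 1:
        raise ValueError("pct must be in [0, 1]")
    return float(np.percentile(solution.von_mises[region], 100 * pct,
                               method="linear"))


def summarize(solution: SolutionField, mesh: TetMesh, scenario: str,
              bite_mode: str, model: str = "", pct: float = 0.98,
              E_bone: float | None = None,
              strength_coefficient: float = STRENGTH_COEFFICIENT,
              bite_side: str | None = None) -> StressSummary:
    """Reduce one solve to the reported stress/safety row.

    Under base biting the nasal recording uses the ipsilateral side only
    (the bird could unload the contralateral side by easing off that
    side of the bite, so its stress is not meaningful); under tip biting
    both nasal regions pool together.
    """
    regions = mesh.element_regions
    needed = {"region_bite_tip", "region_bite_base", "region_nasal_hinge",
              "region_nasal_left", "region_nasal_right"}
    missing = needed - set(regions)
    if missing:
        raise ValueError(f"mesh lacks recording regions {sorted(missing)}")

    mat = mesh.material
    bite_region = regions["region_bite_tip" if bite_mode == "tip"
                          else "region_bite_base"]
    vM1 = region_peak_vm(solution, bite_region, mat, pct)
    vM2 = region_peak_vm(solution, regions["region_nasal_hinge"], mat, pct)
    if bite_mode == "tip":
        nasal = np.concatenate([regions["region_nasal_left"],
                                regions["region_nasal_right"]])
    else:
        side = bite_side or mesh.metadata.get("bite_side", "left")
        nasal = regions[f"region_nasal_{side}"]
    vM3 = region_peak_vm(solution, nasal, mat, pct)

    _, F = reaction_force(solution, locate_bite_nodes(mesh, bite_mode))

    vols = tet_volumes(mesh.nodes, mesh.tets)
    V_bone = float(vols[mat == "bone"].sum())
    V_ker = float(vols[mat == "keratin"].sum())

    if E_bone is None:
        E_bone = 7300.0
    strength = bone_strength(E_bone, strength_coefficient)
    peak = max(vM1, vM2, vM3)
    sf = safety_factor(strength, peak)
    return StressSummary(
        model=model or mesh.metadata.get("group", ""),
        scenario=scenario, bite_mode=bite_mode,
        vM1=vM1, vM2=vM2, vM3=vM3, peak_vm=peak, bite_force=F,
        strength=strength, safety_factor=sf,
        safety_factor_rounded=round_half_up(sf, 1),
        V_bone=V_bone, V_ker=V_ker)


def bone_strength(E: float, k: float = STRENGTH_COEFFICIENT) -> float:
    """Bone strength in MPa from Young's modulus (MPa): strength = k * E.

    Stored unrounded; the conventional reported figure rounds to two
    significant digits (E = 7300 MPa -> 44.53 MPa, reported 45 MPa).
    """
    if E < 0:
        raise ValueError("modulus must be >= 0")
    return k * E


def safety_factor(strength: float, peak_vm: float) -> float:
    """Engineering safety factor strength / peak operating stress."""
    if peak_vm <= 0:
        raise ValueError("peak stress must be > 0")
    return strength / peak_vm


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.75 -> 0.8)."""
    f = 10.0 ** decimals
    return float(np.floor(np.abs(x) * f + 0.5) / f * np.sign(x))


def normalize_gray(values) -> np.ndarray:
    """Min-max normalise intensity values to [0, 1].

    Uncalibrated CT gray values carry only ordinal density information;
    0 maps to the least dense sample, 1 to the densest.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need >= 2 distinct values to define the scale")
    return (v - v.min()) / np.ptp(v)
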