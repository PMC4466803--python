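"""Scenario construction: physiological vs size-scaled, tip vs base biting.

Physiological cases apply a species' own muscle-derived loads to its
own-size beak.  Size-scaled cases first rescale the beak so its outer
surface area equals a reference (the medium ground finch G. fortis in
the reference analysis) and then apply the reference loads, eliminating
size so that only shape differences remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beak_geometry import TetMesh, surface_area
from .fe_core import LoadCase
from .musculature import BeakLoads

__all__ = ["ScenarioSpec", "locate_bite_nodes", "scale_to_reference",
           "build_case"]

# Reference jugal/palatine input forces (N) of the G. fortis model, used
# by every size-scaled scenario.
REFERENCE_LOADS_N = (11.9, 10.9)


@dataclass
class ScenarioSpec:
    scenario: str                    # "physiological" | "scaled"
    bite_mode: str                   # "tip" | "base"
    reference_area: float | None = None      # mm^2, scaled only
    reference_loads: BeakLoads | None = None  # scaled only

    def __post_init__(self) -> None:
        if self.scenario not in ("physiological", "scaled"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.bite_mode not in ("tip", "base"):
            raise ValueError(f"unknown bite mode {self.bite_mode!r}")


def locate_bite_nodes(mesh: TetMesh, mode: str) -> np.ndarray:
    """Bite constraint nodes for a bite mode.

    Tip biting is central, at the axial station of the bony-core tip
    (birds do not bite at the very keratin tip); base biting is a
    unilateral patch at one quarter of the rhamphotheca length, near the
    lateral edge of the bony core, on the generator's configured side.
    Stations are measured as straight axial fractions of total length.
    """
    key = {"tip": "bite_tip", "base": "bite_base_unilateral"}.get(mode)
    if key is None:
        raise ValueError(f"unknown bite mode {mode!r}")
    nodes = mesh.node_sets.get(key)
    if nodes is None or len(nodes) == 0:
        raise ValueError(f"mesh lacks bite node set {key!r} "
                         "(resolution too coarse?)")
    return nodes


def scale_to_reference(mesh: TetMesh, reference_area: float
                       ) -> tuple[TetMesh, float]:
    """Uniformly scale a mesh so its outer surface area hits a reference.

    Returns the scaled copy and the linear scale factor
    s = sqrt(reference_area / current_area).
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    area = surface_area(mesh)
    if area <= 0:
        raise ValueError("degenerate mesh surface area")
    s = float(np.sqrt(reference_area / area))
    scaled = mesh.copy()
    scaled.nodes *= s
    scaled.metadata["length"] = s * mesh.metadata.get("length", np.nan)
    scaled.metadata["scale_factor"] = s
    return scaled, s


def build_case(mesh: TetMesh, spec: ScenarioSpec,
               species_loads: BeakLoads | None = None) -> LoadCase:
    """Assemble the LoadCase for a scenario over a (possibly scaled) mesh.

    Physiological scenarios require ``species_loads``; scaled scenarios
    use ``spec.reference_loads``.  The jugal force is split equally
    between the left and right attachment patches; the back rim is
    always fully constrained.
    """
    if spec.scenario == "scaled":
        if spec.reference_loads is None:
            raise ValueError("scaled scenario requires reference_loads")
        loads = spec.reference_loads
    else:
        if species_loads is None:
            raise ValueError("physiological scenario requires species_loads")
        loads = species_loads

    bite = locate_bite_nodes(mesh, spec.bite_mode)
    fixed = mesh.node_sets["back_fixed"]
    half_jugal = np.asarray(loads.F_jugal, dtype=float) / 2.0
    point_loads = [
        ("jugal_left", mesh.node_sets["jugal_attach_left"], half_jugal),
        ("jugal_right", mesh.node_sets["jugal_attach_right"], half_jugal),
        ("palatine", mesh.node_sets["palatine_attach"],
         np.asarray(loads.F_palatine, dtype=float)),
    ]
    return LoadCase(fixed_nodes=fixed, bite_nodes=bite,
                    point_loads=point_loads, bite_mode=spec.bite_mode)
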