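"""Jaw-muscle forces and the two load paths onto the upper beak.

Dissection data (per-bundle mass and fiber length) are converted to
physiological cross-sectional areas (PCSA = mass / (density x fiber
length)) and maximal forces (PCSA x specific tension).  The external
adductor and pseudotemporalis groups act on the upper beak only
indirectly, through the jugal bone; their resultant is projected onto
the jugal axis through one effective angle.  The pterygoid group loads
the upper beak directly through the pterygoid/palatine complex.

The per-bundle 3-D lines of action behind the published jugal/palatine
input forces are not available, so :func:`calibrate_angles` recovers an
effective jugal projection angle and a palatine scale from published
target forces; these are a stand-in, flagged as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MuscleBundle", "SpeciesMuscles", "BeakLoads",
    "pcsa", "bundle_force", "resolve_beak_loads", "calibrate_angles",
    "load_muscle_table", "load_species", "target_forces",
    "MUSCLE_DENSITY", "SPECIFIC_TENSION",
]

MUSCLE_DENSITY = 1036.0      # kg/m^3
SPECIFIC_TENSION = 30.0      # N/cm^2

PATHWAYS = ("indirect_jugal", "direct_palatine", "none")

# Default load directions in the mesh frame (z base->tip, +y dorsal).
# The jugal pulls the upper beak ventrally during jaw closing; the
# pterygoid/palatine complex pulls caudoventrally on the palate.
DEFAULT_JUGAL_DIR = np.array([0.0, -1.0, 0.0])
DEFAULT_PALATINE_DIR = np.array([0.0, -1.0, -2.0]) / np.sqrt(5.0)


@dataclass(frozen=True)
class MuscleBundle:
    name: str
    mass: float              # g
    fiber_length: float      # mm
    pathway: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be > 0")
        if self.fiber_length <= 0:
            raise ValueError(f"{self.name}: fiber length must be > 0")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"{self.name}: unknown pathway {self.pathway!r}")


@dataclass
class SpeciesMuscles:
    species: str
    bundles: list[MuscleBundle]
    density: float = MUSCLE_DENSITY          # kg/m^3
    specific_tension: float = SPECIFIC_TENSION   # N/cm^2

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_tension <= 0:
            raise ValueError("density and specific_tension must be > 0")
        names = [b.name for b in self.bundles]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.species}: duplicate bundle names")

    def pathway_force(self, pathway: str) -> float:
        """Summed maximal force (N) over bundles of one pathway."""
        return float(sum(
            bundle_force(b, self.density, self.specific_tension)
            for b in self.bundles if b.pathway == pathway))


@dataclass
class BeakLoads:
    """Resolved load vectors applied to the upper beak (N)."""
    F_jugal: np.ndarray          # total, split equally left/right
    F_palatine: np.ndarray
    jugal_angle: float           # degrees
    palatine_direction: np.ndarray


def pcsa(bundle: MuscleBundle, density: float = MUSCLE_DENSITY) -> float:
    """Physiological cross-sectional area in cm^2.

    mass / (density x fiber length), with mass in g, fiber length in mm
    and density in kg/m^3.  Pennate muscles are assumed already split
    into bundles, so no pennation-angle correction is applied.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    # (g -> kg) / (kg/m^3 * mm -> m) = m^2; -> cm^2
    return (bundle.mass / 1000.0) / (density * bundle.fiber_length / 1000.0) * 1e4


def bundle_force(bundle: MuscleBundle, density: float = MUSCLE_DENSITY,
                 specific_tension: float = SPECIFIC_TENSION) -> float:
    """Maximal isometric force of one bundle, N (= tension x PCSA)."""
    if specific_tension < 0:
        raise ValueError("specific_tension must be >= 0")
    return specific_tension * pcsa(bundle, density)


def resolve_beak_loads(muscles: SpeciesMuscles, jugal_angle: float,
                       jugal_dir: np.ndarray = DEFAULT_JUGAL_DIR,
                       palatine_dir: np.ndarray = DEFAULT_PALATINE_DIR,
                       palatine_scale: float = 1.0) -> BeakLoads:
    """Resolve bundle forces into the jugal and palatine load vectors.

    |F_jugal| = cos(jugal_angle) x (sum of indirect-pathway forces);
    |F_palatine| = palatine_scale x (sum of direct-pathway forces).
    The jaw opener (MDM) and any bundle with pathway ``none`` never
    contribute.
    """
    if not 0 <= jugal_angle <= 90:
        raise ValueError("jugal_angle must be in [0, 90] degrees")
    jugal_dir = np.asarray(jugal_dir, dtype=float)
    palatine_dir = np.asarray(palatine_dir, dtype=float)
    for name, d in (("jugal_dir", jugal_dir), ("palatine_dir", palatine_dir)):
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"{name} must be unit-norm (|d| = {n:.6f})")
    if not any(b.pathway == "indirect_jugal" for b in muscles.bundles):
        raise ValueError(f"{muscles.species}: no indirect_jugal bundles")
    if not any(b.pathway == "direct_palatine" for b in muscles.bundles):
        raise ValueError(f"{muscles.species}: no direct_palatine bundles")
    Fj = np.cos(np.deg2rad(jugal_angle)) * muscles.pathway_force("indirect_jugal")
    Fp = palatine_scale * muscles.pathway_force("direct_palatine")
    return BeakLoads(
        F_jugal=Fj * jugal_dir, F_palatine=Fp * palatine_dir,
        jugal_angle=jugal_angle, palatine_direction=palatine_dir)


def calibrate_angles(muscles: SpeciesMuscles, target_Fj: float,
                     target_Fp: float) -> dict:
    """Effective jugal angle and palatine scale matching target forces.

    The jugal angle comes from arccos(target / available); targets above
    the available indirect force are an error.  The palatine scale is a
    plain ratio and may exceed 1: for some species the published
    palatine input force is larger than the bare pterygoid PCSA force
    sum (the original resolution used unpublished 3-D muscle geometry).
    """
    if target_Fj < 0 or target_Fp < 0:
        raise ValueError("targets must be >= 0")
    avail_j = muscles.pathway_force("indirect_jugal")
    avail_p = muscles.pathway_force("direct_palatine")
    if target_Fj > avail_j * (1 + 1e-9):
        raise ValueError(
            f"{muscles.species}: jugal target {target_Fj} N exceeds the "
            f"available indirect force {avail_j:.2f} N")
    angle = float(np.rad2deg(np.arccos(min(target_Fj / avail_j, 1.0))))
    return dict(jugal_angle=angle, palatine_scale=target_Fp / avail_p)


# --- packaged dissection table -------------------------------------------

def load_muscle_table() -> pd.DataFrame:
    """The packaged dissection table (species, muscle, mass_g,
    fiber_length_mm, pathway)."""
    with resources.files("finchbeak.data").joinpath("muscles.csv").open() as fh:
        return pd.read_csv(fh)


def load_species(species: str, include_protractor: bool = False,
                 table: pd.DataFrame | None = None) -> SpeciesMuscles:
    """Build a :class:`SpeciesMuscles` from the packaged table.

    ``include_protractor`` reassigns MPPtQ (m. protractor pterygoidei et
    quadrati) to the direct palatine pathway; by default it is excluded
    from closing loads, like the jaw opener MDM.
    """
    df = load_muscle_table() if table is None else table
    rows = df[df["species"] == species]
    if rows.empty:
        raise KeyError(f"no dissection data for species {species!r}")
    bundles = []
    for _, r in rows.iterrows():
        pathway = r["pathway"]
        if include_protractor and r["muscle"] == "MPPtQ":
            pathway = "direct_palatine"
        bundles.append(MuscleBundle(
            name=r["muscle"], mass=float(r["mass_g"]),
            fiber_length=float(r["fiber_length_mm"]), pathway=pathway))
    return SpeciesMuscles(species=species, bundles=bundles)


def target_forces(species: str, stress_table: pd.DataFrame) -> tuple[float, float]:
    """Published (Fj, Fp) input forces for a species' physiological model."""
    rows = stress_table[(stress_table["species"] == species)
                        & (stress_table["lc"] == "PB")]
    if rows.empty:
        raise KeyError(f"no physiological loading row for {species!r}")
    r = rows.iloc[0]
    return float(r["Fj"]), float(r["Fp"])
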