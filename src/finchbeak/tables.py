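"""Accessors for the packaged reference tables.

Three small CSVs ship with the package: the muscle dissection table
(see :mod:`finchbeak.musculature`), the published per-model stress/force
table for the 13 species (physiological and size-scaled load cases),
the group-level shape-ratio summary, and the published safety-factor
reference used for replay cross-checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stress_table", "load_shape_groups", "load_safety_reference",
           "PREDOMINANT_MODE", "BASE_CRUSHERS"]

# Feeding behaviour -> the bite mode a species predominantly uses.
PREDOMINANT_MODE = {
    "base_crush": "base",
    "probe_and_crush": "base",
    "probe": "base",
    "tip_crush": "tip",
}

# Species whose natural strategy is crushing at the beak base.
BASE_CRUSHERS = ["G. fortis", "G. magnirostris", "G. fuliginosa"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("finchbeak.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_stress_table() -> pd.DataFrame:
    """Published stress/force table: one row per model and load case.

    Columns: species, lc (PB/PT = physiological base/tip, FB/FT = scaled
    base/tip), Fj, Fp (input forces, N), vM1-vM3 (MPa), GV1-GV3
    (normalised gray values), F (model bite force, N), V_bone, V_ker
    (mm^3).
    """
    return _read("stress_table.csv")


def load_shape_groups() -> pd.DataFrame:
    """Group-level shape ratios: mean and SD per functional group."""
    return _read("shape_groups.csv")


def load_safety_reference() -> pd.DataFrame:
    """Published per-species model forces and safety factors."""
    return _read("safety_reference.csv")
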