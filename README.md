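# finchbeak

Finite-element analysis of beak loading in Darwin's finches: do beak
shapes resist the forces their owners' feeding styles generate?

Seed-crushing birds must bite hard without fracturing their beaks. The
upper beak is a layered structure — a thin-walled bony core wrapped in a
keratinous sheath (the rhamphotheca) — loaded during biting through two
paths: the jugal bones, which pull the beak ventrally when the jaw
closes, and the pterygoid/palatine complex, which loads the palate
directly. `finchbeak` implements the full modelling chain for comparing
the 13 Darwin's finch species across their four functional beak types
(crush, probe-and-crush, probe, tip-bite):

1. **Muscle loads.** Per-bundle dissection data (mass *m*, fiber length
   *l*) give each jaw muscle's physiological cross-sectional area,
   PCSA = *m* / (ρ *l*) with ρ = 1036 kg/m³, and maximal force
   σ · PCSA with specific tension σ = 30 N/cm². Adductor and
   pseudotemporalis forces project onto the jugal path through an
   effective angle; pterygoid forces act directly on the palatine path.
2. **Geometry.** A parametric generator builds two-material tetrahedral
   beak meshes — superelliptical sections lofted along a curved,
   tapering axis — realising each group's measured shape ratios (depth,
   width, dorsal/ventral keratin thickness, all relative to length),
   with a compliant nasal-hinge zone and named sets for every
   constraint, load patch and stress-recording site.
3. **FE solve.** Small-strain linear elasticity on 4-node tetrahedra
   (E_bone = 7.3 GPa, E_keratin = 1.7 GPa), back of the beak fixed at
   the neurocranium, bite support constrained on the ventral keratin
   surface either centrally near the bony-core tip ("tip biting") or
   unilaterally at one quarter length ("base biting"). The reaction at
   the bite constraint is the model bite force.
4. **Reporting.** 98th-percentile von Mises stresses on the bony core at
   the three recording sites (near the bite, on the nasal hinge, on the
   nasal bone), bone strength from the linear relation
   strength = 0.0061 E (45 MPa at 7.3 GPa), and the engineering safety
   factor SF = strength / peak stress. SF < 1 predicts failure at full
   muscle effort.
5. **Comparative layer.** Size-scaled scenarios (every beak normalised
   to a common surface area and loaded with the reference *G. fortis*
   muscle forces) isolate shape from size; Pearson correlations with
   Bonferroni control relate safety factors to shape ratios.

## Worked example

```python
from finchbeak import (make_shape_params, generate_beak_mesh, solve_static,
                       build_case, ScenarioSpec, summarize, DEFAULT_MATERIALS)
from finchbeak.musculature import (load_species, calibrate_angles,
                                   resolve_beak_loads, target_forces)
from finchbeak.tables import load_stress_table

muscles = load_species("G. fortis")
cal = calibrate_angles(muscles, *target_forces("G. fortis", load_stress_table()))
loads = resolve_beak_loads(muscles, cal["jugal_angle"],
                           palatine_scale=cal["palatine_scale"])

params = make_shape_params("crush", {"length": 13.0})
mesh = generate_beak_mesh(params, resolution=20000, seed=1)
for mode in ("base", "tip"):
    case = build_case(mesh, ScenarioSpec("physiological", mode), loads)
    sol = solve_static(mesh, DEFAULT_MATERIALS, case)
    s = summarize(sol, mesh, "physiological", mode)
    print(mode, f"F={s.bite_force:.1f} N",
          f"vM1={s.vM1:.1f} vM2={s.vM2:.1f} vM3={s.vM3:.1f} MPa",
          f"SF={s.safety_factor:.2f}")
```

prints

```
base F=9.2 N vM1=13.4 vM2=30.2 vM3=16.4 MPa SF=1.48
tip F=2.5 N vM1=16.9 vM2=37.8 vM3=34.8 MPa SF=1.18
```

Read: with the calibrated *G. fortis* muscle forces (11.9 N jugal,
10.9 N palatine), the synthetic crushing beak transmits 9.2 N to a seed
held at the beak base but only 2.5 N at the tip (the out-lever effect);
peak bone stress sits on the nasal hinge; and the safety factor is
comfortable for base biting (1.48) but thinner for tip biting (1.18) —
the crusher's beak is tuned to its habitual bite point.

The same pipeline is scriptable from the shell:

```
finchbeak generate-beak --group crush --length 13 --resolution 20000 --seed 1 -o beak.vtu
finchbeak muscle-loads --species "G. fortis" --calibrate-to 11.9 10.9
finchbeak run --seed 0 --resolution 4000 -o run_out
```

`finchbeak run` executes the whole synthetic cohort (13 species sampled
around their group shape ratios, size-scaled scenario, both bite modes)
and writes the stress, safety, group-summary and correlation tables.

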