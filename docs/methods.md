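# Methods

## Model overview

The package models the upper beak as a two-material linear-elastic
structure in a consistent N–mm–MPa unit system. Load transfer follows
the cranial anatomy of finches: jaw-closing muscle force reaches the
upper beak (a) indirectly, via the jugal bones pulling the beak
ventrally, and (b) directly, via the pterygoid/palatine complex. The
beak flexes against the braincase at the nasal hinge, a zone of thin
dorsal bone. Biting is modelled as a fully constrained contact patch on
the ventral keratin surface; the reaction force there is the model bite
force.

All stresses reported for comparison are taken on the bony core only.
Keratin carries load in the model (its presence substantially changes
bone stresses) but is excluded from stress reporting: keratin is a
tough, continuously renewed tissue whose local failure is not
structural, whereas bone fracture is.

## Muscle forces

PCSA = mass / (density × fiber length) with density 1036 kg/m³;
bundle force = 30 N/cm² × PCSA. Pennate muscles are treated as already
split into bundles, so no pennation correction is applied. Bundles are
partitioned by pathway: the external adductor and pseudotemporalis
groups are indirect (jugal), the pterygoid groups and the retractor
palatini direct (palatine). The jaw opener (MDM) never contributes to
closing loads; the protractor (MPPtQ) is excluded by default but can be
opted in, since its role during forceful closing is ambiguous.

The per-bundle 3-D lines of action used in the original dissections are
not published. The module therefore exposes a single effective jugal
projection angle plus a palatine scale, calibrated per species so the
resolved loads reproduce the published jugal/palatine input forces
(e.g. 11.9 N and 10.9 N for *G. fortis*; the calibrated angle is 58.5°).
The calibration round-trips to better than 0.5 % for all eight dissected
species. For three small species the published palatine force slightly
exceeds the bare pterygoid PCSA sum, so the palatine scale may exceed 1;
it is a linear scale, not a projection cosine, and is reported in
outputs so the stand-in is visible.

Default load directions in the mesh frame (z from base to tip, +y
dorsal): the jugal pulls straight ventrally, (0, −1, 0), applied
half-and-half to the left and right attachment patches; the palatine
pulls caudoventrally, (0, −1, −2)/√5. Both are configurable.

## Synthetic geometry

The generator idealises a beak as a superelliptical cross-section
(exponent 2.5) lofted along a curved axis with power-law taper. Inputs
are the group-level shape ratios — depth/length, width/length, and
dorsal/ventral keratin thickness over length — plus a bone-wall ratio
(default 0.02, the source geometry gives no wall thickness), curvature
(tip drop/length) and taper exponent. Structured hex grids (axial ×
half-ring × 4 radial layers: 2 bone, 2 keratin) are split into six
tetrahedra per hex with a face-compatible pattern; the left half is an
exact mirror of the right, so the mesh is bitwise bilaterally symmetric
and fully deterministic (optional seeded node jitter exists but is off
by default).

Construction details that matter mechanically:

- **Ventral room.** The ventral semi-depth is enlarged beyond half the
  total depth when the requested ventral keratin plus bone wall would
  not fit, keeping a small internal cavity; dorsal depth shrinks
  correspondingly. Requested ratios are preserved at the base, where
  the fidelity check measures them (within 5 %, verified by an
  independent point-classification probe through the mesh).
- **Tip closure.** Layer thicknesses taper partially with the outer
  profile and are clamped against inversion, so the tip section
  degenerates gracefully into nearly solid keratin around a sliver of
  bone — thin elements with high aspect ratio but positive volume.
- **Nasal hinge.** A Gaussian band of reduced dorsal bone-wall
  thickness (centre 6.5 % of length, half-width 3 %, factor 0.45)
  realises the bending zone; smooth fields keep refinement behaviour
  regular.
- **Back support.** Only the dorsal sector of the back rim is tagged
  `back_fixed`: the upper beak meets the neurocranium at the
  frontal/nasal region, while the ventral rim opens into the mouth.
  Fixing the whole rim would let muscle loads bypass the hinge into the
  support, collapsing bite forces and destroying the tip-versus-base
  stress contrast the analysis is about.
- **Named sets.** Bite patches (diameter capped at 4 % of length) sit
  on the ventral keratin surface: central at the bony-core tip station
  (90 % of length) for tip biting, unilateral (left by convention) at
  25 % of length near the lateral edge for base biting. Axial stations
  are counted as straight-line fractions of length. Attachment patches
  for jugal (lateral) and palatine (ventral) sit on the bony core at
  10–18 % of length, distal to the hinge.

Stress-recording regions are parametric axial bands of dorsal or
lateral bone elements (near-bite band per bite mode, hinge band, left
and right nasal bands); the exact spatial extents of the original
recording sites are unknown, so the defaults are documented here rather
than fitted. Under base biting the contralateral nasal band is excluded
from reporting — a bird could unload the far side by easing that side
of the bite — and under tip biting both sides pool.

## FE solver

Constant-strain 4-node tetrahedra, isotropic materials per label.
Poisson ratios are not part of the measured data; defaults are 0.30
(cortical bone) and 0.40 (β-keratin), exposed in the run config.
Constraints fix all translations of every node in a patch (a multi-node
patch also suppresses rotation, matching a fully clamped support).
Loads distribute each patch total equally over its nodes — statically
equivalent to a rigid attachment, and the recording regions are far
from the attachments. The system is solved by direct sparse
factorisation on the free DOFs with a 1e-8 relative-residual contract;
stresses are element-centroid values with no nodal averaging before
percentile extraction.

Verification included in the suite: exact patch test, element oracle
against an independently hand-assembled stiffness, dense-solve
equivalence at ≤ 200 DOF (1e-10), slender-cantilever deflection within
10 % of Euler–Bernoulli at 60×6×6 resolution (monotonically improving),
global equilibrium to 1e-8 on every solve, frame invariance of von
Mises stress under rigid rotation (1e-8), and the 1/s² stress scaling
law under uniform geometric scaling that underpins the size-scaled
scenario.

## Post-processing conventions

- 98th-percentile regional stress, linear-interpolation rank
  1 + p(n−1) over sorted element values (the percentile convention is
  not stated in the source; this one is fixed and documented).
  Percentile pools are volume-unweighted by default and never contain
  keratin elements.
- Bone strength = 0.0061 × E; stored unrounded (44.53 MPa at
  E = 7300 MPa), conventionally reported as 45 MPa (two significant
  figures).
- Safety factor = strength / peak recorded stress, rounded half-up to
  one decimal for reporting; full precision is kept internally.
- Replaying the packaged published stress table through this chain
  reproduces 14 of the 16 published physiological safety factors
  exactly; the two exceptions (one tip, one base case) differ by 0.1
  because the published stress columns are themselves rounded to whole
  MPa while the published SFs were evidently computed from unrounded
  stresses (the published tables also disagree internally by one last
  digit on a bite force). The replay is kept faithful rather than
  fitted.
- Gray-value handling is retained only as min–max normalisation to
  [0, 1]; uncalibrated CT intensities carry ordinal density information
  only, and no density-to-modulus mapping is applied.

## Synthetic cohort and comparative statistics

The cohort assigns each of the 13 species its functional group's shape
ratios plus within-group variation drawn from the group SDs. The four
ratios share a latent "robustness" factor (70 % of variance): beak
dimensions covary strongly along a robust–gracile axis, and fully
independent draws would produce deep-but-narrow or thick-walled-but-
shallow morphologies outside the natural shape space that the
comparative claim is about. Nominal lengths (12–16 mm by group, probers
longest) and curvatures (0.08–0.16, tip-biters most decurved) are
configuration inputs, not reproductions — absolute lengths are not
published — and the size-scaled scenario removes them anyway by
normalising every mesh to the reference (*G. fortis*) outer surface
area, taken as the keratin surface, before applying the reference
loads.

Group summaries use sample SDs (n−1); a singleton group reports an
undefined SD. Pearson correlations use the exact t reference
distribution on n−2 degrees of freedom (n ≤ 13 here, no asymptotics),
with Bonferroni control at m = 4 per bite mode, matching the published
table's note (the note says 0.05/4 although eight tests appear across
the two rows; the note is followed).

## Problem sizes and determinism

Default cohort runs use ~4000-element meshes (the suite uses 3500), the
convergence study the ladder 8k/16k/32k/64k elements, where the final
doubling changes the peak regional stress and bite force by under 2 %
against the 5 % criterion. All randomness flows through one integer
seed; meshes are deterministic for fixed (parameters, resolution, seed)
and identical configurations produce byte-identical output tables.

## Known limitations

- Geometry is a parametric idealisation, not CT anatomy: absolute
  stress and bite-force magnitudes from synthetic beaks are not
  comparable to the published per-specimen values (synthetic bite
  forces run ~3× lower than the published models for the same muscle
  loads); only printed-table arithmetic and qualitative orderings are.
- Isotropic, homogeneous materials: keratin anisotropy, hydration
  dependence, and density-dependent bone moduli are out of scope.
- No contact mechanics at the seed, no bilateral bite-force tuning, no
  lower jaw: the bite is a bonded constraint patch.
- The open tip annulus and the effective (calibrated) muscle angles are
  stand-ins flagged in outputs.
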