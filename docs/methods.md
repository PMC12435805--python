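# Methods

This note records the models, conventions and design choices behind
`digembody`, in the order the pipeline uses them.

## Coordinate handling

Structures are read and written through gemmi (PDB and mmCIF, author
numbering). Conventions fixed at the package level:

* **Alternate locations** are resolved at read time: the highest-occupancy
  conformer wins, the first-listed on ties. Deterministic and conventional.
* **Multi-model files**: only model 1 is used (a notice is logged). Motion
  series are supplied as one file per frame.
* **Hydrogens** are kept on read but excluded from every mass and distance
  default — centers of mass, clash counting, minimum distances — matching
  how deposited cryo-EM models (usually hydrogen-free) are analyzed.
  Element H/D/T marks a hydrogen.
* Coordinates are Å throughout; PDB round trips are exact to the format's
  3 decimals, mmCIF round trips to the printed precision.

## IMGT annotation by reference alignment

Nanobody numbering is transferred from an embedded, IMGT-pre-numbered VHH
consensus framework (`data/vhh_reference.tsv`, 118 residues, CDR spans
27–38 / 56–65 / 105–117) through a global BLOSUM62 alignment (affine gaps,
open −10 / extend −1, free terminal overhangs). Framework regions of VHH
domains are conserved enough (~80%+ identity, ~1 Å backbone RMSD across
nanobodies) that the framework mapping is insensitive to the scoring
details; the gap parameters are configurable regardless. A query whose
framework identity falls below 0.5 is rejected as not a nanobody.

Residues inserted relative to the reference inside a CDR receive insertion
codes appended to the preceding numbered position (111A-style). This is an
approximation of the official IMGT insertion rules, which place CDR3
insertions symmetrically around 111/112; framework positions — the only
positions the design scheme and the geometry depend on — are exact, and
CDR-internal numbering is documented as approximate. The reference itself
is a synthetic consensus: its framework carries the canonical identities
at the interface-critical positions (S7, L12, Q14, Q44, P46, G47, K84,
Q120, Q123, T125, plus C23/C104 and W41/W118), its CDRs are placeholders
of typical length.

Substitution sets are shipped as data (`core`, `Gb5-006`, `GbD12`,
`GbS2A4`, `GbH12`, `GbRBD3`, `GbC4`, `Gb113`). Instantiating a set against
a query omits positions that already carry the replacement (making design
idempotent) and flags, but still substitutes, positions whose residue
matches neither the expected wild type nor the replacement. Conservation
checking is advisory-only: deviations at 120/123 warn about a possible
interface shift; serine at 12 (a ~30% natural variant) is only noted.

## Superposition

Rigid placement uses the closed-form Kabsch solution (SVD with determinant
correction, uniform weights). Correspondence is framework Cα atoms at
shared IMGT positions, CDRs excluded — CDR conformations differ between a
target-bound nanobody and a scaffold Gb, so including them would bias the
placement. At least 20 shared positions are required. Near-collinear point
sets (second singular value ≤ 1e−8 of the first) are rejected as
degenerate. An optional iterated fit drops pairs deviating by more than
2 Å (≤ 5 cycles) for locally deformed frameworks; it is off by default
because the plain least-squares fit is the simplest reproducible choice.

## Clash screening

The applicability question — *can this target:nanobody complex dimerize
on this scaffold without steric conflict?* — is answered geometrically.
Copy A of the complex is placed on Gb chain 1, copy B on Gb chain 2.
Conventions:

* **Probes** are target heavy atoms only (the nanobody belongs to the
  scaffold after placement); the **environment** is *all* heavy atoms of
  the other placed copy, target and nanobody alike.
* The 4 Å criterion is **inclusive** at exactly 4.0 Å (determinism needs a
  stated convention); cutoff and threshold are configurable.
* **Normalization**: "maximal clash" is taken as every target heavy atom
  clashing, so score = n_clash / n_total with n_total counted over both
  copies. Per-copy or other normalizers would change nothing for the 0 and
  5% class boundaries on symmetric placements but are not provided.
* Waters, non-polymer heteroatoms and hydrogens are excluded from both
  sides. The nanobody chain is auto-detected as the chain with the highest
  framework identity; explicit chain ids override.

Counting uses a k-d tree (nearest environment neighbor per probe) and is
exactly equivalent to all-pairs counting — the test suite and acceptance
script verify this equivalence on random scenes. Library surveys record
per-entry failures (un-annotatable chains, failed placements) as skipped
entries rather than aborting; fractions are over successful entries, and
the under-5% fraction is cumulative (includes no-clash).

## Interface geometry

The Gb axis vector **D** runs from the heavy-atom center of mass to the
Cα of IMGT 12. Choices:

* **Center-of-mass weighting** defaults to atomic masses over heavy atoms;
  a uniform mode is provided because either convention is defensible. For
  a globular domain the two differ by well under 1° in the derived angles
  (the synthetic fixtures confirm this), so the choice is not load-bearing.
* **D_a is the mean of the unnormalized D_i** — no per-frame normalization
  before averaging; the cosine is clamped to [−1, 1] before arccos.
* Frames are superposed on the **static** Gb (framework Cα) before vector
  extraction, so β measures motion of the mobile Gb relative to the
  interface, not global drift.
* The intra-DiGb angle uses the tip-minus-origin orientation for both
  vectors (center of mass → hinge). The supplement convention (flipping
  one vector) would report 180° minus our value; one convention had to be
  fixed and this one follows the defining construction.
* Angles are reported in degrees to 1 decimal in tabular output.

Contacts: residue pairs across an interface with minimum heavy-atom
distance ≤ 4 Å (configurable). Hydrogen bonds are flagged on a pure
distance criterion — any N/O–N/O pair ≤ 3.5 Å — because deposited cryo-EM
models typically lack hydrogens; no donor/acceptor geometry is applied
unless explicit hydrogens would make it meaningful, and none is
implemented at present.

## Synthetic scenes and what they do (not) show

The generators produce labeled rigid bodies, not physically realistic
immunoglobulin domains:

* `make_toy_gb` — a seeded random Cα walk (3.8 Å steps, 30–90° turns)
  decorated with N/C/O atoms in a chiral local frame, carrying the
  reference sequence and IMGT labels. Rigid, asymmetric, and annotatable
  through the real alignment path at the default 118 residues. Below 95
  residues the framework labels are thinned but the interface-critical
  positions are always retained.
* `assemble_digb` — the second copy is the first, rotated about an axis
  through its hinge Cα perpendicular to its axis vector, then displaced
  along the bisector of the two axis vectors by the requested C12–C12
  distance (4–8 Å, the span a side-chain disulfide allows). The requested
  intra-DiGb angle is exact by construction; closure is verified to 0.1°
  and 0.01 Å at build time.
* `make_wobble_series` — per-frame rotations of the mobile Gb about its
  hinge, with signed deviations drawn in ± pairs that always include
  ±amplitude. The pairing makes the mean direction the rest direction, so
  the planted amplitude equals max β exactly (up to floating-point noise);
  wobble is planar by construction.
* `make_clash_scene` / `make_screen_scene` — planted contact counts with
  ≥ 1 Å margins on the non-clashing side. Screening scenes plant clashes
  in symmetric pairs (even counts) far from both Gb bodies along the hinge
  axis, so the post-placement count equals the planted count exactly; the
  generator verifies this with an independent all-pairs check and refuses
  inter-domain angles outside [40°, 140°], where incidental contacts could
  approach the cutoff.

Passing on these scenes demonstrates that the *measurement chain* —
parsing, annotation, placement, counting, angle extraction — is exact and
self-consistent. It does not demonstrate robustness to the variability of
real structures: conformational differences between bound and free
nanobody frameworks (~1 Å RMSD), non-canonical frameworks, missing
residues, or modeling error in deposited coordinates. Real-data surveys
inherit those error sources through the placement RMSD, which is recorded
per entry for exactly that reason.

All generators are pure functions of (seed, parameters); regenerating is
bit-identical. Randomness uses one numpy Generator per call, no global
state.

## Problem sizes

The test suite and the acceptance script use 118-residue toy domains
(472 atoms), 60-frame series, 100-entry-atom clash scenes, libraries of
10 entries, 100 random oracle scenes of up to 500 atoms per side, and 10⁴
sampled rotations per superposition-optimality instance — sizes at which
every oracle comparison is exact and the whole suite runs in seconds on
one CPU.

## Known limitations

* Deposited-structure surveys require the user to supply the coordinate
  files; no PDB harvesting or curation is built in.
* CDR-internal insertion numbering is approximate (see above).
* Hydrogen-bond detection is distance-only.
* The clash criterion is a fixed-radius sphere, not a van-der-Waals-aware
  energy; that is the method's definition, not an approximation to one.
* The toy generator produces self-intersecting walks occasionally; this is
  irrelevant to the geometric measurements but means the toys are not
  usable as physical decoys.
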