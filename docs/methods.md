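# Methods

This note documents the models behind `goqdna`, the parameter choices that
matter, what the synthetic-data generators do and do not emulate, and the
numerical conventions.

## Units and conventions

Internally everything is nm / ps / kJ·mol⁻¹ (the Gromacs convention).  PDB
files are converted from ångström on read and back on write.  Atom indexing
is 0-based in memory, 1-based in serialized PDB/GRO.  Boxes are rectangular
only; the minimum-image convention is available to distance-based
computations as an opt-in flag and is OFF by default, because
builder-generated and mock coordinates are unwrapped.  GRO carries no chain
field, so chains are re-synthesized on read from residue-number runs (a new
chain starts wherever the residue number fails to increase).

## GOQD flakes

Carbon positions are generated on an ideal honeycomb lattice (C–C
0.142 nm) and kept when x² + y² < R².  A ring count that is a centred
hexagonal number (1, 7, 19, 37, …) maps to a radius lying between the
outermost carbons of the last complete ring shell and the nearest atoms of
the next shell; 7 rings give the 24-carbon disc with 12 edge hydrogens.
Every edge carbon with fewer than three carbon neighbours is capped with an
in-plane H at 0.109 nm.  Functionalization replaces a seeded uniform random
subset of edge hydrogens: OH as C–O 0.143 nm / O–H 0.097 nm, COOH as an
idealized planar sp² carboxyl (C–C 0.152, C=O 0.122, C–O 0.136, O–H
0.097 nm).  No geometry optimization is applied — flakes are flat, and
tests treat bond lengths as exact (C–C within 0.001 nm).

## The B-DNA template

The duplex is generated from a fixed idealized Watson–Crick A:T pair
template (frozen coordinate table in `_bdna_template.py`), propagated with
the canonical B-form rise of 0.338 nm and twist of 36° per step.  The
template was constructed from regular aromatic-ring geometry with the two
canonical hydrogen bonds made exactly linear at the donor:
N6(A)⋯O4(T) = 0.295 nm with H61 on the donor–acceptor line, and
N3(T)⋯N1(A) = 0.282 nm likewise.  Consequences used by the tests:

- the hydrogen-bond detector finds exactly 2 bonds per pair (40 for 20 bp)
  under the default criteria, with no spurious cross-pair bonds;
- thymine O2 faces the minor groove and O4 the major groove, so they serve
  as groove proxies;
- end-to-end length is (n−1)·0.338 nm to well within 2%.

The backbone is a radial proxy (P at 0.92 nm from the axis with OP1/OP2
out of plane, O5′, C1′), adequate for selections, SASA and RDF targets but
not a crystallographic sugar-phosphate geometry.  Chains are antiparallel
by residue numbering: chain A residue *i* pairs with chain B residue
*n*+1−*i*.

## System assembly

The duplex axis is placed along z through the centre of a cubic box
(default 11 nm).  Two flakes sit on the axis beyond the duplex ends,
centroids 8 nm apart by default.  The remaining flakes form an azimuthal
shell, each oriented edge-on (flake plane spanning the axial and radial
directions) and slid radially until its minimum heavy-atom distance to the
DNA equals the surface gap (default 0.2 nm, solved by bisection to
±0.001 nm).  Edge-on orientation was chosen because ten face-on flakes at
a 0.2 nm gap cannot avoid mutual clashes; assembly enforces ≥ 0.3 nm
between flakes and fails loudly otherwise.

## Metrics

**Contacts.** Pairs (i ∈ A, j ∈ B) with r < 0.6 nm, over all atoms
(hydrogens included, since the definition is over "atoms" unqualified).
Implemented with a kd-tree but contractually equal to the all-pairs count;
selections must be disjoint.

**SASA / CSA.** Shrake–Rupley with a 0.14 nm probe and 960 sphere points,
Bondi radii (C 0.170, N 0.155, O 0.152, H 0.120, P 0.180 nm), hydrogens
included.  Only atoms inside the selection occlude.  CSA is exactly the
half-difference of three SASA calls and is clamped at zero (with a
warning) if numerical noise drives it infinitesimally negative.

**Lennard-Jones energy.** Plain truncated 12-6 sum at a 1.2 nm cutoff, no
switching, no electrostatics, Lorentz–Berthelot or geometric combination;
parameters are user-supplied configuration, not hard-coded.  This is an
analysis-grade energy, not a dynamics force field.

**Hydrogen bonds.** Geometric criterion: D⋯A ≤ 0.35 nm and the angle at
the donor between D→H and D→A ≤ 30° (the common `gmx hbond` convention).
Donor hydrogens are resolved within the donor's residue by the covalent
distance (≤ 0.115 nm); a donor with no resolvable H is an error.  The
inter-strand mode requires donor and acceptor on different chains and both
on base (non-backbone) atoms.

**π–π stacking.** Ring centroids closer than 0.4 nm with best-fit-plane
(SVD) normals at < 36°, the angle folded to [0°, 90°] because normals have
sign ambiguity.  Adenine contributes its six- and five-membered rings,
thymine one; ring pairs within the same base are excluded.

**DNA length.** Distance between the base centroids (backbone excluded) of
the first and last base pairs, the pairs taken in chain order of strand 1.

**RMSD.** Optional Kabsch superposition (SVD with determinant correction)
before the root-mean-square deviation.

**RDF and Gibbs energy.** g(r) is the frame-averaged pair-distance
histogram normalized by the ideal-gas shell count N_A·N_B/V·4πr²Δr
(N(N−1)/2 for identical selections).  V is the box volume, or the bounding
sphere of the participating atoms for unboxed synthetic frames — a
documented convention, adequate for peak positions but not for absolute
tails.  The contact-breaking Gibbs energy is dG = k_B·T·ln(g_max/g_∞)
with k_B = 0.0083145 kJ·mol⁻¹·K⁻¹ and T = 310 K by default; g_∞ is the
mean over the last 20% of the r-range rather than 1, because finite
non-periodic systems do not plateau at exactly 1.

**Adsorption sites.** A flake with no DNA atom within the contact cutoff
is unbound.  Otherwise its centroid is projected on the helical axis (a
least-squares line through the base-pair centroids): beyond the first pair
minus a margin of half a rise (0.17 nm) is A (head), beyond the last pair
is D (terminal); positions along the duplex are B in the first half and C
in the second.  B and C are both minor-groove sites; thymine O2 (minor)
and O4 (major) act as groove proxies, and the half-based rule is the tie
rule when the proxy distances do not discriminate.

**Clustering.** Flakes are linked when their minimum heavy-atom distance
is below 0.35 nm — a van der Waals/stacking contact distance, chosen
because the source analyses leave the cluster criterion unstated; it is
exposed as a parameter.  Clusters are connected components; ids are keyed
by the lowest member index for determinism.

## Synthetic trajectories

The generators are kinematic: rigid-body motion on programmed paths, no
forces, no solvent, no thermostat.  They exist to give every metric an
exactly known answer.

- *Approach*: flakes travel straight to docking poses at sites A–D
  (edge-on "fan blade" poses solved by sliding to a 0.34 nm heavy-atom
  gap), starting 3 nm back along their own approach line so each flake's
  minimum distance to the DNA shrinks monotonically.  DNA is rigid;
  non-DNA atoms get seeded Gaussian jitter (σ = 0.01 nm, small enough
  never to flip a threshold).  The ground truth records, per frame and
  flake, the programmed site, an arrival flag, and an adsorbed flag
  measured with the same all-atom 0.6 nm criterion the classifier uses.
- *Unwinding*: programmed pairs open at given frames — both bases displace
  apart in-plane by 1.0 nm total, and the terminal pair shifts axially by
  0.02 nm per broken pair, so the hydrogen-bond count is exactly
  2n − 2k and the length strictly increases with k.
- *Aggregation*: flakes on a planar grid (centres ≥ 2 nm apart) merge into
  vertical stacks at 0.34 nm spacing per a schedule; cluster counts and
  the largest-cluster size follow from the bookkeeping exactly.

Because the mocks are kinematic, passing tests validate the *analysis*
code — not force fields, sampling, or any thermodynamic claim about real
GOQD–DNA systems.  Quantities that in a real study emerge from long
explicit-solvent MD (CSA plateaus, contact counts in the thousands, RMSD
convergence values, endpoint stacking counts, cluster-count decay) are out
of reach at this scale and are not asserted anywhere.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale systems: a
20-bp duplex (700 atoms), coronene-sized flakes (36–48 atoms), systems of
10–20 flakes, trajectories of 20–25 frames, and 10⁴-point uniform gases
for RDF normalization.  The whole suite completes in a few seconds.

## Known limitations

- The B-DNA template is idealized fiber-like geometry, not an equilibrated
  structure; absolute SASA/RDF values differ from solvated MD.
- The backbone proxy omits the sugar ring; per-residue SASA decomposition
  and helical-parameter analyses are out of scope.
- Only rectangular boxes; no velocities; no topology perception.
- The selection grammar covers chain/resname/name/element/resid with
  boolean combinations — not ranges or geometric selections.
- π–π ring tables ship for DA/DT only (extension point for other
  residues).
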