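# Methods

## System and model

`helicoil` analyses homodimeric four-helix transmembrane coiled coils of
the sensor-histidine-kinase type.  Each protomer contributes two helical
arms: TM1 (residues 14–34) continuing through a short sensor–TM linker
(34–38) into sensor helix H1 (membrane-proximal part, 39–60), and sensor
helix H4 (120–146) continuing into TM2 (147–167).  Residue numbers are
author numbering throughout, never re-indexed; coordinates are in Å and
frame times in ns.  Only backbone atoms (N, Cα, C, O) are modeled; a
residue must have a Cα to exist, other backbone atoms are optional and
flagged when absent (they are never estimated — a residue without O simply
contributes no hydrogen bonds, one without N/C no dihedrals).

Three conformational modes are quantified:

* **Helical rotation.**  The Crick angle of residue i is the signed angle,
  in the plane perpendicular to the local helix-axis tangent at i, between
  the direction from the axis point toward the bundle axis and the
  direction from the axis point to Cα(i).  The zero reference toward the
  bundle core follows the convention of coiled-coil parameterization
  tools; the sign is right-handed about the local N→C tangent and is
  controlled by a single constant (`crick.CRICK_HANDEDNESS`).  Rotation of
  a helix about its own axis shifts all its Crick angles uniformly by the
  rotation angle.
* **Diagonal scissoring.**  Per-residue cross-protomer Cα–Cα distances
  over residue sets 34–50 (TM1/H1 side) and 133–147 (H4/TM2 side).
* **Piston shift.**  Difference of equal-weight Cα-centroid projections of
  two segments (TM1 vs TM2 by default) on the bundle axis.  Cα centroids
  rather than all-atom mass-weighted centers keep the whole pipeline at
  backbone level; for long helices the two differ negligibly and only
  differences between states are interpreted.

## Geometric constructions

**Local helix axis.**  For residue i the angle bisectors of the Cα trace
at i and i+1 both point at the helix axis (exactly so for an ideal
helix).  The axis point of residue i is the midpoint of the shortest
segment connecting those two bisector lines, so it draws on Cα(i−1..i+2)
— a 4-Cα window, the minimum for the construction; terminal residues get
no axis point and are excluded from Crick angles.  Tangents are central
differences of axis points, normalized and oriented N→C.  On an ideal
helix the construction is exact to machine precision; under coordinate
noise its error grows smoothly (covered by a monotonicity test).

**Bundle axis.**  First principal component of the pooled axis points of
the given helices, after centering each helix's points on its own
centroid (without per-helix centering the lateral separation of the
helices, not their direction, would dominate the PCA).  The line passes
through the mean of the per-helix centroids.  Orientation convention,
fixed in one place: **+z is the periplasmic side**, i.e. the direction of
increasing TM1 residue numbers (residue 14 is cytoplasmic, 34
periplasmic).  This convention fixes all piston-shift signs.  A single
helix falls back to its own axis line.  When a membrane frame exists the
membrane normal would be the natural z axis; synthetic systems have no
membrane, so the bundle axis is used throughout.

**Superposition.**  CA-only, equal weights, via the optimal-rotation
solver of `scipy.spatial.transform.Rotation.align_vectors` (Kabsch
equivalent, always proper rotation).  RMSD is reported over the fitted
set; tests verify it equals the brute-force RMSD after applying the
returned transform.

**Dihedrals and linker state.**  φ/ψ are standard IUPAC backbone
torsions; residues at chain termini or with missing atoms are flagged
undefined rather than guessed.  A residue is "helical" iff
φ ∈ [−120°, −30°] and ψ ∈ [−80°, −5°] (closed intervals; boundary values
count as helical).  The window is a stated default, deliberately generous
around the canonical (−57°, −47°); the generator's broken-linker state
(ψ = 60°) and strand fixtures (ψ = 135°) are unambiguous under any
reasonable window.  A chain's linker state is "helical" iff every
classifiable linker residue (34–38) is helical, else "broken".

**Backbone hydrogen bonds.**  Residue i's carbonyl O is tested against
the amide N of i+3 (3₁₀-like) and i+4 (α); both may coexist (bifurcated).
A bond requires O···N ≤ 3.5 Å **and**, when the donor's amide hydrogen can
be placed (geometrically: 1.01 Å from N, in the C(prev)–N–Cα plane,
opposite their bisector), O···H ≤ 2.5 Å.  The directional term is
necessary, not cosmetic: on an ideal α-helix the *non-bonded*
O(i)···N(i+3) separation is ≈3.1 Å, inside any defensible N···O cutoff,
while the hydrogen criterion separates the patterns with wide margins
(α: O···H 1.89 Å at i+4 vs 2.69 Å at i+3; 3₁₀: 1.83 Å at i+3 vs 4.21 Å
at i+4).  Both cutoffs are per-call parameters.

**Circular statistics.**  All aggregation of angles uses circular means
(angle of the mean unit vector) and circular SD (√(−2 ln R)); linear
means of angles are not offered anywhere in the API, since the observed
distributions sit near the ±180° wrap.

## Trajectory pipeline

Analysis runs over the trailing window of a trajectory (default: last
200 ns), matching how equilibrated MD output is summarized.  Distances
are histogrammed at 0.1 Å, angles at 5°, per protomer.  Snapshot export
takes one frame per stride (default 10 ns → 20 snapshots per 200 ns
window), nearest-frame for incommensurate spacing with each frame used at
most once, and superposes every snapshot on the first using CA atoms of
residues 45–55 from both protomers.  Crystal-reference overlays evaluate
each descriptor once per reference structure — always computed, never
hard-coded, because no numeric reference values are available to copy.
Descriptors failing on isolated frames are flagged and counted; a
descriptor failing on more than half the frames aborts the run with a
diagnostic.  The pipeline contains no hidden randomness: identical inputs
give bit-identical CSVs.

The two-state comparison superposes state 2 onto state 1 using the core
set (residues 48–54 and 122–130, both protomers — the membrane-distal
parts that barely move), then reports per-residue Crick-angle changes
over H1, cross-protomer distance changes for both profile sets, and
per-residue axial displacements of TM1 measured after re-superposition on
TM2 (and of H1 on H4), projected on the reference state's bundle axis.
This operationalizes "piston shift of TM1 relative to TM2" for structure
pairs; the TM1-vs-TM2 versus H1-vs-H4 contrast quantifies how much the
linker break amplifies the piston.

## Synthetic generator

The generator is the package's ground-truth engine, not a fixture.  It
emulates the study conditions: a C2-symmetric dimer whose four helix axes
sit on a square of circumradius 7 Å about the bundle axis, helices as
ideal α-cylinders (rise 1.5 Å/residue, twist 100°/residue, Cα radius
2.3 Å, φ/ψ = −57°/−47° — canonical values), arms antiparallel with
residues 50 and 133 at the same height.  Cα atoms are placed exactly on
the requested cylinder; residue-template N/C positions are refined by
weighted least squares so that screw-replication reproduces ideal bond
lengths/angles and the requested torsions (torsions carry the largest
weights; measured φ/ψ land within ~0.3° of the request for canonical
parameters), and O is placed in the carbonyl sp² plane.  Non-helical
pieces (broken linker, strand fixtures) are built by internal-coordinate
(NeRF) chain extension.

State parameters are imposed as controlled sub-transformations with
exactly factorized effects:

* `h1_rotation_deg` — extra azimuthal phase for H1 residues about their
  own helix axis (changes Crick angles by exactly the imposed angle,
  leaves the fitted axis in place);
* `scissor_h1_tip_A` / `scissor_h4_tip_A` — rigid tilt of each arm about
  its membrane-distal end, with the angle solved (Brent) so the
  cross-protomer distance at the tip residue (34 / 147) changes by
  exactly the requested amount; positive = tips apart;
* `piston_tm1_z_A` / `piston_h1_z_A` — axial translations of TM1 and H1,
  linearly ramped across the linker;
* `linker_state` — 'broken' rebuilds residues 34–38 by torsion
  continuation with (φ, ψ) = (−80°, 60°), whose ψ falls outside the
  α-window; 'helical' keeps the continuous cylinder.

The bound-like preset carries the non-zero magnitudes (26° rotation, 3 Å
TM1 / 1 Å H1 piston, ±2 Å scissors, broken linker, 7.1 Å residue-50/133
contact); the free-like preset is the all-zero continuous-helix reference
at 7.8 Å contact.  The contact distances are the observed bound
(7.0–7.2 Å) and free (7.5–8.2 Å) ranges of the receptor; the directions
reproduce the activation mechanism (relative to bound: free has H1–H1′
tips closer, H4–H4′ farther, piston released, linker continuous), and the
piston magnitudes mirror the ~1 Å → ~3 Å amplification across the linker
break.  Putting the piston offsets on the broken-linker state keeps the
axial shear absorbed by the (already disordered) linker, so the
continuous-helix state stays classifiable.  Two-state pseudo-trajectories
concatenate state-A frames then state-B frames (switch fraction 0.5 by
default) and add i.i.d. Gaussian noise per coordinate from a seeded
generator; same seed → bit-identical coordinates.  Clash screening
rejects geometries with inter-chain Cα contacts under 2 Å.

What the generator does **not** emulate: solvent, lipids, side chains,
the ligand, physical dynamics or kinetics — frames are i.i.d. noisy
copies of two discrete states, with no autocorrelation or intermediate
conformations.  Recovery tests therefore demonstrate the correctness and
noise robustness of the descriptors, not anything about real free-energy
landscapes.  One geometric caveat documented here because a naive
expectation fails: rotating H1 about its own axis *does* move individual
Cα cross-protomer distances (by up to 2·r·sin(Δφ/2) ≈ 1 Å at 26°) even
though the helix axes stay fixed; "rotation is not scissoring" holds at
the level of fitted axis positions, which is what the tests assert.

## Problem sizes and numerical choices

Validation runs use dimers of 2 × 95 residues, trajectories of 20–400
frames, a 10⁴-sample Monte-Carlo oracle for noise-propagated distance
SD, and noise levels σ ∈ {0, 0.1, 0.3, 0.5} Å — sizes chosen so the full
suite runs in well under a minute while leaving Monte-Carlo comparisons
statistically meaningful (a sample SD over 200 frames has ≈5% relative
error, against a 10% test tolerance).  Noisy rotation recovery averages
Crick angles over trajectory windows (as the real analysis averages over
the last 200 ns) rather than using single structure pairs, whose
single-snapshot error at σ = 0.3 Å is several degrees.

Degenerate inputs are errors, not silent results: Crick angles are
refused when the Cα sits within 0.3 Å of its axis point or the axis point
lies on the bundle axis; axis fitting needs ≥ window+1 residues;
superposition needs ≥3 atoms; trajectory frames must share an exact
chain/residue/atom topology (atom order may permute; mapping is by name
and residue number).  Alternate-location atoms resolve to the
highest-occupancy conformer at parse time.  PDB round trips preserve
coordinates to the format's 10⁻³ Å precision; descriptor CSVs preserve
full float precision.

## Limitations

* The dimer-asymmetry estimate of the original study is not reproduced —
  its method is not described in the available text.  `ca_rmsd` between
  protomer A and protomer B after optimal superposition can serve as a
  crude stand-in but is *not* that metric.
* Crick angles use the bundle axis as reference; a pairwise helix–helix
  axis variant can be obtained by passing a two-helix `bundle_segments`
  list, but no claim is made that either matches unpublished reference
  values.
* The α-region φ/ψ window and the H-bond cutoffs are defensible defaults,
  not fitted to any experimental criterion; all are configurable.
* mmCIF writing, electron-density handling and ligand geometry are out of
  scope; binary trajectory reading requires MDAnalysis.
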