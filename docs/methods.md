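# Methods

This note documents the geometric models, conventions, numerical choices
and known limitations behind `g4geom`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Conventions

**Torsions.** All torsions use the standard nucleic-acid sign convention
(verified against rdkit, MDAnalysis and biotite on canonical test
configurations) and are reported on [0°, 360°), matching how glycosidic
restraints (anti ≈ 240°) and pucker windows (C2′-endo: 135–180°) are quoted
in the structural literature. Backbone angles are α: O3′(i−1)–P–O5′–C5′,
β: P–O5′–C5′–C4′, γ: O5′–C5′–C4′–C3′, δ: C5′–C4′–C3′–O3′,
ε: C4′–C3′–O3′–P(i+1), ζ: C3′–O3′–P(i+1)–O5′(i+1); χ is O4′–C1′–N9–C4 for
purines and O4′–C1′–N1–C2 for pyrimidines. Angles undefined at chain
termini or through missing atoms are reported as `None` with a recorded
reason, never as exceptions.

**Glycosidic classes.** *anti* ⇔ χ ∈ (170°, 310°); everything else is
*syn*. The window is the outer-tetrad restraint range 240 ± 70° turned into
a closed decision rule; a restraint window is not itself a classifier, so
the boundary placement is a design choice.

**Pseudorotation.** P and τm invert the cosine model
ν\_j = τm·cos(P + 144°(j−2)) exactly:
P = atan2((ν4+ν1) − (ν3+ν0), 2ν2(sin 36° + sin 72°)), with τm the length of
the corresponding resultant. Pucker classes are the ten 36°-wide sectors
centered at 18° + k·36° (C3′-endo at 18°, C2′-endo at 162°, …). A planar
ring (τm → 0) gets class `planar` and undefined P.

**z-deviation.** The plane is through C4′, O4′, C1′ with normal
n = unit((C1′ − C4′) × (O4′ − C4′)); z(X) = n · (X − C4′). The
cross-product order was calibrated on an independently embedded
D-2′-deoxyguanosine so that C2′-endo sugars give z\_C2′ > 0 and C3′-endo
sugars z\_C3′ > 0 (the endo side — toward C5′ and the base — is positive).
Note a geometric subtlety: C2′ and C3′ fall on *opposite* sides of the
plane only near the north/south of the pseudorotation wheel (where real
DNA sugars sit). For east/west puckers such as O4′-endo the displaced atom
is a plane atom itself, and C2′/C3′ legitimately share a side; the property
tests therefore assert the opposite-sign rule only within ±18° of 0°/180°,
and the class implications everywhere.

**Stacking twist.** The C1′→N9 (or C1′→N1) vectors of two stacked residues
are projected onto the plane perpendicular to the local stack axis,
oriented 5′→3′; the signed angle rotating the 5′ projection onto the 3′
projection is positive for right-handed (counter-clockwise looking down
the axis) progression. Left-handed cores give ≈ −27°/step.

**Superposition.** Kabsch closed form restricted to proper rotations
(mirror images never superpose to zero). Ensemble RMSD averages all
unordered model pairs; atom correspondence is by (chain, residue number,
atom name). The "all non-H atoms excluding the bulges" selector used for
crystal-structure comparisons is exposed as a predicate, not hard-coded,
because the atom set behind published single numbers is not always stated.

## Annotation model

A **tetrad** is a directed 4-cycle in the Hoogsteen-candidate graph:
guanine *i* donates to *j* when N2(i)→N7(j) ≤ 3.5 Å *and*
N1(i)→O6(j) ≤ 3.5 Å (the 2.9 ± 0.3 Å restraint targets plus
crystallographic tolerance; hydrogen criteria H21→N7/H1→O6 ≤ 2.5 Å apply
additionally whenever hydrogens exist, so heavy-atom-only crystal
structures analyze identically). Cycles must be near-planar (ring-atom RMS
< 1.0 Å); conflicts are resolved greedily in favour of the smaller
planarity RMS — the planarity restraint motivates the criterion, since no
published rule exists.

**Core assembly** orders tetrads along the principal axis of their
centroids, accepts adjacency below a 6 Å centroid separation (farther
tetrads become separate cores), matches guanines of adjacent tetrads into
columns by minimal C1′ distance (Hungarian assignment), and splits blocks
where the ring-order-oriented base normals of consecutive tetrads invert
(the 5′-5′ opposite-polarity interface). Handedness is the sign of the
mean intra-block signed twist with a ±10° confidence margin (generous
against the observed 27–30° magnitudes); interface steps are excluded.

**Elements.** Every non-core nucleotide run is classified from the column
membership of its sequence-flanking core guanines: same column and
stack-consecutive → *bulge*; different columns of one block → *loop*;
different blocks → *linker*; a missing anchor → *overhang*. Runs split at
backbone breaks (O3′–P > 2.2 Å) with a warning. Zero-nucleotide loops
(sequence-adjacent core guanines in different columns) are emitted as
loops with empty residue lists. The capping flag (element base centroid
within 4.5 Å of an outer-tetrad plane, lateral offset < 4 Å) and the
handedness margin are tunable; the capping thresholds are calibrated
values, since no numeric criterion for T-capping is published.

## Comparison model

Reference profiles pool the five transition torsions over all intra-block,
sequence-adjacent core steps of non-bulged structures of the declared
handedness (plus χ and P over all core guanines). Structures containing
bulges, failing annotation, or of the wrong handedness are rejected with
explicit warnings. Statistics are circular throughout (resultant-vector
mean; circular sd √(−2 ln R̄)) because the interesting alterations sit near
the 0°/360° wrap. Pooling weights all steps equally; per-structure
averaging first is available as an option.

Each bulge yields a *previous residue* record (step from the 5′-side core
guanine into the bulge) and a *next residue* record (step out of the bulge
into the 3′-side core guanine); this step convention is the default. The
alternative *skip* convention measures all five angles on the core
guanines as if the bulge were absent, making the two sides coincide; it is
selectable (`--transition-convention`) because the residue attribution
behind published per-side figures is ambiguous. Deviations are absolute
circular differences in [0°, 180°], flagged above a 60° threshold
(configurable). Pucker alteration is a class comparison against the
reference majority class — "P around 0°" claims are operationalized as the
C3′-endo sector, never as numeric equality.

## Synthetic generator

The generator produces idealized coordinates with exactly known ground
truth; it is geometric, not thermodynamic (no energies, ions or sterics).

* **Bases** are fixed planar templates in the standard reference frame.
* **Tetrad pose**: the in-plane guanine placement is solved so four copies
  related by 90° rotations close the Hoogsteen cycle at exactly
  N2→N7 = N1→O6 = 2.9 Å. The exact solutions are discrete; the physical
  one (sugars pointing outward, no inter-base overlap) is selected.
* **Sugars** are embedded from (P, τm): the furanose ring is solved in a
  local frame — ideal bond lengths exact, the five endocyclic torsions at
  their cosine-model targets in least squares (a closed five-ring with
  fixed bonds has only four torsional degrees of freedom, so the model's
  intrinsic slack, up to ≈0.6° depending on phase, lands in the torsions)
  — then attached to the base through the requested χ and the calibrated
  D-sugar chirality branch of the C1′ stereocenter.
* **Backbone**: residue units are placed rigidly by the helical parameters
  (twist, rise, column azimuths); each step's three linking atoms
  (P, O5′, C5′) are then solved for exact ideal bond lengths with
  near-ideal angles. This relaxed closure is deterministic and equivariant,
  so congruent core steps carry *identical* emergent torsions — the
  reference profile of a uniform core has zero circular spread by
  construction.
* **Bulges**: the thymine's rigid pose and both flanking linkers are
  solved jointly (a homotopy that ramps the step torsions from the start
  configuration's values to the no-bulge baseline plus the requested
  offsets), so the five transition torsions around the bulge are
  controlled *exactly*. Defaults alter α by −90° and β by −70°: the
  literature reports these alterations as magnitudes (~90°, ~70°), circular
  deviation is unsigned, and these signs are solvable for both helical
  senses.
* **Feasibility choices** (made once, all within published restraint
  windows): left-handed builds default to χ = 280° because the clash-free
  Hoogsteen-exact tetrad cannot close a −27°/3.3 Å step with rigid χ = 240°
  sugars (the O3′→C4′ gap exceeds the three-atom linker's 6.15 Å reach);
  right-handed builds use χ = 240°. Propeller loops wind with the helix
  sense (left-handed strands visit columns in the 0→3→2→1 azimuthal
  order). Two-block cores invert base polarity at the interface exactly as
  annotated in real structures, but the flipped block threads from its far
  face toward the interface with a 3-thymine linker — rigid units close
  the backbone in one direction only, whereas deposited structures enter
  the second block at the interface through a single-thymine linker by
  locally rearranging the backbone.
* **Noise** is isotropic Gaussian, applied last, fully seeded: one seed
  gives bit-identical output.

### What the generator does and does not emulate

It reproduces the *defining geometric observables* — Hoogsteen distances,
planarity, stacking twist and rise, pucker phase/amplitude, glycosidic
angle, element topology, polarity inversion — with exact ground truth. It
does **not** emulate thermal disorder, sequence-dependent base-step
variation, ion coordination, capping-base geometry optimization, backbone
conformer heterogeneity, or physically relaxed loop/bulge conformations
(loop and bulge backbones satisfy bond geometry, not energetics). Passing
the synthetic suites therefore demonstrates that the measurement and
classification machinery is correct and stable, not that real structures
have ideal geometry; analyses of deposited structures exercise the same
code paths on real coordinates.

## Problem sizes and tolerances

The default test fixtures are two-tetrad cores (the block size of the
four-layered, two-block left-handed structures) with single-thymine
propeller loops, four-layer stacks for multi-step twist statistics, and
two-block cores for interface handling. Synthetic round-trip tolerances:
0.5° on twist, P, τm, χ; 0.01 Å on distances; noise-stability checks use
σ = 0.1 Å over 100 seeds; profile recovery uses von Mises-distributed χ
over 25 repeats of 3-structure reference sets. Solver tolerances: ring
closure 1e−4 Å; step closure bonds 1e−4 Å; bulge-step torsion targets
0.01°. The acceptance script rebuilds everything from scratch with the
supplied seed; ensemble-RMSD checks compare the measured mean pairwise
RMSD of independently noised copies against the σ√6 expectation.

## Known limitations

* Tetrad detection assumes guanine Hoogsteen chemistry; mixed tetrads
  (e.g. G·C·G·C) are out of scope.
* Handedness is a single pooled verdict; cores with genuinely mixed
  per-block senses report `mixed` rather than per-block calls.
* The capping criterion is distance-based only; it does not assess ring
  overlap.
* Bulges in the polarity-flipped block of a synthetic two-block core are
  not supported (real-data analysis is unaffected).
* The z-deviation sign convention, while calibrated to D-sugars, flips for
  L-nucleic acids (mirror-image models), consistently with every other
  chirality-sensitive quantity.
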