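# g4geom

Geometric annotation and analysis of G-quadruplex (G4) structures, with a
focus on the features that distinguish **left-handed** G4s and the
**bulges** they can accommodate.

G-quadruplexes are four-stranded nucleic-acid structures built from stacked
G-tetrads — planar, cyclic arrangements of four guanines paired through
Hoogsteen hydrogen bonds (N2–H···N7 and N1–H···O6 around the cycle).
Outside the tetrad core, the important structural elements are *loops*
(connecting different G-columns), *bulges* (nucleotides protruding between
two stacked guanines of the **same** G-column), *linkers* (joining stacked
G4 blocks across a polarity-inverted 5′-5′ interface) and *overhangs*.
Telling a bulge from a loop requires the 3D structure, not the sequence:
the stacking guanines must be identified first, which in left-handed G4s
means recognizing an anticlockwise helical progression with a base rotation
magnitude of ≈27° per step.

`g4geom` provides, for structural biologists and nucleic-acid modellers:

* **structure I/O** — PDB and mmCIF reading/writing (via `gemmi`), with
  atom-name dialect normalization (`C1*` → `C1'`), altloc resolution and
  hetero tagging;
* **geometry** — backbone torsions α–ζ, glycosidic χ (O4′–C1′–N9–C4 for
  purines; anti ⇔ χ ∈ (170°, 310°)), Altona–Sundaralingam pseudorotation
  (P, τm) with the full 10-sector pucker wheel, the *z-deviation* pucker
  descriptor (signed distance of C2′/C3′ from the C4′–O4′–C1′ plane,
  calibrated so C2′-endo ⇒ z\_C2′ > 0), least-squares base planes, signed
  stacking twist, and Kabsch superposition RMSD (single pair or ensemble);
* **annotation** — tetrad detection from heavy-atom Hoogsteen distance
  criteria (≤ 3.5 Å), core assembly into columns/blocks with per-step
  signed twists, handedness classification (left ⇔ mean intra-block twist
  < −10°), and bulge/loop/linker/overhang classification with capping
  flags and local sugar orientation;
* **comparison** — circular-statistics reference profiles of the five
  transition torsions (ε, ζ of a step's 5′ residue; α+1, β+1, γ+1 of its
  3′ residue) plus χ and P, pooled over non-bulged reference structures;
  per-bulge deviation records with a >60° significance rule, and pucker
  alteration calls;
* **synthetic structures** — an idealized G4 coordinate generator (exact
  2.9 Å Hoogsteen geometry, controlled twist/rise, sugars embedded from
  (P, τm), bulges with exactly controlled transition-angle alterations,
  loops, two-block cores, noise) so the entire pipeline is testable with
  known ground truth and no downloads.

## Worked example

Build a left-handed bulged quadruplex and its bulge-free twin, then ask
which transition angles the bulge altered:

```python
from g4geom import BuildSpec, build_g4, annotate
from g4geom.comparison import (build_reference_profile, extract_transitions,
                               compare_to_reference)

twin   = build_g4(BuildSpec(n_tetrads=2, twist_per_step=-27.0))
bulged = build_g4(BuildSpec(n_tetrads=2, twist_per_step=-27.0,
                            bulges=((1, 0),)))   # one T in column 1

core, elements = annotate(bulged)
print(core.handedness,
      [round(t, 1) for t in core.intra_block_twists()],
      [e.kind for e in elements])
# left [-27.0] ['loop', 'loop', 'loop', 'bulge']

profile = build_reference_profile([twin], "left")
records = extract_transitions(core, elements, bulged)
for d in compare_to_reference(records, profile, threshold=60.0):
    if d.flagged:
        print(d.side, d.angle_name, round(d.deviation, 1))
# previous alpha+1 90.0
# previous beta+1 70.0
# next alpha+1 90.0
# next beta+1 70.0
```

The bulge leaves ε, ζ and γ+1 untouched (deviations 0.0°) and alters α+1
and β+1 by exactly the 90°/70° the build requested — the signature of a
single-thymine bulge between stacked guanines of one column in a
left-handed core.

The same pipeline runs from the shell on any PDB/mmCIF file:

```sh
g4geom annotate structure.pdb --out annotation/
g4geom compare --bulged bulged.pdb --reference ref1.pdb --reference ref2.pdb \
               --handedness left --threshold 60 --out report/
g4geom synth --tetrads 2 --twist -27 --bulges 1:0 --seed 7 --out synth.pdb
g4geom rmsd a.pdb b.pdb
```

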