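# Methods

## Scope and model

The package models the geometry of one- and two-metal-ion nuclease active
sites — catalytic centers in which one Mg²⁺ (HNH-type) or two Mg²⁺
(RuvC-type) ions, octahedrally coordinated by carboxylate oxygens, an
imidazole nitrogen, water oxygens and scissile-phosphate oxygens at roughly
2.0 Å, position a water nucleophile for in-line attack on a DNA backbone
phosphate. Around that core it provides the supporting workflow a modeller
needs when no single experimental structure captures the cleavage state:
chimeric assembly from several templates, rigid-body density fitting, and
geometric screening of general-base candidates.

## Coordination restraints and the surrogate energy

Refinement minimizes

E = Σ k_d (d − d₀)² + Σ k_a (θ − θ₀)² + Σ_{pairs, d < r_min} k_rep (r_min − d)²

| parameter | default | units | role |
|---|---|---|---|
| d₀ | 2.0 | Å | Mg–O and Mg–N coordination target (configurable per pair) |
| k_d | 100 | energy/Ų | distance stiffness; dominates the other terms |
| θ₀ | 90 | degrees | cis ligand-pair target under the octahedral assignment |
| k_a | 0.02 | energy/deg² | angle stiffness; soft, shapes rather than pins |
| r_min | 2.4 | Å | soft-sphere contact floor |
| k_rep | 50 | energy/Ų | contact stiffness; prevents collapse |
| mobile radius | 8.0 | Å | sphere around the site's ions inside which atoms move |

Angle restraints cover the 12 cis pairs of each ion's best octahedral
vertex assignment (found by trying all injective ligand-to-vertex
assignments with an SVD-optimal rotation per assignment); the three trans
pairs are implied by the cis set and left unrestrained. Two-metal sites
carry six distance restraints per ion. A backbone oxygen within the
ligand-inclusion radius (3.5 Å) of both ions bridges them and is restrained
to each; a carboxylate whose two oxygens both fall in range is treated as a
metal bridge, one oxygen per ion, paired to minimize total distance so that
coordinate noise near the inter-ion midplane cannot flip the assignment.

**No ion–ion restraint exists in any restraint set.** The two-metal spacing
must emerge from the shared bridging-ligand geometry; it is an output of
refinement, never an input.

**Repulsion exemption.** The soft-sphere floor applies to heavy-atom pairs
*not governed by the restraint network*: pairs in the same residue, in
covalently bonded neighbor residues, directly restrained to each other, or
with both members belonging to the site's restrained atom set (ions plus
designated ligands) are exempt. The last exemption is load-bearing: with
full 2.0 Å octahedral shells on two ions ~3.2–3.3 Å apart, cross-shell
donor–donor contacts of ~2.0–2.2 Å are geometrically intrinsic (a numerical
search over all shell orientations bounds the best achievable non-bridge
cross-shell separation at ~2.0 Å for 3.2 Å ion spacing). A generic 2.4 Å
floor applied inside the network would push the refined ion spacing out
toward ~3.8 Å — i.e. the floor, not the coordination architecture, would
own the answer. The restraints own the network; the floor protects
everything else.

**Minimizer.** L-BFGS with a strong-Wolfe line search over the mobile
atoms, analytic gradients for every term (verified against central finite
differences in a property test), gradient tolerance 1e-6, at most 5000
iterations. Accepted iterates never increase the energy; the trajectory is
recorded and asserted monotone. The refiner accepts a seed for interface
symmetry but is fully deterministic.

## Octahedricity

For a six-coordinate shell the score is the minimum over the 15 partitions
of the ligands into three trans pairs of the RMS of |observed − ideal|
across all 15 ligand-pair angles (ideal 180° for the trans pairs, 90°
otherwise). This equals the minimum over all 6! vertex assignments, which
the test suite verifies against an independent permutation brute force.
Shells with other coordination numbers are flagged incomplete and scored
by matching each observed angle to the nearer of 90°/180°. Ion labels in
two-metal sites: ion A is the one nearer the His Nδ1 donor when the site
defines one, else nearer the scissile pro-Rp oxygen; ties break on atom
serial.

Shell classification: first shell = protein residues with a side-chain
N/O/S within 2.6 Å of any site ion (the 2.6 Å default encloses 1.8–2.1 Å
coordination bonds with margin while excluding second-sphere atoms); second
shell = remaining protein residues with a side-chain donor within 6.0 Å of
an ion or of a first-shell ligand atom. Both cutoffs are arguments.

## Scissile phosphate and the general-base screen

Strand positions are counted −1, −2, … moving 5′-ward from the PAM-proximal
nucleotide; the cleavage linkage lies between −3 and −4, consistent with
blunt cleavage 3 bp from the PAM. The linkage's P atom belongs to the
−3 nucleotide; O3′ of the −4 nucleotide is the leaving group. The pro-Rp
non-bridging oxygen is identified geometrically (the sign of
det[O5′−P, O3′−P, OP−P]) rather than trusted from OP1/OP2 naming.

A His candidate passes the screen iff its Cα lies within the screen radius
(default 10.0 Å, chosen to admit candidates near 9.6 Å with margin) of the
scissile P *and* the angle between the Cγ→Nδ1 bond direction and the Nδ1→P
direction is at most the orientation threshold (default 60°; "points
toward" is not sharper than that, so the threshold is configurable and
always reported alongside results). The reference distance reported with
every screen is 7.8 Å, the Cα–P distance of the canonical one-metal
general base. In-line attack geometry reports the nucleophile–P distance
and the deviation of the nucleophile–P–O3′ angle from the ideal 180°.

## Density fitting

Model density: each heavy atom contributes an isotropic Gaussian of width
σ = 0.425 × stated resolution (the half-width convention of common fitting
tools) and amplitude proportional to atomic number, accumulated on a
regular grid with 4σ support. Scoring: Pearson correlation between map and
model density over the map voxels inside the model's padded bounding box,
both z-scored. Pose search: deterministic pattern search — six axis
translations (initial step one voxel) and six axis rotations about the
model centroid (initial step 4°), taking the best improving move and
halving the steps when none improves, down to 0.05 Å / 0.1°. Accepted
scores are monotone non-decreasing. This local search assumes a starting
pose within a few Å / tens of degrees of the optimum, which is the regime
of template-derived models; there is no FFT global search.

## Synthetic fixtures and what they do (not) show

The generators build standard-nomenclature structures (ASP/GLU/ASN/HIS
side-chain fragments, HOH, DT/DC nucleotides, MG) so downstream code never
special-cases synthetic input; every planted quantity is recorded in a
JSON manifest that oracle tests read instead of re-deriving.

* **One-metal site**: Mg at the origin, six O donors at octahedral vertices
  at d₀ = 2.0 Å (Asp Oδ1, Asn Oδ1, two waters, one non-bridging phosphate
  oxygen from each of two consecutive nucleotides of a 5-nt strand), a
  His mimic in the second shell with Cα 7.8 Å from the scissile P and the
  imidazole chain collinear with the Cα→P direction. `sigma` adds seeded
  Gaussian noise to the six ligand atoms only.
* **Two-metal site**: ions 3.30 Å apart. The designed spacing sits inside
  the 3.0–4 Å range that two-metal centers occupy and was fixed together
  with the shell orientations (equatorial phases 60°/61°, from the same
  numerical search as above) so that the designed geometry satisfies every
  default restraint *exactly* and is clash-free at 2.0 Å: the scissile
  pro-Rp oxygen bridges both ions as a shared vertex; the two closest
  cross-shell vertex pairs are realized as the two bridging carboxylates
  (one oxygen per ion, bite ~2.0 Å); His Nδ1 coordinates ion A; a second
  carboxylate and waters complete the shells. Because the design is an
  exact energy zero, refinement started from it is a fixed point and the
  measured Mg–Mg spacing is genuinely produced by the bridging network.
  His mimics with Cα at 7.3 and 9.6 Å from P (imidazole at P) provide
  general-base candidates; the coordinating His points at the ion and
  fails the orientation screen by construction.
* **Duplex**: idealized B-form-like double helix (rise 3.38 Å, twist 36°,
  P radius 8.9 Å) with P/OP1/OP2/O5′/O3′/C1′ per residue and O3′(i)–P(i+1)
  linkage distances of 1.6 Å. Base pairing, sugar puckers and sequence-
  dependent geometry are not modelled.
* **Template triplet**: a reference complex (six 12-residue helical
  Cα/Cβ pseudo-domains on a ring, duplex, two ions); template B and C are
  globally moved by planted rigid transforms with their non-donor domains
  additionally hinged away, so only the recipe's assembly reproduces the
  reference; the manifest stores the true transforms.

Passing tests on these fixtures demonstrate the correctness of the
geometry, assembly and refinement machinery under known ground truth. They
do not demonstrate transferability to experimental coordinates — fixtures
have no conformational strain, missing atoms, alternate locations or
density noise, and the refined distances recover the restraint targets by
construction of a consistent restraint set, not because the energy model
captures real Mg²⁺ bonding.

## Numerical choices and degenerate inputs

* Altlocs collapse to the highest-occupancy conformer (ties: alphabetical
  altloc) at parse time; hydrogens are parsed but excluded from all
  geometry; author residue numbering is preserved verbatim; coordinates
  are Å throughout.
* Superposition requires ≥ 3 non-collinear pairs and forbids reflections
  (determinant forced to +1). Pairing key: (chain, seq, icode, atom name);
  unmatched residues are skipped with a logged count.
* Clash detection excludes same-residue pairs, consecutive-residue pairs
  in a chain (covalent neighbors), and metal-to-N/O/S contacts
  (coordination bonds); the k-d-tree path is asserted equal to the
  all-pairs brute force.
* Distance ties in shell listings break on atom serial; candidate ties in
  the screen break on residue number.
* Water placement puts O atoms at 2.0 Å along the open ideal-vertex
  directions of the partial shell's best octahedral fit and fails loudly
  on a saturated ion.
* Angle gradients guard sin θ ≥ 1e-6; arccos conditioning near 0°/180°
  limits orientation-angle reproducibility to ~1e-4 degrees, far below
  any decision threshold.

## Problem sizes

The shipped protocols operate on sites of 30–60 atoms (≤ ~35 mobile), maps
of ~40³ voxels, and 100-seed perturbation ensembles; refinement of one site
converges in well under a second and the full test suite plus the headline
recomputation completes in well under a minute on one CPU. These sizes were
chosen because the quantities of interest — coordination distances, shell
composition, emergent ion spacing, screen distances — are properties of the
site, not of the scaffold bulk.

## Known limitations

* The harmonic-plus-soft-sphere energy has no bonded terms, electrostatics
  or solvent; stub atoms of mimic residues are held only by the repulsion
  floor. Conclusions about energetics (pKa, proton transfer, reaction
  barriers) are out of scope by design.
* The two-metal spacing, while never restrained, is stabilized by the
  bridging topology the site definition designates; with no bridging
  ligand at all the spacing would be undetermined up to the repulsion
  floor.
* Domain boundaries for chimeric assembly must be stated in the recipe;
  the conventional SpCas9 table shipped as a convenience is from prior
  structural literature and is overridable, and junction residues between
  donors are never guessed.
* The density-fit search is local; poses farther than a few voxels /
  ~10° from the optimum may converge to a side lobe.
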