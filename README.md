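# mgforge

Tools for building and interrogating atomic models of metal-dependent
nuclease active sites — the kind of model needed to ask *how* an enzyme like
SpCas9 positions Mg²⁺ ions, water and catalytic side chains around a
scissile DNA phosphate when no experimental structure captures the cleavage
state directly.

The package is aimed at structural biologists and modellers who need to:

1. **Assemble a chimeric model** of a multi-domain protein–RNA–DNA complex
   from several templates, each of which captures a different part of the
   active conformation (rigid domain transfer after optimal superposition,
   with clash checking).
2. **Fit** the composite model into a density map by rigid-body
   cross-correlation search.
3. **Refine metal sites under coordination restraints**: harmonic distance
   restraints near 2.0 Å between Mg²⁺ and its N/O donors plus octahedral
   angle restraints, standing in for a restrained-MD treatment.
4. **Analyze the coordination geometry**: first/second shell membership,
   coordination number, octahedricity (RMS deviation of ligand–metal–ligand
   angles from the ideal 90°/180° vertex assignment), and the distance
   tables that characterize one-metal (HNH-type) and two-metal (RuvC-type)
   catalytic centers.
5. **Screen general-base candidates**: locate the scissile phosphate
   (between strand positions −3 and −4 from the PAM-proximal nucleotide),
   then rank histidines by Cα–P distance against the 7.8 Å reference of the
   canonical one-metal general base and by whether the imidazole Nδ1 points
   at the phosphorus, plus in-line-attack geometry checks
   (nucleophile–P–O3′ angle near 180°).

## The model in brief

A metal site is scored and refined with the surrogate energy

```
E = Σ k_d (d − d₀)²  +  Σ k_a (θ − θ₀)²  +  Σ_{d<r_min} k_rep (r_min − d)²
```

with `d₀ = 2.0 Å` for every Mg–O/N pair, `θ₀ = 90°` for the cis ligand
pairs of each ion's best octahedral vertex assignment, and a soft-sphere
floor `r_min = 2.4 Å` for heavy-atom pairs not governed by the restraint
network. Two-metal sites get six restraints per ion with bridging
scissile-phosphate oxygens shared between the shells — and deliberately
**no ion–ion restraint**, so the characteristic ~3.2 Å Mg–Mg spacing is an
emergent property of the bridging geometry, not an input. Minimization is
a deterministic quasi-Newton descent with monotone non-increasing energy.

Octahedricity of a six-coordinate shell is the minimum, over all
assignments of ligands to octahedron vertices, of the RMS deviation of the
15 ligand-pair angles from their assigned ideals; an independent
6!-permutation brute force backs it in the tests.

## Worked example

Generate the synthetic two-metal (RuvC-like) site, refine it under the
default coordination restraints, and screen for general bases:

```bash
mgforge make-fixtures --kind two_metal_site --seed 7 --outdir fx
mgforge refine --model fx/two_metal_site.pdb --site ruvc --chain A \
    --mechanism two_metal --seed 1 --out refined.pdb --trace energy.csv
# converged=True iterations=24 final energy=1.59e-14 max residual=3.978e-09 A
mgforge analyze-metals --model refined.pdb --site ruvc --chain A
```

The analysis reports (abridged):

```json
{
  "distances": {
    "MgA-MgB": 3.3,
    "ASP10:OD1-MgA": 1.9999,
    "GLU762:OE1-MgA": 2.0001,
    "HIS983:ND1-MgA": 2.0001,
    "ASP986:OD1-MgB": 1.9998
  },
  "first_shell":  ["A:10", "A:762", "A:983", "A:986"],
  "second_shell": ["A:982", "A:985"]
}
```

Every donor sits 2.0 Å from its ion; the two ions end 3.3 Å apart with no
restraint between them; the four acidic/His residues form the first
coordination shell, while the two candidate general bases sit in the second
shell. Screening those candidates:

```bash
mgforge screen-bases --model refined.pdb --nts-chain C --pam-pos 5
```

```json
{
  "candidates": [
    {"residue": "A:983", "d_ca_p": 6.062, "orientation_angle": 72.01, "passes": false},
    {"residue": "A:982", "d_ca_p": 7.3,   "orientation_angle": 0.0,   "passes": true},
    {"residue": "A:985", "d_ca_p": 9.6,   "orientation_angle": 0.01,  "passes": true}
  ]
}
```

The ion-coordinating histidine fails the orientation test (its imidazole
points at Mg²⁺ A, not at the phosphorus), while the two His residues at
7.3 and 9.6 Å from the scissile P pass both criteria — the geometric
signature of general-base candidates.

## Package layout

| module | contents |
|---|---|
| `mgforge.structio` | structure hierarchy, PDB/mmCIF I/O (gemmi-backed), selections |
| `mgforge.superpose` | Kabsch superposition, RMSD, domain-restricted alignment |
| `mgforge.chimera` | component extraction, domain transfer, clash detection, assembly |
| `mgforge.metalgeom` | ion finding, coordination shells, octahedricity, distance tables |
| `mgforge.restrain` | coordination restraints, harmonic energy, restrained minimizer, water placement |
| `mgforge.basescreen` | scissile-phosphate location, general-base screen, in-line geometry |
| `mgforge.densfit` | simulated density, cross-correlation, rigid-body fitting, MRC I/O |
| `mgforge.synthfix` | synthetic fixtures with planted ground truth (manifests) |
| `mgforge.pipeline` | YAML-configured end-to-end orchestration |
| `mgforge.cli` | `mgforge` command-line entry points |
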