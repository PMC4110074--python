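# redoxpot

Reduction potentials of redox-site-containing proteins from crystal
structures, by continuum electrostatics.

The free energy of reduction is split into an **intrinsic** term
`dG_in` (a precomputed quantum-chemical value stored in a parameter
library, per redox-site type and couple) and an **environmental** term
`dG_out` computed from the structure by finite-difference linear
Poisson–Boltzmann (PB) calculations through a four-state thermodynamic
cycle:

```
E0 = -(dG_in + dG_out + dG_SHE) / (n * F)

dG_out = dG_solv(reduced) - dG_solv(oxidized)
```

`dG_solv` is the "solvation" free energy of the redox site by the rest
of the protein plus solvent: the difference between a PB solve of the
whole system (three dielectric regions: site eps=1, protein eps=4,
solvent eps=78) and the site alone in vacuum (uniform eps=1).  `F` is
chosen so 1 V corresponds to 23.0605 kcal/mol per electron;
`dG_SHE = +102.158 kcal/mol` encodes a 4.43 V absolute reference
electrode.  Grid self-energies cancel exactly because all four legs
share one grid and one charge discretization.

Currently supported sites: cysteine-ligated [4Fe-4S] cubane clusters
(PDB residue names `SF4`/`FS4`), couples 1-/2- and 2-/3-, one site and
one electron per run.

## What it does

- **Structure model** — reads PDB (Biopython), keeps one monomer,
  partitions atoms into protein / standard-heteroatom / redox-site
  segments, detects ligating side chains by a 2.6 A heteroatom bond
  cutoff, assigns CHARMM36-style charges and vdW radii from shipped
  residue templates, and builds hydrogens from ideal geometry (crystal
  structures usually carry none).  Protonation-state edits
  (hsd/hse/hsp, aspp, glup, lsn, cysm), charge knock-outs, and
  truncation point mutations (X→ALA/GLY and other subset targets) are
  supported; the four cycle states can be exported as PQR.
- **PB engine** — edge-centered dielectric maps with harmonic-mean
  boundary smoothing, trilinear charge spreading, Debye–Hückel/Coulomb
  boundary conditions, two-level grid focusing, Jacobi-preconditioned
  conjugate gradients (deterministic), and an exact DST direct solve
  for uniform-dielectric reference legs.  Validated against the Born
  ion and Kirkwood off-center-charge closed forms (≤2% / ≤3% at 0.25 A
  focused spacing).
- **Analyses** — per-residue electrostatic contributions by charge
  knock-out (|contribution| > 0.03 V flags a sequence determinant),
  protonation shifts and mutation shifts.  All differences are computed
  from `dG_out` directly, so `dG_in`/`dG_SHE` cancel bit-for-bit.
- **Fixtures** — Born ion, off-center sphere (with an independent
  Kirkwood-series oracle) and a deterministic toy site-plus-shell
  system exercise the full pipeline with no external data.

## Command line

```sh
# validate a redox parameter library file
redoxpot lib validate src/redoxpot/data/redox_library.yaml

# build the four cycle states as PQR files
redoxpot build protein.pdb --monomer A --site SF4 --couple 1-/2- -o states

# full reduction-potential calculation (JSON report)
redoxpot redox protein.pdb --couple 1-/2- --spacing 0.4 -o result.json

# the same with an edited structure
redoxpot redox protein.pdb --protonate 42:hsp --knockout "resid 42"
redoxpot redox protein.pdb --protonate 42:hsp --mutate 42:ALA

# knock-out scan over residues, flagging determinants (>0.03 V)
redoxpot contrib protein.pdb --residues 10,42,57 -o contrib.json

# analytic validation fixtures
redoxpot fixture born -q -1 -a 2.0 -o born.pqr
redoxpot fixture offcenter -q 1 -a 3 -d 1 -o kirkwood.pqr
redoxpot fixture peptide --seed 7 -o toy.pqr
```

Selections use a small conjunctive grammar: `resid N`, `resid N:M`,
`segid X`, `name PATTERN` (fnmatch), e.g. `"resid 42 name ND1"`.
PB parameters (`--spacing`, `--eps-core/-protein/-solvent`, or a YAML
`--config`) default to 0.4 A fine spacing and dielectrics 1/4/78; use
0.2 A for higher accuracy.

## Library format

`src/redoxpot/data/redox_library.yaml` documents the entry format:
multi-document YAML with site residue names and aliases, the couple,
`dg_in_kcal`/`dg_she_kcal`, per-state partial charges and radii for the
cofactor core and the ligating side-chain atoms, and provenance text.
Entries are validated on load (formal-charge sums, one-electron couples,
positive radii).  The shipped `dg_in` values are documented placeholders
in the physically expected range: the quantum-chemical intrinsic terms
are not derivable from structure, and users should supply or recalibrate
them (absolute E0 shifts rigidly with `dg_in`; all difference analyses
are independent of it).
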