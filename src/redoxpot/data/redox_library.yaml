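# Redox parameter library.
#
# One YAML document per entry.  Units: charges in e, radii in Angstrom,
# free energies in kcal/mol.  Sign convention (documented in README):
#
#     E0 = -(dg_in + dg_out + dg_she) / (n * F),  F = 23.0605 kcal/(mol*V)
#
# so dg_she = +102.158 kcal/mol corresponds to an absolute standard
# hydrogen electrode potential of 4.43 V.
#
# dg_in values for the cysteine-ligated [4Fe-4S] couples are quantum-
# chemical quantities that are NOT derivable from structure; the shipped
# numbers are placeholders in the physically expected range, to be
# replaced (or recalibrated against a measured benchmark) by the user.
# The per-atom charge sets below are constructed, symmetric models that
# satisfy the formal-state sums; they are not fitted values.
---
site: SF4
aliases: [FS4]
couple: 1-/2-
n_electrons: 1
dg_in_kcal: -49.5
dg_she_kcal: 102.158
state_resnames: {ox: FS4O, red: FS4R}
provenance: >
  Constructed placeholder parameter set for the cysteine-ligated
  [4Fe-4S] high-potential couple; charge sets distribute the formal
  site charge uniformly over the cubane core and thiolate ligands.
core_atoms:
  - {name: FE1, radius: 1.4, q_ox: 0.50, q_red: 0.42}
  - {name: FE2, radius: 1.4, q_ox: 0.50, q_red: 0.42}
  - {name: FE3, radius: 1.4, q_ox: 0.50, q_red: 0.42}
  - {name: FE4, radius: 1.4, q_ox: 0.50, q_red: 0.42}
  - {name: S1, radius: 1.9, q_ox: -0.45, q_red: -0.52}
  - {name: S2, radius: 1.9, q_ox: -0.45, q_red: -0.52}
  - {name: S3, radius: 1.9, q_ox: -0.45, q_red: -0.52}
  - {name: S4, radius: 1.9, q_ox: -0.45, q_red: -0.52}
ligand:
  residue: CYS
  link_atom: SG
  count: 4
  atoms:
    - {name: SG, radius: 2.0, q_ox: -0.40, q_red: -0.50}
    - {name: CB, radius: 2.175, q_ox: -0.08, q_red: -0.08}
    - {name: HB1, radius: 1.32, q_ox: 0.09, q_red: 0.09}
    - {name: HB2, radius: 1.32, q_ox: 0.09, q_red: 0.09}
---
site: SF4
aliases: [FS4]
couple: 2-/3-
n_electrons: 1
dg_in_kcal: -5.0
dg_she_kcal: 102.158
state_resnames: {ox: FS4P, red: FS4Q}
provenance: >
  Constructed placeholder parameter set for the cysteine-ligated
  [4Fe-4S] ferredoxin couple; oxidized charges equal the reduced
  charges of the 1-/2- entry.
core_atoms:
  - {name: FE1, radius: 1.4, q_ox: 0.42, q_red: 0.34}
  - {name: FE2, radius: 1.4, q_ox: 0.42, q_red: 0.34}
  - {name: FE3, radius: 1.4, q_ox: 0.42, q_red: 0.34}
  - {name: FE4, radius: 1.4, q_ox: 0.42, q_red: 0.34}
  - {name: S1, radius: 1.9, q_ox: -0.52, q_red: -0.59}
  - {name: S2, radius: 1.9, q_ox: -0.52, q_red: -0.59}
  - {name: S3, radius: 1.9, q_ox: -0.52, q_red: -0.59}
  - {name: S4, radius: 1.9, q_ox: -0.52, q_red: -0.59}
ligand:
  residue: CYS
  link_atom: SG
  count: 4
  atoms:
    - {name: SG, radius: 2.0, q_ox: -0.50, q_red: -0.60}
    - {name: CB, radius: 2.175, q_ox: -0.08, q_red: -0.08}
    - {name: HB1, radius: 1.32, q_ox: 0.09, q_red: 0.09}
    - {name: HB2, radius: 1.32, q_ox: 0.09, q_red: 0.09}
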