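"""Partitioning, redox-site assembly and four-state building."""


import numpy as np
import pytest

from redoxpot.library import get_entry
from redoxpot.fixtures import toy_entry
from redoxpot.structure import (read_structure, partition_segments,
                                assign_redox_site, parameterize,
                                build_states, CompositionError,
                                StructureError, LIGAND_BOND_CUTOFF,
                                ROLE_PROTEIN, ROLE_REDOX, ROLE_GOOD_HET)
from redoxpot.structure.records import AtomRecord, SegmentedSystem

from conftest import build_mini_protein, write_pdb


class TestPartition:
    def test_roles_and_membership(self, mini_pdb, library):
        raw = read_structure(mini_pdb)
        system = partition_segments(raw, "A", library)
        assert system.segment_roles == {"a-pro": ROLE_PROTEIN,
                                        "a-bad": ROLE_REDOX,
                                        "a-het": ROLE_GOOD_HET}
        bad = {a.residue_name for a in system.atoms
               if a.segment_id == "a-bad"}
        het = {a.residue_name for a in system.atoms
               if a.segment_id == "a-het"}
        assert bad == {"SF4"}
        assert het == {"SO4"}

    def test_partition_is_a_partition(self, mini_pdb, library):
        raw = read_structure(mini_pdb)
        system = partition_segments(raw, "A", library)
        n_chain_a = sum(1 for a in raw.atoms if a.segment_id == "A")
        kept = len(system.atoms)
        dropped = (system.discard_report["waters"]
                   + sum(system.discard_report["unknown_het"].values()))
        assert kept + dropped == n_chain_a
        assert all(a.segment_id in system.segment_roles
                   for a in system.atoms)

    def test_waters_discarded_and_counted(self, mini_pdb, library):
        raw = read_structure(mini_pdb)
        system = partition_segments(raw, "A", library)
        assert system.discard_report["waters"] == 2
        assert not any(a.residue_name == "HOH" for a in system.atoms)

    def test_keep_waters_flag(self, mini_pdb, library):
        raw = read_structure(mini_pdb)
        system = partition_segments(raw, "A", library, keep_waters=True)
        waters = [a for a in system.atoms if a.residue_name == "HOH"]
        assert len(waters) == 2
        assert all(a.segment_id == "a-het" and a.charge == 0.0
                   for a in waters)

    def test_unknown_heteroatom_flagged_and_excluded(self, tmp_path,
                                                     library):
        atoms = build_mini_protein()
        atoms.append(dict(name="C1", resname="XYZ", chain="A", resid=401,
                          xyz=np.array([14.0, 0, 0]), occ=1.0, altloc="",
                          element="C"))
        path = tmp_path / "unknown.pdb"
        write_pdb(atoms, path)
        system = partition_segments(read_structure(path), "A", library)
        assert system.discard_report["unknown_het"] == {"XYZ": 1}
        assert not any(a.residue_name == "XYZ" for a in system.atoms)

    def test_missing_monomer(self, mini_pdb, library):
        with pytest.raises(StructureError, match="monomer"):
            partition_segments(read_structure(mini_pdb), "Z", library)

    def test_second_monomer_discarded(self, mini_pdb, library):
        raw = read_structure(mini_pdb)
        system = partition_segments(raw, "A", library)
        assert system.discard_report["other_monomers"] == 5


class TestAssignRedoxSite:
    def test_four_cysteines_reassigned(self, mini_pdb, library):
        entry = get_entry(library, "SF4", "1-/2-")
        system = partition_segments(read_structure(mini_pdb), "A", library)
        assigned = assign_redox_site(system, entry)
        assert len(assigned.ligating) == 4
        bad_names = sorted(a.atom_name for a in assigned.atoms
                           if a.segment_id == "a-bad")
        assert bad_names.count("SG") == 4
        assert bad_names.count("CB") == 4
        assert bad_names.count("HB1") == 4
        # backbones stay in the protein segment
        for (_, rid) in assigned.ligating:
            pro = [a.atom_name for a in assigned.atoms
                   if a.residue_id == rid and a.segment_id == "a-pro"]
            assert {"N", "CA", "C", "O"} <= set(pro)

    def test_composition_matches_entry(self, mini_pdb, library):
        entry = get_entry(library, "SF4", "1-/2-")
        system = partition_segments(read_structure(mini_pdb), "A", library)
        assigned = assign_redox_site(system, entry)
        counts = {}
        for a in assigned.atoms:
            if a.segment_id == "a-bad":
                counts[a.atom_name] = counts.get(a.atom_name, 0) + 1
        assert counts == entry.composition()

    def test_distance_cutoff(self, tmp_path, library):
        """SG at 2.3 A is reassigned; SG at 3.5 A is not."""
        entry = get_entry(library, "SF4", "1-/2-")
        for dist, ok in ((2.3, True), (3.5, False)):
            atoms = [a for a in build_mini_protein()
                     if not (a["resname"] == "CYS" and a["resid"] == 6)]
            # rebuild residue 6 with its SG at the requested Fe distance
            from conftest import sf4_cube, _unit, _perp_basis, backbone
            fe = sf4_cube()["FE4"]
            f = _unit(fe)
            e1, _ = _perp_basis(f)
            sg = fe + dist * f
            cb = sg + 1.81 * _unit(f + 0.35 * e1)
            ca = cb + 1.53 * _unit(f - 0.25 * e1)
            n, c, o = backbone(ca, _unit(cb - ca))
            for name, xyz in (("N", n), ("CA", ca), ("CB", cb),
                              ("SG", sg), ("C", c), ("O", o)):
                atoms.append(dict(name=name, resname="CYS", chain="A",
                                  resid=6, xyz=xyz, occ=1.0, altloc="",
                                  element=name[0]))
            path = tmp_path / f"cutoff_{dist}.pdb"
            write_pdb(atoms, path)
            system = partition_segments(read_structure(path), "A", library)
            if ok:
                assigned = assign_redox_site(system, entry)
                assert ("a-pro", 6) in assigned.ligating
            else:
                with pytest.raises(CompositionError):
                    assign_redox_site(system, entry)
        assert LIGAND_BOND_CUTOFF == pytest.approx(2.6)

    def test_cofactor_without_ligand_requirement(self):
        """Entry with no ligand spec: site stays heteroatoms-only."""
        entry = toy_entry()
        atoms = []
        for spec, xyz in zip(entry.core_atoms,
                             ([1.1, 1.1, 1.1], [-1.1, -1.1, 1.1],
                              [1.1, -1.1, -1.1], [-1.1, 1.1, -1.1])):
            atoms.append(AtomRecord(spec.name, spec.name[:2].capitalize(),
                                    "TOY", 100, "t-bad", np.array(xyz)))
        system = SegmentedSystem(atoms=atoms,
                                 segment_roles={"t-bad": ROLE_REDOX})
        assigned = assign_redox_site(system, entry)
        assert [a.atom_name for a in assigned.atoms] == \
            [a.atom_name for a in atoms]

    def test_no_redox_segment_refused(self, twelve_atom_pdb, library):
        entry = get_entry(library, "SF4", "1-/2-")
        system = partition_segments(read_structure(twelve_atom_pdb), "A",
                                    library)
        with pytest.raises(CompositionError):
            assign_redox_site(system, entry)


@pytest.fixture(scope="module")
def prepared(mini_pdb, library):
    entry = get_entry(library, "SF4", "1-/2-")
    system = parameterize(assign_redox_site(
        partition_segments(read_structure(mini_pdb), "A", library), entry))
    return system, entry


class TestBuildStates:
    def test_invariants_hold(self, prepared):
        system, entry = prepared
        states = build_states(system, entry)
        states.validate()

    def test_redox_segment_charges_differ_only(self, prepared):
        system, entry = prepared
        states = build_states(system, entry)
        for ao, ar in zip(states.protein_ox.atoms, states.protein_red.atoms):
            assert np.allclose(ao.coords, ar.coords)
            if ao.segment_id != "a-bad":
                assert ao.charge == ar.charge

    def test_total_charges_match_formal_states(self, prepared):
        system, entry = prepared
        states = build_states(system, entry)
        # protein net 0, sulfate -2, site -1 (ox) / -2 (red)
        assert states.protein_ox.total_charge() == pytest.approx(-3, abs=1e-3)
        assert states.protein_red.total_charge() == pytest.approx(-4,
                                                                  abs=1e-3)
        assert states.reference_ox.total_charge() == pytest.approx(
            entry.couple[0], abs=1e-3)
        assert states.reference_red.total_charge() == pytest.approx(
            entry.couple[1], abs=1e-3)

    def test_reference_is_exactly_the_redox_segment(self, prepared):
        system, entry = prepared
        states = build_states(system, entry)
        site = [a for a in states.protein_ox.atoms
                if a.segment_id == "a-bad"]
        assert len(site) == len(states.reference_ox.atoms)
        for a, b in zip(site, states.reference_ox.atoms):
            assert a.atom_name == b.atom_name
            assert np.array_equal(a.coords, b.coords)
            assert a.charge == b.charge

    def test_site_residue_renamed_per_state(self, prepared):
        system, entry = prepared
        states = build_states(system, entry)
        ox_names = {a.residue_name for a in states.protein_ox.atoms
                    if a.segment_id == "a-bad" and a.residue_id == 101}
        red_names = {a.residue_name for a in states.protein_red.atoms
                     if a.segment_id == "a-bad" and a.residue_id == 101}
        assert ox_names == {entry.state_resnames["ox"]}
        assert red_names == {entry.state_resnames["red"]}

    def test_unmatched_site_atom_raises(self, prepared):
        system, entry = prepared
        broken = system.copy()
        for a in broken.atoms:
            if a.segment_id == "a-bad" and a.atom_name == "FE1":
                a.atom_name = "FEX"
        with pytest.raises(CompositionError):
            build_states(broken, entry)

    def test_deterministic(self, prepared):
        system, entry = prepared
        s1 = build_states(system, entry)
        s2 = build_states(system, entry)
        for a, b in zip(s1.protein_red.atoms, s2.protein_red.atoms):
            assert a.atom_name == b.atom_name and a.charge == b.charge
            assert np.array_equal(a.coords, b.coords)
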