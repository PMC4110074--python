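"""Segment partitioning, redox-site assembly and cycle-state building."""

from __future__ import annotations

import logging

import numpy as np

from ..library import RedoxEntry, site_residue_names
from .records import (AtomRecord, FourStates, RedoxState, SegmentedSystem,
                      StructureError, BACKBONE_ATOMS, ROLE_PROTEIN,
                      ROLE_GOOD_HET, ROLE_REDOX)
from .templates import load_registry, place_hydrogens

logger = logging.getLogger(__name__)

__all__ = ["partition_segments", "assign_redox_site", "build_states",
           "CompositionError", "LIGAND_BOND_CUTOFF", "GOOD_HET_PARAMS"]

#: Distance defining "directly bonded to a cofactor heteroatom" (A).
#: Covers Fe-S coordination (~2.3 A) while excluding nonbonded contacts.
LIGAND_BOND_CUTOFF = 2.6

WATER_NAMES = {"HOH", "WAT", "TIP3", "H2O", "DOD"}

#: Charges (e) and radii (A) for heteroatoms found in standard
#: parameter sets.  Multi-atom entries map atom name -> (charge, radius).
GOOD_HET_PARAMS = {
    "SO4": {"S": 1.1, "O1": -0.775, "O2": -0.775, "O3": -0.775,
            "O4": -0.775},
    "CL": {"CL": (-1.0, 2.27)},
    "NA": {"NA": (1.0, 1.36)},
    "K": {"K": (1.0, 1.76)},
    "MG": {"MG": (2.0, 1.19)},
    "ZN": {"ZN": (2.0, 1.09)},
    "CA": {"CA": (2.0, 1.71)},
}
_SO4_RADII = {"S": 2.0, "O1": 1.7, "O2": 1.7, "O3": 1.7, "O4": 1.7}


class CompositionError(StructureError):
    """Assembled redox site does not match the library entry."""


def _good_het_param(resname, atom_name):
    table = GOOD_HET_PARAMS.get(resname.upper())
    if table is None:
        return None
    val = table.get(atom_name.upper())
    if val is None:
        return None
    if isinstance(val, tuple):
        return val
    return (val, _SO4_RADII.get(atom_name.upper(), 1.7))


def partition_segments(raw: SegmentedSystem, monomer: str,
                       library, keep_waters: bool = False) -> SegmentedSystem:
    """Split raw atoms into protein / good-het / redox-site segments.

    Only atoms of the selected ``monomer`` chain are kept (crystals often
    hold several copies in the asymmetric unit).  Amino-acid residues
    go to the ``<m>-pro`` segment; heteroatom residues named in the
    redox ``library`` go to ``<m>-bad``; other recognized heteroatoms go
    to ``<m>-het``; waters are discarded unless ``keep_waters``; unknown
    heteroatoms are dropped with a warning and reported.
    """
    monomer = (monomer or "A").strip()
    chains = {a.segment_id for a in raw.atoms}
    if monomer not in chains:
        raise StructureError(
            f"monomer {monomer!r} not in structure (chains: "
            f"{sorted(chains)})")
    registry = load_registry()
    site_names = site_residue_names(library)
    aa_names = set(registry.names()) | {"HIS"}

    m = monomer.lower()
    seg_pro, seg_bad, seg_het = f"{m}-pro", f"{m}-bad", f"{m}-het"
    atoms = []
    discarded = {"waters": 0, "other_monomers": 0, "unknown_het": {}}
    for a in raw.atoms:
        if a.segment_id != monomer:
            discarded["other_monomers"] += 1
            continue
        rn = a.residue_name.upper()
        b = a.copy()
        if rn in aa_names:
            b.segment_id = seg_pro
        elif rn in site_names:
            b.segment_id = seg_bad
        elif rn in WATER_NAMES:
            if keep_waters:
                # crystal waters carry no hydrogens; kept as neutral
                # dielectric-displacing spheres
                b.segment_id = seg_het
                b.charge, b.radius = 0.0, 1.7
            else:
                discarded["waters"] += 1
                continue
        elif rn in GOOD_HET_PARAMS:
            b.segment_id = seg_het
            param = _good_het_param(rn, b.atom_name)
            if param is not None:
                b.charge, b.radius = param
        else:
            discarded["unknown_het"][rn] = \
                discarded["unknown_het"].get(rn, 0) + 1
            logger.warning("unknown heteroatom residue %s %d excluded",
                           rn, a.residue_id)
            continue
        atoms.append(b)

    roles = {seg_pro: ROLE_PROTEIN}
    if any(a.segment_id == seg_bad for a in atoms):
        roles[seg_bad] = ROLE_REDOX
    if any(a.segment_id == seg_het for a in atoms):
        roles[seg_het] = ROLE_GOOD_HET
    return SegmentedSystem(atoms=atoms, segment_roles=roles, monomer=monomer,
                           discard_report=discarded)


def assign_redox_site(system: SegmentedSystem,
                      entry: RedoxEntry) -> SegmentedSystem:
    """Move ligating side chains into the redox segment.

    A protein residue ligates the cofactor when any of its atoms lies
    within :data:`LIGAND_BOND_CUTOFF` of a cofactor heteroatom.  Its
    side-chain atoms named in the entry's ligand spec are reassigned to
    the redox segment (hydrogens built from ideal geometry if absent);
    remaining side-chain atoms not in the spec are dropped (thiolate
    ligation removes HG1).  The assembled site must match the entry's
    atom composition.
    """
    out = system.copy()
    bad_segs = out.segments_with_role(ROLE_REDOX)
    if not bad_segs:
        raise CompositionError("no redox segment present; nothing to assign")
    bad_seg = bad_segs[0]
    cofactor = [a for a in out.atoms if a.segment_id == bad_seg]
    if not cofactor:
        raise CompositionError("redox segment is empty")
    cof_xyz = np.array([a.coords for a in cofactor])

    if entry.ligand is not None:
        registry = load_registry()
        lig_tmpl = registry.get(entry.ligand.residue)
        lig_atom_names = {s.name for s in entry.ligand.atoms}
        found = []
        for (seg, rid, rname), atoms in out.residues(role=ROLE_PROTEIN):
            xyz = np.array([a.coords for a in atoms])
            d = np.sqrt(((xyz[:, None, :] - cof_xyz[None, :, :]) ** 2)
                        .sum(-1))
            if d.min() <= LIGAND_BOND_CUTOFF:
                found.append((seg, rid, rname, atoms))
        wrong = [(r, n) for (_, r, n, _) in found
                 if n.upper() not in (entry.ligand.residue.upper(), "CYS")]
        if wrong or len(found) != entry.ligand.count:
            raise CompositionError(
                f"expected {entry.ligand.count} {entry.ligand.residue} "
                f"ligand(s), found "
                f"{[(n, r) for (_, r, n, _) in found]}")
        dropped = []
        for seg, rid, rname, atoms in found:
            coords = {a.atom_name: a.coords for a in atoms
                      if not a.is_hydrogen}
            site_h = [n for n in lig_atom_names
                      if n in lig_tmpl.hydrogen_atoms()]
            built = place_hydrogens(lig_tmpl, coords, site_h) \
                if site_h else {}
            new_res_atoms = []
            for a in atoms:
                name = a.atom_name
                if a.is_hydrogen:
                    # all input hydrogens are rebuilt with template names
                    continue
                if name in lig_atom_names:
                    a.segment_id = bad_seg
                    new_res_atoms.append(a)
                elif name.upper() in BACKBONE_ATOMS:
                    new_res_atoms.append(a)
                else:
                    # side-chain leftovers outside the site spec (e.g.
                    # the thiol HG1 lost upon metal ligation)
                    dropped.append((rid, name))
            for name, xyz in built.items():
                new_res_atoms.append(AtomRecord(
                    atom_name=name, element="H", residue_name=rname,
                    residue_id=rid, segment_id=bad_seg,
                    coords=np.asarray(xyz, dtype=float)))
            # splice the residue back in place
            atom_ids = {id(x) for x in atoms}
            rebuilt = []
            done = False
            for a in out.atoms:
                if id(a) in atom_ids:
                    if not done:
                        rebuilt.extend(new_res_atoms)
                        done = True
                    continue
                rebuilt.append(a)
            out.atoms = rebuilt
            out.ligating.add((seg, rid))
        if dropped:
            out.discard_report["ligand_side_chain"] = dropped

    _check_composition(out, entry, bad_seg)
    return out


def _check_composition(system, entry, bad_seg):
    counts = {}
    for a in system.atoms:
        if a.segment_id == bad_seg:
            counts[a.atom_name] = counts.get(a.atom_name, 0) + 1
    expected = entry.composition()
    if counts != expected:
        missing = {k: v for k, v in expected.items()
                   if counts.get(k, 0) != v}
        surplus = {k: v for k, v in counts.items()
                   if expected.get(k, 0) != v}
        raise CompositionError(
            f"site composition mismatch; expected counts {missing}, "
            f"found {surplus}")


def build_states(system: SegmentedSystem, entry: RedoxEntry) -> FourStates:
    """Build the four parameterized systems of the thermodynamic cycle.

    The two protein systems share coordinates and differ only in the
    redox-segment charges; the reference systems are the redox segment
    alone.  The cofactor residue is renamed per oxidation state.
    """
    bad_segs = system.segments_with_role(ROLE_REDOX)
    if not bad_segs:
        raise CompositionError(
            "system has no redox segment; cannot build cycle states")
    bad_seg = bad_segs[0]
    _check_composition(system, entry, bad_seg)
    site_names_upper = {n.upper() for n in entry.site_names}

    def one_state(state: str) -> SegmentedSystem:
        charge_map = entry.atom_charge_map(state)
        resname = entry.state_resnames[state]
        st = system.copy()
        unmatched = []
        for a in st.atoms:
            if a.segment_id != bad_seg:
                continue
            if a.atom_name not in charge_map:
                unmatched.append(a.atom_name)
                continue
            a.charge, a.radius = charge_map[a.atom_name]
            if a.residue_name.upper() in site_names_upper or \
                    a.residue_name in entry.state_resnames.values():
                a.residue_name = resname
        if unmatched:
            raise CompositionError(
                f"site atoms not in library entry: {sorted(set(unmatched))}")
        return st

    protein_ox = one_state("ox")
    protein_red = one_state("red")

    def reference(protein: SegmentedSystem) -> SegmentedSystem:
        ref_atoms = [a.copy() for a in protein.atoms
                     if a.segment_id == bad_seg]
        return SegmentedSystem(atoms=ref_atoms,
                               segment_roles={bad_seg: ROLE_REDOX},
                               monomer=protein.monomer)

    states = FourStates(
        protein_ox=protein_ox,
        protein_red=protein_red,
        reference_ox=reference(protein_ox),
        reference_red=reference(protein_red),
        state_ox=RedoxState("oxidized", entry.couple[0]),
        state_red=RedoxState("reduced", entry.couple[1]),
    )
    return states.validate()
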