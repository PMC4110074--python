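"""Structure file I/O: PDB reading (via Biopython) and PQR round-trip.

PQR is the PDB-like format carrying per-atom charge and radius in place
of occupancy/B-factor.  The writer emits whitespace-separated columns
with the segment id in a trailing column; the reader accepts exactly
that dialect (files produced by this package).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .records import AtomRecord, SegmentedSystem, StructureError

__all__ = ["read_structure", "write_pqr", "read_pqr",
           "PDBReadError", "EmptyStructureError"]


class PDBReadError(StructureError):
    pass


class EmptyStructureError(PDBReadError):
    pass


def read_structure(path) -> SegmentedSystem:
    """Parse a PDB file into a raw (unpartitioned) system.

    All ATOM/HETATM records of the first model are read; alternate
    locations are resolved to the highest-occupancy conformer (ties go
    to the first in file); chains are preserved as segment ids.
    """
    path = Path(path)
    if not path.exists():
        raise PDBReadError(f"no such file: {path}")
    with open(path, errors="replace") as fh:
        if not any(line.startswith(("ATOM", "HETATM")) for line in fh):
            raise EmptyStructureError(f"{path} holds no ATOM/HETATM records")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("structure", str(path))
    except Exception as exc:
        raise PDBReadError(f"cannot parse {path}: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise EmptyStructureError(f"{path} holds no coordinates")
    model = models[0]

    atoms = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.get_id()
            # pick one conformer per atom name: highest occupancy,
            # ties resolved by file order
            best = {}
            for atom in residue.get_unpacked_list():
                name = atom.get_name().strip()
                occ = atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                if name not in best or occ > best[name][0] + 1e-12:
                    best[name] = (occ, atom)
            for name, (occ, atom) in best.items():
                element = (atom.element or "").strip() or name[0]
                atoms.append(AtomRecord(
                    atom_name=name,
                    element=element.capitalize(),
                    residue_name=residue.get_resname().strip(),
                    residue_id=int(resseq),
                    segment_id=chain.id.strip() or "A",
                    coords=np.asarray(atom.get_coord(), dtype=float),
                    occupancy=occ,
                    altloc=(atom.get_altloc() or "").strip(),
                ))
    if not atoms:
        raise EmptyStructureError(f"{path} holds no ATOM/HETATM records")
    return SegmentedSystem(atoms=atoms)


def write_pqr(system: SegmentedSystem, path):
    """Write a parameterized system as PQR (trailing segid column)."""
    with open(path, "w") as fh:
        fh.write("REMARK generated by redoxpot; columns: "
                 "serial name resname resid x y z charge radius segid\n")
        serial = 0
        for a in system.atoms:
            if a.charge is None or a.radius is None:
                raise StructureError(
                    f"atom {a.atom_name} of {a.residue_name}{a.residue_id} "
                    "lacks charge/radius; parameterize first")
            serial += 1
            fh.write(
                f"ATOM  {serial:>5d} {a.atom_name:<4s} {a.residue_name:<4s} "
                f"{a.residue_id:>4d}    "
                f"{a.coords[0]:10.4f}{a.coords[1]:10.4f}{a.coords[2]:10.4f} "
                f"{a.charge:8.4f} {a.radius:7.4f} {a.segment_id}\n")
        fh.write("END\n")


def read_pqr(path) -> SegmentedSystem:
    """Read a PQR file produced by :func:`write_pqr`."""
    atoms = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise PDBReadError(f"malformed PQR line: {line.rstrip()}")
            (_, _serial, name, resname, resid,
             x, y, z, charge, radius) = parts[:10]
            segid = parts[10] if len(parts) > 10 else "A"
            atoms.append(AtomRecord(
                atom_name=name,
                element=_pqr_element(name),
                residue_name=resname,
                residue_id=int(resid),
                segment_id=segid,
                coords=np.array([float(x), float(y), float(z)]),
                charge=float(charge),
                radius=float(radius),
            ))
    if not atoms:
        raise EmptyStructureError(f"{path} holds no ATOM records")
    return SegmentedSystem(atoms=atoms)


def _pqr_element(name):
    from .templates import element_of
    return element_of(name)
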