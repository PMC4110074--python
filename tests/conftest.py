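"""Shared fixtures: synthetic PDB structures built from ideal geometry.

The miniature [4Fe-4S] protein below has a cubane cofactor, four
cysteines whose SG atoms sit at bonding distance from the irons, a
histidine, sensible termini, plus the partition edge cases (second
chain, sulfate, waters, altlocs).  Everything is generated at test time;
no external data is read.
"""

import math

import numpy as np
import pytest

from redoxpot.library import load_library
from redoxpot.pb.grids import PBParams


# ---------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------

def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp_basis(d):
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(d, ref))
    e2 = _unit(np.cross(d, e1))
    return e1, e2


def _tetra_dirs(d, e1, e2):
    """Three unit vectors completing a tetrahedron around direction d."""
    out = []
    for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
        out.append(_unit(-d / 3 + (2 * math.sqrt(2) / 3)
                         * (math.cos(phi) * e1 + math.sin(phi) * e2)))
    return out


def backbone(ca, side_dir):
    """Heavy backbone atoms (N, C, O) for a CA and side-chain direction."""
    d = _unit(side_dir)
    e1, e2 = _perp_basis(d)
    t0, t1, _ = _tetra_dirs(d, e1, e2)
    n = ca + 1.46 * t0
    c = ca + 1.52 * t1
    o = c + 1.24 * _unit(_unit(c - ca) + 0.9 * e2)
    return n, c, o


def residue_atoms(restype, ca, side_dir):
    """Heavy atoms of one residue as (name, xyz) pairs."""
    d = _unit(side_dir)
    e1, e2 = _perp_basis(d)
    n, c, o = backbone(ca, d)
    atoms = [("N", n), ("CA", ca), ("C", c), ("O", o)]
    if restype == "GLY":
        return atoms
    cb = ca + 1.53 * d
    atoms.insert(2, ("CB", cb))
    d2 = _unit(math.cos(0.5) * d + math.sin(0.5) * e1)
    if restype == "ALA":
        pass
    elif restype == "SER":
        atoms.append(("OG", cb + 1.42 * d2))
    elif restype == "CYS":
        atoms.append(("SG", cb + 1.81 * d2))
    elif restype == "ASP":
        cg = cb + 1.50 * d2
        e3 = _unit(np.cross(d2, e2))
        atoms.append(("CG", cg))
        atoms.append(("OD1", cg + 1.25 * _unit(d2 + 1.2 * e3)))
        atoms.append(("OD2", cg + 1.25 * _unit(d2 - 1.2 * e3)))
    elif restype == "HIS":
        cg = cb + 1.50 * d2
        atoms.append(("CG", cg))
        ring_r = 1.37 / (2 * math.sin(math.pi / 5))
        a = d2
        b = _unit(e2 - np.dot(e2, a) * a)
        center = cg + ring_r * a
        names = ["ND1", "CE1", "NE2", "CD2"]
        for k, name in enumerate(names, start=1):
            theta = math.pi - k * 2 * math.pi / 5
            atoms.append((name, center + ring_r * (math.cos(theta) * a
                                                   + math.sin(theta) * b)))
    else:
        raise ValueError(restype)
    return atoms


def sf4_cube(half=1.13):
    """Cubane [4Fe-4S] heavy atoms; Fe-S neighbours at 2*half A."""
    fe = {"FE1": (half, half, half), "FE2": (half, -half, -half),
          "FE3": (-half, half, -half), "FE4": (-half, -half, half)}
    s = {"S1": (-half, -half, -half), "S2": (-half, half, half),
         "S3": (half, -half, half), "S4": (half, half, -half)}
    return {k: np.array(v, dtype=float) for k, v in {**fe, **s}.items()}


def build_mini_protein():
    """Atom records for the miniature [4Fe-4S] protein (chain A).

    Returns a list of dicts accepted by :func:`write_pdb`.
    """
    atoms = []

    def add(name, resname, resid, xyz, chain="A", occ=1.0, altloc="",
            element=None):
        if element is None:
            element = "FE" if name.startswith("FE") else name[0]
        atoms.append(dict(name=name, resname=resname, chain=chain,
                          resid=resid, xyz=np.asarray(xyz, dtype=float),
                          occ=occ, altloc=altloc, element=element))

    cube = sf4_cube()

    # four cysteines, SG 2.3 A outward from each Fe
    cys_ids = (2, 3, 5, 6)
    for rid, fe_name in zip(cys_ids, ("FE1", "FE2", "FE3", "FE4")):
        f = _unit(cube[fe_name])
        e1, _ = _perp_basis(f)
        sg = cube[fe_name] + 2.3 * f
        cb = sg + 1.81 * _unit(f + 0.35 * e1)
        ca = cb + 1.53 * _unit(f - 0.25 * e1)
        d_side = _unit(cb - ca)
        n, c, o = backbone(ca, d_side)
        for name, xyz in (("N", n), ("CA", ca), ("CB", cb), ("SG", sg),
                          ("C", c), ("O", o)):
            add(name, "CYS", rid, xyz)

    # remaining residues on a wider shell
    others = [
        (1, "ALA", np.array([9.0, 0.5, 0.5]), np.array([-1.0, 0.0, 0.2])),
        (4, "GLY", np.array([-9.0, 0.5, -0.5]), np.array([1.0, 0.1, 0.0])),
        (42, "HIS", np.array([0.5, 9.5, 0.5]), np.array([0.0, -1.0, 0.1])),
        (50, "SER", np.array([0.5, -9.0, 0.8]), np.array([0.1, 1.0, 0.0])),
    ]
    for rid, restype, ca, toward in others:
        for name, xyz in residue_atoms(restype, ca, toward):
            add(name, restype, rid, xyz)

    # cofactor (HETATM block)
    for name, xyz in cube.items():
        add(name, "SF4", 101, xyz)

    # a sulfate, two waters, and a second-chain residue
    s0 = np.array([0.0, 0.0, 12.0])
    add("S", "SO4", 201, s0)
    for i, v in enumerate([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                          start=1):
        add(f"O{i}", "SO4", 201, s0 + 1.49 * _unit(v))
    add("O", "HOH", 301, [12.0, 0.0, 0.0])
    add("O", "HOH", 302, [0.0, 12.0, 0.0])
    for name, xyz in residue_atoms("ALA", np.array([20.0, 20.0, 20.0]),
                                   np.array([1.0, 0.0, 0.0])):
        add(name, "ALA", 1, xyz, chain="B")
    # sequence order within each chain, protein before heteroatoms
    atoms.sort(key=lambda a: (a["chain"],
                              a["resname"] in ("SF4", "SO4", "HOH"),
                              a["resid"]))
    return atoms


def write_pdb(atoms, path):
    """Write atom dicts in fixed-column PDB format."""
    with open(path, "w") as fh:
        serial = 0
        for a in atoms:
            serial += 1
            record = "HETATM" if a["resname"] in ("SF4", "SO4", "HOH") \
                else "ATOM"
            name = a["name"]
            if len(name) < 4 and len(a["element"]) == 1:
                name_field = f" {name:<3s}"
            else:
                name_field = f"{name:<4s}"
            x, y, z = a["xyz"]
            fh.write(
                f"{record:<6s}{serial:>5d} {name_field}{a['altloc'] or ' ':1s}"
                f"{a['resname']:>3s} {a['chain']:1s}{a['resid']:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a['occ']:6.2f}{0.0:6.2f}"
                f"          {a['element']:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------

@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def mini_pdb(tmp_path_factory):
    """Path to the miniature [4Fe-4S] protein PDB."""
    path = tmp_path_factory.mktemp("structures") / "mini4fe4s.pdb"
    write_pdb(build_mini_protein(), path)
    return path


@pytest.fixture(scope="session")
def altloc_pdb(tmp_path_factory):
    """Three-residue GLY chain; residue 2 CA has two conformers."""
    path = tmp_path_factory.mktemp("structures") / "altloc.pdb"
    atoms = []
    for rid in (1, 2, 3):
        ca = np.array([3.8 * rid, 0.0, 0.0])
        for name, xyz in residue_atoms("GLY", ca, np.array([0.0, 1.0, 0.0])):
            if rid == 2 and name == "CA":
                atoms.append(dict(name=name, resname="GLY", chain="A",
                                  resid=rid, xyz=xyz, occ=0.4, altloc="A",
                                  element="C"))
                atoms.append(dict(name=name, resname="GLY", chain="A",
                                  resid=rid, xyz=xyz + [0.5, 0, 0], occ=0.6,
                                  altloc="B", element="C"))
                continue
            atoms.append(dict(name=name, resname="GLY", chain="A", resid=rid,
                              xyz=xyz, occ=1.0, altloc="", element=name[0]))
    write_pdb(atoms, path)
    return path


@pytest.fixture(scope="session")
def twelve_atom_pdb(tmp_path_factory):
    """Exactly 12 ATOM records (three glycines)."""
    path = tmp_path_factory.mktemp("structures") / "twelve.pdb"
    atoms = []
    for rid in (1, 2, 3):
        ca = np.array([3.8 * rid, 0.0, 0.0])
        for name, xyz in residue_atoms("GLY", ca, np.array([0.0, 1.0, 0.0])):
            atoms.append(dict(name=name, resname="GLY", chain="A", resid=rid,
                              xyz=xyz, occ=1.0, altloc="", element=name[0]))
    write_pdb(atoms, path)
    return path


@pytest.fixture()
def fast_params():
    """Coarse-but-quick PB parameters for pipeline tests."""
    return PBParams(spacing_fine=0.6, eps_solvent=78.54, padding=12.0,
                    spacing_coarse=1.2)
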