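"""Residue templates: charges, radii, connectivity, hydrogen building.

Charges follow the CHARMM36 protein residue topology; radii are vdW
Rmin/2 values.  Hydrogens absent from the input structure (crystal
structures usually carry none) are rebuilt from ideal local geometry:
tetrahedral/trigonal placement with staggered orientations for
rotatable groups.  Input hydrogens are discarded and rebuilt so that
naming and charges always match the template.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .records import (AtomRecord, SegmentedSystem, StructureError,
                      ROLE_PROTEIN)

__all__ = ["ResidueTemplate", "TemplateRegistry", "load_registry",
           "ParameterizationError", "parameterize", "apply_template",
           "place_hydrogens", "DEFAULT_TEMPLATE_FOR", "TITRATION_GROUPS"]


class ParameterizationError(StructureError):
    pass


#: Residue-name -> default template at pH 7 (standard charge states).
DEFAULT_TEMPLATE_FOR = {
    "HIS": "HSD",   # neutral delta tautomer unless overridden
    "HSD": "HSD", "HSE": "HSE", "HSP": "HSP",
    "ASP": "ASP", "GLU": "GLU", "LYS": "LYS", "ARG": "ARG", "CYS": "CYS",
}

#: Valid protonation-state labels per titratable residue family.
TITRATION_GROUPS = {
    "HIS": ("HSD", "HSE", "HSP"),
    "HSD": ("HSD", "HSE", "HSP"),
    "HSE": ("HSD", "HSE", "HSP"),
    "HSP": ("HSD", "HSE", "HSP"),
    "ASP": ("ASP", "ASPP"),
    "ASPP": ("ASP", "ASPP"),
    "GLU": ("GLU", "GLUP"),
    "GLUP": ("GLU", "GLUP"),
    "LYS": ("LYS", "LSN"),
    "LSN": ("LYS", "LSN"),
    "CYS": ("CYS", "CYSM"),
    "CYSM": ("CYS", "CYSM"),
}

# terminal patches: charge overrides and extra hydrogens (name, parent,
# charge, radius).  NTER-style patches drop the amide HN.
NTER_PATCH = {
    "charges": {"N": -0.30, "CA": 0.21, "HA": 0.10},
    "add_h": [("HT1", "N", 0.33, 0.2245), ("HT2", "N", 0.33, 0.2245),
              ("HT3", "N", 0.33, 0.2245)],
    "remove": ["HN"],
}
GLYP_PATCH = {
    "charges": {"N": -0.30, "CA": 0.13, "HA1": 0.09, "HA2": 0.09},
    "add_h": [("HT1", "N", 0.33, 0.2245), ("HT2", "N", 0.33, 0.2245),
              ("HT3", "N", 0.33, 0.2245)],
    "remove": ["HN"],
}
PROP_PATCH = {
    "charges": {"N": -0.07, "CA": 0.16, "HA": 0.09, "CD": 0.16,
                "HD1": 0.09, "HD2": 0.09},
    "add_h": [("HN1", "N", 0.24, 0.2245), ("HN2", "N", 0.24, 0.2245)],
    "remove": [],
}
CTER_PATCH = {
    "charges": {"C": 0.34, "OT1": -0.67, "OT2": -0.67},
}

_H_BOND_LENGTH = {"C": 1.09, "N": 1.00, "O": 0.96, "S": 1.34}


def element_of(atom_name: str) -> str:
    """Best-effort element from a template/PDB atom name."""
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("FE", "ZN", "MG", "NA", "CL", "BR", "MN", "CU",
                            "CO", "NI", "SE"):
        return name[:2].capitalize()
    return name[0].upper()


@dataclass
class ResidueTemplate:
    name: str
    atoms: dict          # name -> (charge, radius), insertion-ordered
    bonds: set           # frozenset pairs

    def neighbors(self, atom: str) -> list:
        out = []
        for b in self.bonds:
            if atom in b:
                (other,) = set(b) - {atom}
                out.append(other)
        # deterministic order: template atom order
        order = {n: i for i, n in enumerate(self.atoms)}
        return sorted(out, key=lambda n: order.get(n, 99))

    def heavy_atoms(self) -> list:
        return [n for n in self.atoms if element_of(n) != "H"]

    def hydrogen_atoms(self) -> list:
        return [n for n in self.atoms if element_of(n) == "H"]

    def net_charge(self) -> float:
        return sum(q for q, _ in self.atoms.values())


class TemplateRegistry:
    def __init__(self, residues: dict):
        self.residues = residues

    def __contains__(self, name):
        return name.upper() in self.residues

    def get(self, name: str) -> ResidueTemplate:
        key = name.upper()
        if key not in self.residues:
            raise ParameterizationError(
                f"no residue template named {name!r}")
        return self.residues[key]

    def names(self):
        return list(self.residues)


_REGISTRY = None


def load_registry() -> TemplateRegistry:
    """Load (and cache) the shipped residue template registry."""
    global _REGISTRY
    if _REGISTRY is None:
        path = importlib.resources.files("redoxpot.data") / \
            "protein_templates.yaml"
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        residues = {}
        for name, doc in raw["residues"].items():
            atoms = {a[0]: (float(a[1]), float(a[2])) for a in doc["atoms"]}
            bonds = {frozenset(b) for b in doc["bonds"]}
            residues[name.upper()] = ResidueTemplate(name.upper(), atoms, bonds)
        _REGISTRY = TemplateRegistry(residues)
    return _REGISTRY


# ----------------------------------------------------------------------
# hydrogen geometry
# ----------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ParameterizationError("degenerate geometry while placing H")
    return v / n


def _any_perpendicular(v):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def place_hydrogens(template: ResidueTemplate, coords: dict, h_names,
                    extra_neighbors: dict | None = None,
                    bond_overrides: dict | None = None) -> dict:
    """Ideal-geometry positions for the requested hydrogens.

    Parameters
    ----------
    coords : dict
        Known atom positions (name -> 3-vector), heavy atoms at least.
    h_names : iterable
        Hydrogen names (template members or patch additions via
        ``bond_overrides``).
    extra_neighbors : dict, optional
        Extra heavy neighbours outside the residue, e.g.
        ``{"N": [prev_C_coords]}`` for the backbone amide.
    bond_overrides : dict, optional
        H name -> parent name for hydrogens absent from the template
        (terminal patch hydrogens).
    """
    extra_neighbors = extra_neighbors or {}
    bond_overrides = bond_overrides or {}
    out = {}
    h_names = list(h_names)

    # group hydrogens by parent so multi-H groups are placed together
    by_parent = {}
    for h in h_names:
        parent = bond_overrides.get(h)
        if parent is None:
            nbs = [n for n in template.neighbors(h)]
            if len(nbs) != 1:
                raise ParameterizationError(f"hydrogen {h} lacks unique parent")
            parent = nbs[0]
        by_parent.setdefault(parent, []).append(h)

    for parent, hs in by_parent.items():
        if parent not in coords:
            raise ParameterizationError(
                f"cannot place {hs}: parent {parent} has no coordinates")
        p = np.asarray(coords[parent], dtype=float)
        elem = element_of(parent)
        length = _H_BOND_LENGTH.get(elem, 1.09)
        heavy_nbs = []
        if parent in template.atoms:
            for n in template.neighbors(parent):
                if element_of(n) != "H" and n in coords:
                    heavy_nbs.append(np.asarray(coords[n], dtype=float))
        for extra in extra_neighbors.get(parent, []):
            heavy_nbs.append(np.asarray(extra, dtype=float))
        n_h = len(hs)
        units = [_unit(nb - p) for nb in heavy_nbs]

        if len(units) >= 3 and n_h == 1:
            d = -_unit(np.sum(units, axis=0))
            out[hs[0]] = p + length * d
        elif len(units) == 2 and n_h == 1:
            d = -_unit(units[0] + units[1])
            out[hs[0]] = p + length * d
        elif len(units) == 2 and n_h == 2:
            b = -_unit(units[0] + units[1])
            perp = _unit(np.cross(units[0], units[1]))
            alpha = np.deg2rad(54.75)
            out[hs[0]] = p + length * (np.cos(alpha) * b + np.sin(alpha) * perp)
            out[hs[1]] = p + length * (np.cos(alpha) * b - np.sin(alpha) * perp)
        elif len(units) == 1:
            axis = -units[0]  # points away from the heavy neighbour
            ref = _reference_direction(template, parent, coords,
                                       heavy_nbs[0], extra_neighbors)
            if ref is None:
                e1 = _any_perpendicular(axis)
            else:
                rv = ref - heavy_nbs[0]
                e1 = rv - np.dot(rv, axis) * axis
                norm = np.linalg.norm(e1)
                e1 = _any_perpendicular(axis) if norm < 1e-6 else e1 / norm
            e2 = _unit(np.cross(axis, e1))
            if n_h == 2 and elem == "N":
                # planar amide/guanidinium NH2: both H in the reference plane
                theta = np.deg2rad(60.0)
                for h, sign in zip(hs, (1.0, -1.0)):
                    d = _unit(np.cos(theta) * axis + sign * np.sin(theta) * e1)
                    out[h] = p + length * d
            else:
                # staggered sp3 group (CH3, NH3+, OH, SH): anti first
                theta = np.deg2rad(70.53)
                phis = {1: (180.0,), 2: (180.0, 60.0),
                        3: (180.0, 60.0, -60.0)}[n_h]
                for h, phi in zip(hs, phis):
                    a = np.deg2rad(phi)
                    d = _unit(np.cos(theta) * axis
                              + np.sin(theta) * (np.cos(a) * e1
                                                 + np.sin(a) * e2))
                    out[h] = p + length * d
        else:
            raise ParameterizationError(
                f"unsupported hydrogen environment at {parent} "
                f"({len(units)} heavy neighbours, {n_h} H)")
    return out


def _reference_direction(template, parent, coords, nb_coord, extra_neighbors):
    """Coordinates of a reference atom bonded to the parent's neighbour,
    used to fix the dihedral of staggered/planar groups."""
    nb_name = None
    if parent in template.atoms:
        for n in template.neighbors(parent):
            if element_of(n) != "H" and n in coords and \
                    np.allclose(coords[n], nb_coord):
                nb_name = n
                break
    if nb_name is None:
        return None
    for cand in template.neighbors(nb_name):
        if cand != parent and cand in coords and element_of(cand) != "H":
            return np.asarray(coords[cand], dtype=float)
    return None


# ----------------------------------------------------------------------
# residue parameterization
# ----------------------------------------------------------------------

def apply_template(residue_atoms, template: ResidueTemplate, *,
                   nter=False, cter=False, prev_c=None,
                   keep_heavy_extras=(), extra_h_neighbors=None) -> list:
    """Re-parameterize one residue against a template.

    Heavy atoms keep their coordinates; charges/radii are (re)assigned;
    existing hydrogens are dropped and rebuilt; terminal patches are
    applied when requested.  Returns the new atom list in template
    order.

    Raises
    ------
    ParameterizationError
        On missing or unexpected heavy atoms.
    """
    base = residue_atoms[0]
    heavy = {}
    for a in residue_atoms:
        if a.is_hydrogen:
            continue
        name = a.atom_name.upper()
        if cter and name == "OXT":
            name = "OT2"
        if cter and name == "O":
            name = "OT1"
        heavy[name] = a

    charges = dict(template.atoms)  # name -> (q, r)
    tmpl_heavy = set(template.heavy_atoms())
    h_names = list(template.hydrogen_atoms())
    bond_overrides = {}
    rename_back = {}

    if cter:
        # carboxy terminus: O -> OT1, add OT2; both carboxylate oxygens
        o_q, o_r = charges.pop("O")
        charges["OT1"] = (CTER_PATCH["charges"]["OT1"], o_r)
        charges["OT2"] = (CTER_PATCH["charges"]["OT2"], o_r)
        charges["C"] = (CTER_PATCH["charges"]["C"], template.atoms["C"][1])
        tmpl_heavy = (tmpl_heavy - {"O"}) | {"OT1", "OT2"}
        rename_back = {"OT1": "OT1", "OT2": "OT2"}
    if nter:
        patch = (GLYP_PATCH if template.name == "GLY"
                 else PROP_PATCH if template.name == "PRO" else NTER_PATCH)
        for name, q in patch["charges"].items():
            if name in charges:
                charges[name] = (q, charges[name][1])
        for h in patch["remove"]:
            if h in charges:
                del charges[h]
                h_names.remove(h)
        for h, parent, q, r in patch["add_h"]:
            charges[h] = (q, r)
            h_names.append(h)
            bond_overrides[h] = parent

    missing = tmpl_heavy - set(heavy)
    buildable = {"OT2"} if cter else set()
    if missing - buildable:
        raise ParameterizationError(
            f"residue {base.residue_name}{base.residue_id}: missing heavy "
            f"atoms {sorted(missing - buildable)}")
    extras = set(heavy) - tmpl_heavy - set(keep_heavy_extras)
    if extras:
        raise ParameterizationError(
            f"residue {base.residue_name}{base.residue_id}: unexpected "
            f"heavy atoms {sorted(extras)} for template {template.name}")

    coords = {n: a.coords for n, a in heavy.items()}
    if cter:
        # template geometry still refers to O
        coords["O"] = coords["OT1"]
        if "OT2" not in coords:
            coords["OT2"] = _build_ot2(coords)

    extra_nb = {k: list(v) for k, v in (extra_h_neighbors or {}).items()}
    if prev_c is not None:
        extra_nb.setdefault("N", []).append(np.asarray(prev_c, dtype=float))
    h_coords = place_hydrogens(template, coords, h_names,
                               extra_neighbors=extra_nb,
                               bond_overrides=bond_overrides)

    new_atoms = []
    order = list(template.atoms)
    for extra_name in ("OT1", "OT2", "HT1", "HT2", "HT3", "HN1", "HN2"):
        if extra_name in charges and extra_name not in order:
            order.append(extra_name)
    if cter:
        order = [n for n in order if n != "O"]
    for name in order:
        if name not in charges:
            continue
        q, r = charges[name]
        if element_of(name) == "H":
            if name not in h_coords:
                continue
            xyz = h_coords[name]
            elem = "H"
        else:
            src = heavy.get(name)
            if src is None and name == "OT2":
                xyz = coords["OT2"]
            else:
                xyz = src.coords
            elem = element_of(name)
        new_atoms.append(AtomRecord(
            atom_name=name, element=elem,
            residue_name=template.name, residue_id=base.residue_id,
            segment_id=base.segment_id, coords=np.asarray(xyz, dtype=float),
            charge=q, radius=r))
    # carry along retained extras (e.g. side-chain atoms owned by the
    # redox segment are never passed in here)
    return new_atoms


def _build_ot2(coords):
    """Place the second carboxylate oxygen of a C-terminus (sp2, in plane)."""
    c = np.asarray(coords["C"], dtype=float)
    ca = np.asarray(coords["CA"], dtype=float)
    o = np.asarray(coords["OT1"], dtype=float)
    u_ca = _unit(ca - c)
    u_o = _unit(o - c)
    d = -_unit(u_ca + u_o)
    return c + 1.25 * d


def parameterize(system: SegmentedSystem, registry=None) -> SegmentedSystem:
    """Assign charges, radii and hydrogens to every protein residue.

    Titration overrides recorded on the system (``overrides``) replace
    the default pH-7 templates.  Ligating residues (side chains owned by
    the redox segment) are parameterized backbone-only.  Good-het atoms
    must already carry charges/radii (set by partitioning).
    """
    registry = registry or load_registry()
    out = system.copy()
    new_atoms = []
    consumed = set()

    residues = out.residues(role=ROLE_PROTEIN)
    prot_segs = set(out.segments_with_role(ROLE_PROTEIN))
    # chain layout: first/last residue per segment
    seg_res = {}
    for (seg, rid, rname), atoms in residues:
        seg_res.setdefault(seg, []).append(rid)

    prev_c_coord = {}
    replacement = {}
    for (seg, rid, rname), atoms in residues:
        tmpl_name = out.overrides.get((seg, rid))
        if tmpl_name is None:
            tmpl_name = DEFAULT_TEMPLATE_FOR.get(rname.upper(), rname.upper())
        template = registry.get(tmpl_name)
        nter = rid == seg_res[seg][0]
        cter = rid == seg_res[seg][-1]
        prev_c = None
        if not nter:
            prev_c = prev_c_coord.get(seg)
        ligating = (seg, rid) in out.ligating
        if ligating:
            cb = [a.coords for a in out.atoms
                  if a.residue_id == rid and a.atom_name == "CB"
                  and out.segment_roles.get(a.segment_id) == "redox-site"]
            new = _parameterize_backbone(atoms, template, nter=nter,
                                         cter=cter, prev_c=prev_c,
                                         cb_coord=cb[0] if cb else None)
        else:
            new = apply_template(atoms, template, nter=nter, cter=cter,
                                 prev_c=prev_c)
        replacement[(seg, rid)] = new
        cs = [a for a in new if a.atom_name == "C"]
        if cs:
            prev_c_coord[seg] = cs[0].coords

    for a in out.atoms:
        key = (a.segment_id, a.residue_id)
        if a.segment_id in prot_segs and key in replacement:
            if key not in consumed:
                consumed.add(key)
                new_atoms.extend(replacement[key])
        else:
            new_atoms.append(a)
    out.atoms = new_atoms
    return out


def reparameterize_residue(system: SegmentedSystem, residue_id: int,
                           segment_id: str, template_name: str,
                           registry=None) -> SegmentedSystem:
    """Re-apply a (possibly different) template to one residue only.

    All other atoms — including any charge edits on them — are left
    untouched, so residue-local edits commute.  Returns a new system.
    """
    registry = registry or load_registry()
    template = registry.get(template_name)
    out = system.copy()
    if (segment_id, residue_id) in out.ligating:
        raise ParameterizationError(
            f"residue {residue_id} ligates the redox site; its side chain "
            "is owned by the redox segment")
    rids = [rid for (seg, rid, _), _ in out.residues()
            if seg == segment_id]
    if residue_id not in rids:
        raise StructureError(
            f"residue {residue_id} not found in segment {segment_id}")
    nter = residue_id == rids[0]
    cter = residue_id == rids[-1]
    prev_c = None
    if not nter:
        prev_rid = rids[rids.index(residue_id) - 1]
        prev_cs = [a.coords for a in out.residue_atoms(prev_rid, segment_id)
                   if a.atom_name == "C"]
        prev_c = prev_cs[0] if prev_cs else None
    atoms = out.residue_atoms(residue_id, segment_id)
    new_atoms = apply_template(atoms, template, nter=nter, cter=cter,
                               prev_c=prev_c)
    atom_ids = {id(a) for a in atoms}
    rebuilt, spliced = [], False
    for a in out.atoms:
        if id(a) in atom_ids:
            if not spliced:
                rebuilt.extend(new_atoms)
                spliced = True
            continue
        rebuilt.append(a)
    out.atoms = rebuilt
    out.overrides[(segment_id, residue_id)] = template.name
    return out


def _parameterize_backbone(atoms, template, *, nter, cter, prev_c,
                           cb_coord=None):
    """Backbone-only parameterization for redox-site-ligating residues.

    The side chain lives in the redox segment; only N/HN/CA/HA/C/O keep
    template charges (a charge-neutral group in CHARMM36).  The CB
    position, when available, steers HA to the correct tetrahedral slot.
    """
    backbone = {"N", "CA", "C", "O", "OXT"}
    kept = [a for a in atoms if a.atom_name.upper() in backbone
            and not a.is_hydrogen]
    stripped = ResidueTemplate(
        name=template.name,
        atoms={n: qr for n, qr in template.atoms.items()
               if n in {"N", "HN", "CA", "HA", "C", "O"}},
        bonds={b for b in template.bonds
               if all(x in {"N", "HN", "CA", "HA", "C", "O"} for x in b)},
    )
    extra = {"CA": [cb_coord]} if cb_coord is not None else None
    return apply_template(kept, stripped, nter=nter, cter=cter, prev_c=prev_c,
                          extra_h_neighbors=extra)
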