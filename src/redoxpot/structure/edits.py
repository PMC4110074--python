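"""Structure edits: protonation states, charge knock-outs, mutations.

All edit functions are pure: they return a modified copy and leave the
input system untouched, so edits on disjoint residues commute trivially.

Selection mini-language
-----------------------
A selection is a whitespace-separated conjunction of clauses::

    selection := clause { clause }
    clause    := "resid" INT [":" INT]     residue id or inclusive range
               | "segid" WORD              segment id (exact, case-insensitive)
               | "name" PATTERN            atom name, fnmatch-style pattern

Examples: ``resid 42``, ``resid 10:20 segid a-pro``, ``name SG``.
"""

from __future__ import annotations

import fnmatch
import re

from .records import SegmentedSystem, StructureError, ROLE_PROTEIN
from .templates import (TITRATION_GROUPS, load_registry,
                        reparameterize_residue)

__all__ = ["SelectionError", "parse_selection", "select_atoms",
           "set_protonation", "knockout_charges", "mutate_residue",
           "UnsupportedMutationError"]


class SelectionError(StructureError):
    pass


class UnsupportedMutationError(StructureError):
    pass


_RESID_RE = re.compile(r"^(-?\d+)(?::(-?\d+))?$")


def parse_selection(text: str):
    """Parse the selection mini-language into a list of clause predicates."""
    tokens = text.split()
    if not tokens:
        return []
    clauses = []
    i = 0
    while i < len(tokens):
        kw = tokens[i].lower()
        if i + 1 >= len(tokens):
            raise SelectionError(f"clause {kw!r} lacks an argument")
        arg = tokens[i + 1]
        if kw == "resid":
            m = _RESID_RE.match(arg)
            if not m:
                raise SelectionError(
                    f"bad resid argument {arg!r}; expected N or N:M")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise SelectionError(f"empty resid range {arg!r}")
            clauses.append(("resid", (lo, hi)))
        elif kw == "segid":
            clauses.append(("segid", arg.lower()))
        elif kw == "name":
            clauses.append(("name", arg.upper()))
        else:
            raise SelectionError(
                f"unknown selection keyword {kw!r}; valid: resid, segid, name")
        i += 2
    return clauses


def _matches(atom, clauses) -> bool:
    for kind, arg in clauses:
        if kind == "resid":
            if not (arg[0] <= atom.residue_id <= arg[1]):
                return False
        elif kind == "segid":
            if atom.segment_id.lower() != arg:
                return False
        elif kind == "name":
            if not fnmatch.fnmatchcase(atom.atom_name.upper(), arg):
                return False
    return True


def select_atoms(system: SegmentedSystem, selection: str):
    """Indices of atoms matched by a selection string."""
    clauses = parse_selection(selection)
    if not clauses:
        return []
    return [i for i, a in enumerate(system.atoms) if _matches(a, clauses)]


def knockout_charges(system: SegmentedSystem,
                     selection: str) -> SegmentedSystem:
    """Zero the partial charges of the selected atoms.

    Radii and coordinates are untouched; an empty selection returns an
    unchanged copy.
    """
    idx = select_atoms(system, selection)
    out = system.copy()
    for i in idx:
        out.atoms[i].charge = 0.0
    return out


def set_protonation(system: SegmentedSystem, residue_id: int,
                    state: str, segment_id: str | None = None,
                    registry=None) -> SegmentedSystem:
    """Set a titratable residue to the requested protonation state.

    ``state`` is a template label such as ``hsp``/``hsd``/``hse`` for
    histidine, ``aspp``, ``glup``, ``lsn`` or ``cysm``.  Hydrogens and
    charges of the residue are rebuilt from the new template; all other
    residues are untouched.  Applying the current state is a no-op.
    """
    registry = registry or load_registry()
    out = system.copy()
    prot_segs = out.segments_with_role(ROLE_PROTEIN)
    seg = segment_id or (prot_segs[0] if prot_segs else None)
    atoms = out.residue_atoms(residue_id, seg)
    current = out.overrides.get((seg, residue_id),
                                atoms[0].residue_name.upper())
    group = TITRATION_GROUPS.get(current)
    if group is None:
        raise StructureError(
            f"residue {current}{residue_id} is not titratable; titratable "
            f"residues: {sorted(set(TITRATION_GROUPS) - {'HIS'})}")
    label = state.upper()
    if label not in group:
        raise StructureError(
            f"unknown protonation state {state!r} for {current}; "
            f"valid labels: {[g.lower() for g in group]}")
    return reparameterize_residue(out, residue_id, seg, label,
                                  registry=registry)


def mutate_residue(system: SegmentedSystem, residue_id: int, target: str,
                   segment_id: str | None = None,
                   registry=None) -> SegmentedSystem:
    """Replace a residue by truncation re-templating.

    The backbone (and any side-chain heavy atoms shared by name with
    the target template, e.g. CB for X->ALA) keeps its coordinates;
    hydrogens and charges come from the target template.  Mutations
    requiring heavy-atom placement beyond the source side chain raise
    :class:`UnsupportedMutationError`.
    """
    registry = registry or load_registry()
    target = target.upper()
    target = {"HIS": "HSD"}.get(target, target)
    template = registry.get(target)
    out = system.copy()
    prot_segs = out.segments_with_role(ROLE_PROTEIN)
    seg = segment_id or (prot_segs[0] if prot_segs else None)
    atoms = out.residue_atoms(residue_id, seg)
    if (seg, residue_id) in out.ligating:
        raise StructureError(
            f"residue {residue_id} ligates the redox site; mutating it "
            "would change the redox couple")

    backbone = {"N", "CA", "C", "O", "OXT", "OT1", "OT2"}
    present_heavy = {a.atom_name.upper() for a in atoms if not a.is_hydrogen}
    needed = set(template.heavy_atoms()) - {"O"}  # O/OT1 handled by termini
    missing = needed - present_heavy - backbone
    if missing:
        raise UnsupportedMutationError(
            f"mutation to {target} needs heavy atoms {sorted(missing)} "
            "absent from the source residue; only truncation-reachable "
            "targets are supported")

    keep = backbone | set(template.heavy_atoms())
    kept_atoms = [a for a in atoms
                  if not a.is_hydrogen and a.atom_name.upper() in keep]
    atom_ids = {id(a) for a in atoms}
    kept_ids = {id(a) for a in kept_atoms}
    for a in kept_atoms:
        a.residue_name = target
    out.atoms = [a for a in out.atoms
                 if id(a) not in (atom_ids - kept_ids)]
    return reparameterize_residue(out, residue_id, seg, target,
                                  registry=registry)
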