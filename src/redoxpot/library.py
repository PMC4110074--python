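"""Redox parameter library: intrinsic free energies and per-state charges.

Each entry describes one redox site type and one redox couple: the site
atom composition (cofactor core plus ligating side-chain atoms), partial
charges for the oxidized and reduced states, atomic radii, the intrinsic
reduction free energy ``dg_in`` and the electrode reference ``dg_she``.

The on-disk format is multi-document YAML, one document per entry, with
explicit units (kcal/mol, e, Angstrom).  See ``data/redox_library.yaml``
for the shipped entries and the documented key set.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "AtomSpec",
    "LigandSpec",
    "RedoxEntry",
    "LibraryValidationError",
    "UnsupportedSiteError",
    "parse_couple",
    "load_library",
    "save_library",
    "get_entry",
    "default_library_path",
]

CHARGE_TOL = 1e-3


class LibraryValidationError(ValueError):
    """An entry violates a library invariant."""

    def __init__(self, entry_name, rule):
        self.entry_name = entry_name
        self.rule = rule
        super().__init__(f"library entry '{entry_name}': {rule}")


class UnsupportedSiteError(LookupError):
    """No library entry matches the requested site/couple."""


@dataclass(frozen=True)
class AtomSpec:
    """One site atom: name, dielectric radius and per-state charges."""

    name: str
    radius: float
    charge_ox: float
    charge_red: float


@dataclass(frozen=True)
class LigandSpec:
    """Protein side-chain atoms reassigned into the redox site.

    ``link_atom`` is the atom expected to sit within bonding distance of
    a cofactor heteroatom (e.g. cysteine SG near Fe).
    """

    residue: str
    link_atom: str
    count: int
    atoms: tuple  # of AtomSpec


@dataclass(frozen=True)
class RedoxEntry:
    """Library record for one site type and redox couple."""

    site_names: tuple           # PDB residue names, first is canonical
    couple: tuple               # (q_ox, q_red) in e
    n_electrons: int
    dg_in: float                # kcal/mol
    dg_she: float               # kcal/mol
    core_atoms: tuple           # of AtomSpec (cofactor heteroatoms)
    ligand: LigandSpec | None
    state_resnames: dict        # {"ox": ..., "red": ...}
    provenance: str = ""

    @property
    def name(self) -> str:
        return f"{self.site_names[0]} {couple_label(self.couple)}"

    def atom_charge_map(self, state: str) -> dict:
        """Map atom name -> (charge, radius) for 'ox' or 'red'."""
        if state not in ("ox", "red"):
            raise ValueError("state must be 'ox' or 'red'")
        out = {}
        for spec in self.all_atoms():
            q = spec.charge_ox if state == "ox" else spec.charge_red
            out[spec.name] = (q, spec.radius)
        return out

    def all_atoms(self):
        specs = list(self.core_atoms)
        if self.ligand is not None:
            specs.extend(self.ligand.atoms)
        return specs

    def composition(self) -> dict:
        """Expected atom-name multiset of the assembled site."""
        counts = {}
        for spec in self.core_atoms:
            counts[spec.name] = counts.get(spec.name, 0) + 1
        if self.ligand is not None:
            for spec in self.ligand.atoms:
                counts[spec.name] = counts.get(spec.name, 0) + self.ligand.count
        return counts

    def total_charge(self, state: str) -> float:
        mult = 1 if self.ligand is None else None
        total = sum(getattr(s, f"charge_{state}") for s in self.core_atoms)
        if self.ligand is not None:
            total += self.ligand.count * sum(
                getattr(s, f"charge_{state}") for s in self.ligand.atoms)
        return total

    def validate(self):
        name = self.name
        q_ox, q_red = self.couple
        if q_red != q_ox - self.n_electrons:
            raise LibraryValidationError(
                name, f"q_red ({q_red}) != q_ox - n_electrons "
                      f"({q_ox} - {self.n_electrons})")
        if self.n_electrons != 1:
            raise LibraryValidationError(
                name, "only single-electron couples are supported")
        for state, target in (("ox", q_ox), ("red", q_red)):
            total = self.total_charge(state)
            if abs(total - target) > CHARGE_TOL:
                raise LibraryValidationError(
                    name, f"sum of {state} charges {total:.4f} differs from "
                          f"formal charge {target}")
        for spec in self.all_atoms():
            if spec.radius <= 0:
                raise LibraryValidationError(
                    name, f"atom {spec.name} has non-positive radius")
        if not self.state_resnames.get("ox") or not self.state_resnames.get("red"):
            raise LibraryValidationError(name, "missing state residue names")


_COUPLE_RE = re.compile(r"^\s*(\d+)\s*([+-])\s*/\s*(\d+)\s*([+-])\s*$")


def parse_couple(value) -> tuple:
    """Normalize a couple given as '1-/2-' or an (q_ox, q_red) pair."""
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return int(value[0]), int(value[1])
    m = _COUPLE_RE.match(str(value))
    if not m:
        raise ValueError(
            f"cannot parse redox couple {value!r}; expected e.g. '1-/2-'")
    q_ox = int(m.group(1)) * (-1 if m.group(2) == "-" else 1)
    q_red = int(m.group(3)) * (-1 if m.group(4) == "-" else 1)
    return q_ox, q_red


def couple_label(couple) -> str:
    def one(q):
        return f"{abs(q)}{'-' if q < 0 else '+'}"
    return f"{one(couple[0])}/{one(couple[1])}"


def _atom_specs(raw, context):
    specs = []
    for item in raw:
        try:
            specs.append(AtomSpec(name=str(item["name"]),
                                  radius=float(item["radius"]),
                                  charge_ox=float(item["q_ox"]),
                                  charge_red=float(item["q_red"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise LibraryValidationError(context, f"malformed atom spec {item!r}") \
                from exc
    return tuple(specs)


def entry_from_dict(doc: dict) -> RedoxEntry:
    context = f"{doc.get('site', '?')} {doc.get('couple', '?')}"
    try:
        site_names = tuple([str(doc["site"])] +
                           [str(a) for a in doc.get("aliases", [])])
        couple = parse_couple(doc["couple"])
        ligand = None
        if doc.get("ligand"):
            lig = doc["ligand"]
            ligand = LigandSpec(residue=str(lig["residue"]),
                                link_atom=str(lig["link_atom"]),
                                count=int(lig["count"]),
                                atoms=_atom_specs(lig["atoms"], context))
        entry = RedoxEntry(
            site_names=site_names,
            couple=couple,
            n_electrons=int(doc.get("n_electrons", 1)),
            dg_in=float(doc["dg_in_kcal"]),
            dg_she=float(doc["dg_she_kcal"]),
            core_atoms=_atom_specs(doc["core_atoms"], context),
            ligand=ligand,
            state_resnames=dict(doc.get("state_resnames",
                                        {"ox": "RXO", "red": "RXR"})),
            provenance=str(doc.get("provenance", "")),
        )
    except LibraryValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise LibraryValidationError(context, f"malformed entry: {exc}") from exc
    entry.validate()
    return entry


def entry_to_dict(entry: RedoxEntry) -> dict:
    def atoms(specs):
        return [{"name": s.name, "radius": s.radius,
                 "q_ox": s.charge_ox, "q_red": s.charge_red} for s in specs]
    doc = {
        "site": entry.site_names[0],
        "aliases": list(entry.site_names[1:]),
        "couple": couple_label(entry.couple),
        "n_electrons": entry.n_electrons,
        "dg_in_kcal": entry.dg_in,
        "dg_she_kcal": entry.dg_she,
        "state_resnames": dict(entry.state_resnames),
        "provenance": entry.provenance,
        "core_atoms": atoms(entry.core_atoms),
    }
    if entry.ligand is not None:
        doc["ligand"] = {"residue": entry.ligand.residue,
                         "link_atom": entry.ligand.link_atom,
                         "count": entry.ligand.count,
                         "atoms": atoms(entry.ligand.atoms)}
    return doc


def load_library(path=None) -> list:
    """Load and validate all entries of a library file.

    With no path, the library shipped with the package is loaded.
    """
    if path is None:
        path = default_library_path()
    with open(path) as fh:
        docs = [d for d in yaml.safe_load_all(fh) if d]
    if not docs:
        raise LibraryValidationError(str(path), "library file holds no entries")
    return [entry_from_dict(d) for d in docs]


def save_library(entries, path):
    with open(path, "w") as fh:
        yaml.safe_dump_all([entry_to_dict(e) for e in entries], fh,
                           sort_keys=False)


def get_entry(library, site_name, couple) -> RedoxEntry:
    """Unique entry for a site residue name (or alias) and couple."""
    couple = parse_couple(couple)
    matches = [e for e in library
               if site_name.upper() in (n.upper() for n in e.site_names)
               and e.couple == couple]
    if not matches:
        raise UnsupportedSiteError(
            f"no library entry for site {site_name!r} couple "
            f"{couple_label(couple)}")
    if len(matches) > 1:
        raise LibraryValidationError(
            f"{site_name} {couple_label(couple)}",
            "multiple entries match; library is ambiguous")
    return matches[0]


def site_residue_names(library) -> set:
    names = set()
    for e in library:
        names.update(n.upper() for n in e.site_names)
    return names


def default_library_path():
    return importlib.resources.files("redoxpot.data") / "redox_library.yaml"
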