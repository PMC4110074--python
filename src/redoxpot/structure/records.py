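"""Core structure data types: atoms, segmented systems, cycle states."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtomRecord", "SegmentedSystem", "RedoxState", "FourStates",
           "StructureError"]

#: Backbone atom names never reassigned into a redox segment.
BACKBONE_ATOMS = {"N", "HN", "CA", "HA", "HA1", "HA2", "C", "O",
                  "OT1", "OT2", "OXT", "HT1", "HT2", "HT3", "HN1", "HN2"}

ROLE_PROTEIN = "protein"
ROLE_GOOD_HET = "good-het"
ROLE_REDOX = "redox-site"


class StructureError(ValueError):
    """Structure-level inconsistency."""


@dataclass(eq=False)
class AtomRecord:
    """One atom with coordinates and (once parameterized) charge/radius."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    segment_id: str
    coords: np.ndarray
    charge: float | None = None
    radius: float | None = None
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.radius is not None and self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.atom_name, self.element, self.residue_name,
                          self.residue_id, self.segment_id,
                          self.coords.copy(), self.charge, self.radius,
                          self.occupancy, self.altloc)


@dataclass
class SegmentedSystem:
    """Atoms partitioned into protein / good-het / redox-site segments.

    ``segment_roles`` maps every segment id to one of ``protein``,
    ``good-het`` or ``redox-site``; ``ligating`` records (segment,
    residue_id) pairs of protein residues whose side chains belong to
    the redox site; ``overrides`` pins per-residue template choices
    (protonation states) so re-parameterization is reproducible.
    """

    atoms: list = field(default_factory=list)
    segment_roles: dict = field(default_factory=dict)
    monomer: str = ""
    ligating: set = field(default_factory=set)
    overrides: dict = field(default_factory=dict)
    discard_report: dict = field(default_factory=dict)

    def copy(self) -> "SegmentedSystem":
        return SegmentedSystem(
            atoms=[a.copy() for a in self.atoms],
            segment_roles=dict(self.segment_roles),
            monomer=self.monomer,
            ligating=set(self.ligating),
            overrides=dict(self.overrides),
            discard_report=copy.deepcopy(self.discard_report),
        )

    # -- queries ---------------------------------------------------------
    def segments_with_role(self, role: str) -> list:
        return [s for s, r in self.segment_roles.items() if r == role]

    def atoms_in_role(self, role: str) -> list:
        segs = set(self.segments_with_role(role))
        return [a for a in self.atoms if a.segment_id in segs]

    def residues(self, role: str | None = None):
        """Residues as ``((segment_id, residue_id, residue_name), atoms)``
        in file order, optionally restricted to one segment role."""
        segs = None
        if role is not None:
            segs = set(self.segments_with_role(role))
        order = []
        groups = {}
        for a in self.atoms:
            if segs is not None and a.segment_id not in segs:
                continue
            key = (a.segment_id, a.residue_id)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        return [((seg, rid, groups[(seg, rid)][0].residue_name),
                 groups[(seg, rid)]) for seg, rid in order]

    def residue_atoms(self, residue_id: int, segment_id: str | None = None):
        hits = [a for a in self.atoms if a.residue_id == residue_id
                and (segment_id is None or a.segment_id == segment_id)]
        if not hits:
            where = f" in segment {segment_id}" if segment_id else ""
            raise StructureError(f"residue {residue_id}{where} not found")
        return hits

    def total_charge(self) -> float:
        if any(a.charge is None for a in self.atoms):
            raise StructureError("system is not fully parameterized")
        return float(sum(a.charge for a in self.atoms))

    # -- PB bridge -------------------------------------------------------
    def to_pb_system(self):
        """Point-charge view for the PB engine (requires parameterization)."""
        from ..pb.grids import PBSystem
        missing = [a for a in self.atoms if a.charge is None or a.radius is None]
        if missing:
            a = missing[0]
            raise StructureError(
                f"{len(missing)} atom(s) lack charge/radius (first: "
                f"{a.segment_id}/{a.residue_name}{a.residue_id}/{a.atom_name})")
        redox_segs = set(self.segments_with_role(ROLE_REDOX))
        return PBSystem(
            coords=np.array([a.coords for a in self.atoms]),
            charges=np.array([a.charge for a in self.atoms]),
            radii=np.array([a.radius for a in self.atoms]),
            site_mask=np.array([a.segment_id in redox_segs
                                for a in self.atoms]),
        )


@dataclass(frozen=True)
class RedoxState:
    """Oxidation-state label and formal redox-site charge."""

    label: str                 # "oxidized" | "reduced"
    formal_site_charge: int

    def __post_init__(self):
        if self.label not in ("oxidized", "reduced"):
            raise ValueError("label must be 'oxidized' or 'reduced'")


@dataclass
class FourStates:
    """The four parameterized systems of the thermodynamic cycle."""

    protein_ox: SegmentedSystem
    protein_red: SegmentedSystem
    reference_ox: SegmentedSystem
    reference_red: SegmentedSystem
    state_ox: RedoxState
    state_red: RedoxState

    def validate(self, tol=1e-9):
        if self.state_red.formal_site_charge != \
                self.state_ox.formal_site_charge - 1:
            raise StructureError("reduced formal charge must be ox - 1")
        po, pr = self.protein_ox, self.protein_red
        if len(po.atoms) != len(pr.atoms):
            raise StructureError("ox/red protein systems differ in atom count")
        redox_segs = set(po.segments_with_role(ROLE_REDOX))
        for ao, ar in zip(po.atoms, pr.atoms):
            if not np.allclose(ao.coords, ar.coords, atol=tol):
                raise StructureError("ox/red protein coordinates differ")
            if ao.segment_id not in redox_segs and \
                    abs((ao.charge or 0) - (ar.charge or 0)) > tol:
                raise StructureError(
                    "non-redox charges differ between ox and red systems")
        for prot, ref in ((po, self.reference_ox), (pr, self.reference_red)):
            site = prot.atoms_in_role(ROLE_REDOX)
            if len(site) != len(ref.atoms):
                raise StructureError("reference does not equal redox segment")
            for a, b in zip(site, ref.atoms):
                if a.atom_name != b.atom_name or \
                        not np.allclose(a.coords, b.coords, atol=tol):
                    raise StructureError(
                        "reference atoms differ from protein redox segment")
                if abs((a.charge or 0) - (b.charge or 0)) > tol:
                    raise StructureError(
                        "reference charges differ from protein redox segment")
        return self
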