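"""Thermodynamic-cycle assembly: dG_out, E0 and the analysis procedures.

Sign convention (pinned operationally, documented in the README)::

    E0 = -(dG_in + dG_out + dG_SHE) / (n * F)

with F such that 1 V corresponds to 23.0605 kcal/mol per electron and
``dG_out = dG_solv(reduced) - dG_solv(oxidized)``.  Analysis outputs
(protonation shifts, knock-out contributions, mutation shifts) are
differences of E0 values on identical grids, in which dG_in and dG_SHE
cancel identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import KCAL_PER_VOLT
from .library import RedoxEntry
from .pb.energy import system_grid_energy
from .pb.grids import GridSpec, PBParams, grid_from_atoms
from .structure.records import FourStates, SegmentedSystem, StructureError, \
    ROLE_REDOX
from .structure.segments import build_states
from .structure.edits import knockout_charges, select_atoms

__all__ = ["RedoxResult", "delta_g_out", "reduction_potential",
           "compute_redox", "residue_contribution", "state_shift",
           "common_grid", "DETERMINANT_THRESHOLD_V"]

#: Residues with |contribution| above this are flagged as sequence
#: determinants of E0.
DETERMINANT_THRESHOLD_V = 0.03


@dataclass
class RedoxResult:
    """All terms of one reduction-potential calculation."""

    dg_solv_ox: float          # kcal/mol
    dg_solv_red: float         # kcal/mol
    dg_out: float              # kcal/mol
    dg_in: float               # kcal/mol
    dg_she: float              # kcal/mol
    n_electrons: int
    e0: float                  # volts
    grid_meta: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if abs(self.dg_out - (self.dg_solv_red - self.dg_solv_ox)) > 1e-9:
            raise ValueError("dg_out must equal dg_solv_red - dg_solv_ox")
        if not math.isfinite(self.e0):
            raise ValueError("E0 must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


def reduction_potential(dg_in: float, dg_out: float, dg_she: float,
                        n: int = 1) -> float:
    """E0 in volts from the cycle terms (kcal/mol)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for v in (dg_in, dg_out, dg_she):
        if not math.isfinite(v):
            raise ValueError("cycle terms must be finite")
    return -(dg_in + dg_out + dg_she) / (n * KCAL_PER_VOLT)


def common_grid(systems, params: PBParams) -> GridSpec:
    """One fine grid covering every system (so results are comparable)."""
    coords = np.vstack([np.array([a.coords for a in s.atoms])
                        for s in systems])
    radii = np.concatenate([np.array([a.radius if a.radius is not None
                                      else 2.0 for a in s.atoms])
                            for s in systems])
    return grid_from_atoms(coords, radii, params.spacing_fine,
                           margin=params.fine_margin)


def delta_g_out(states: FourStates, params: PBParams,
                grid: GridSpec | None = None):
    """Run the four PB legs and return the cycle's environmental term.

    Returns ``(dg_solv_ox, dg_solv_red, dg_out, grid_meta)`` in
    kcal/mol.  All four legs share one grid so grid self-energies of
    shared charges cancel exactly.
    """
    states.validate()
    if grid is None:
        grid = common_grid([states.protein_ox], params)
    legs = {}
    for label, system, uniform in (
            ("protein_ox", states.protein_ox, None),
            ("protein_red", states.protein_red, None),
            ("reference_ox", states.reference_ox, 1.0),
            ("reference_red", states.reference_red, 1.0)):
        try:
            legs[label] = system_grid_energy(system.to_pb_system(), grid,
                                             params, uniform=uniform)
        except Exception as exc:
            raise RuntimeError(f"PB leg {label!r} failed: {exc}") from exc
    dg_solv_ox = legs["protein_ox"] - legs["reference_ox"]
    dg_solv_red = legs["protein_red"] - legs["reference_red"]
    meta = {"spacing": grid.spacing, "dims": list(grid.dims),
            "origin": [float(x) for x in grid.origin]}
    return dg_solv_ox, dg_solv_red, dg_solv_red - dg_solv_ox, meta


def compute_redox(system: SegmentedSystem, entry: RedoxEntry,
                  params: PBParams, grid: GridSpec | None = None,
                  knockout: str | None = None) -> RedoxResult:
    """Full cycle for one prepared system: states, four PB legs, E0."""
    if knockout:
        _refuse_redox_knockout(system, knockout)
        system = knockout_charges(system, knockout)
    states = build_states(system, entry)
    dg_ox, dg_red, dg_out, meta = delta_g_out(states, params, grid=grid)
    e0 = reduction_potential(entry.dg_in, dg_out, entry.dg_she,
                             entry.n_electrons)
    return RedoxResult(
        dg_solv_ox=dg_ox, dg_solv_red=dg_red, dg_out=dg_out,
        dg_in=entry.dg_in, dg_she=entry.dg_she,
        n_electrons=entry.n_electrons, e0=e0, grid_meta=meta,
        provenance=entry.provenance.strip())


def _refuse_redox_knockout(system, selection):
    redox_segs = set(system.segments_with_role(ROLE_REDOX))
    for i in select_atoms(system, selection):
        a = system.atoms[i]
        if a.segment_id in redox_segs:
            raise StructureError(
                f"knock-out selection hits redox-site atom {a.atom_name} "
                f"({a.residue_name}{a.residue_id}); site charges define "
                "the couple and cannot be knocked out")


def residue_contribution(system: SegmentedSystem, residue_id: int,
                         entry: RedoxEntry, params: PBParams,
                         grid: GridSpec | None = None):
    """Electrostatic contribution of one residue to E0, in volts.

    ``E0(system) - E0(system with the residue's charges zeroed)`` on a
    shared grid.  Returns ``(contribution, is_determinant)`` where the
    flag marks |contribution| > 0.03 V.  dG_in and dG_SHE cancel in the
    difference, so the value is independent of library energetics.
    """
    selection = f"resid {residue_id}"
    _refuse_redox_knockout(system, selection)
    if grid is None:
        grid = common_grid([system], params)
    full = compute_redox(system, entry, params, grid=grid)
    ko = compute_redox(system, entry, params, grid=grid, knockout=selection)
    # difference the environmental terms directly: dG_in and dG_SHE then
    # cancel identically, independent of their floating-point values
    contribution = -(full.dg_out - ko.dg_out) / (entry.n_electrons
                                                 * KCAL_PER_VOLT)
    return contribution, abs(contribution) > DETERMINANT_THRESHOLD_V


def state_shift(system_a: SegmentedSystem, system_b: SegmentedSystem,
                entry: RedoxEntry, params: PBParams,
                entry_b: RedoxEntry | None = None,
                grid: GridSpec | None = None) -> float:
    """``E0(b) - E0(a)`` on one shared grid, in volts.

    Used for protonation shifts (wild type vs modified) and mutation
    shifts.  Both systems must share the redox couple.
    """
    entry_b = entry_b or entry
    if entry_b.couple != entry.couple:
        raise ValueError(
            f"systems have different redox couples {entry.couple} vs "
            f"{entry_b.couple}; shifts are only defined within one couple")
    if grid is None:
        grid = common_grid([system_a, system_b], params)
    ra = compute_redox(system_a, entry, params, grid=grid)
    rb = compute_redox(system_b, entry_b, params, grid=grid)
    # dG_in/dG_SHE cancel identically in the dg_out difference
    return -(rb.dg_out - ra.dg_out) / (entry.n_electrons * KCAL_PER_VOLT)
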