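"""Synthetic fixtures with analytic oracles.

Every fixture carries the independent value it should reproduce (Born
closed form, Kirkwood image series, or a two-path equality), so the
full pipeline is testable without any external data.
"""

from __future__ import annotations

import numpy as np

from .constants import COULOMB
from .library import AtomSpec, RedoxEntry
from .structure.records import (AtomRecord, SegmentedSystem, ROLE_PROTEIN,
                                ROLE_REDOX)

__all__ = ["born_energy", "kirkwood_energy", "make_born_ion",
           "make_offcenter_sphere", "make_toy_site_peptide", "toy_entry"]


def born_energy(q: float, a: float, eps_solvent: float,
                eps_in: float = 1.0) -> float:
    """Born solvation free energy of a charge q in a cavity of radius a."""
    if a <= 0:
        raise ValueError("cavity radius must be > 0")
    return -(COULOMB * q * q / (2.0 * a)) * (1.0 / eps_in - 1.0 / eps_solvent)


def kirkwood_energy(q: float, a: float, d: float, eps_solvent: float,
                    eps_in: float = 1.0, rtol: float = 1e-8,
                    max_terms: int = 100000) -> float:
    """Reaction-field energy of an off-center charge in a sphere.

    Image-series solution for a point charge at distance ``d`` from the
    center of a cavity of radius ``a`` (inner dielectric ``eps_in``,
    outer ``eps_solvent``), summed to relative tolerance ``rtol``.  The
    ``d = 0`` term reduces to the Born expression.
    """
    if not 0 <= d < a:
        raise ValueError("require 0 <= d < a")
    x = (d / a) ** 2
    total = 0.0
    for l in range(max_terms):
        coeff = ((l + 1) * (eps_solvent - eps_in)
                 / (eps_in * ((l + 1) * eps_solvent + l * eps_in)))
        term = coeff * x ** l
        total += term
        if l > 2 and abs(term) <= rtol * abs(total):
            break
    else:
        raise RuntimeError("Kirkwood series did not converge")
    return -(COULOMB * q * q / (2.0 * a)) * total


def make_born_ion(q: float, a: float, eps_solvent: float = 78.54):
    """Single-ion fixture: one redox-site atom of radius ``a``, charge ``q``.

    Returns ``(system, meta)``; the reference system for the solvation
    leg is the same single atom in vacuum, and ``meta['oracle_kcal']``
    holds the analytic Born value.
    """
    if a <= 0:
        raise ValueError("cavity radius must be > 0")
    atom = AtomRecord(atom_name="ION", element="X", residue_name="BRN",
                      residue_id=1, segment_id="b-bad",
                      coords=np.zeros(3), charge=float(q), radius=float(a))
    system = SegmentedSystem(atoms=[atom],
                             segment_roles={"b-bad": ROLE_REDOX})
    meta = {"kind": "born_ion", "q": q, "a": a, "eps_solvent": eps_solvent,
            "oracle_kcal": born_energy(q, a, eps_solvent)}
    return system, meta


def make_offcenter_sphere(q: float, a: float, d: float,
                          eps_solvent: float = 78.54):
    """Off-center charge in a dielectric cavity, with Kirkwood oracle.

    A zero-charge dummy atom of radius ``a`` defines the cavity; the
    unit-radius-free point charge sits at distance ``d`` from center.
    """
    if d >= a or d < 0:
        raise ValueError("require 0 <= d < a")
    cavity = AtomRecord(atom_name="CAV", element="X", residue_name="KIR",
                        residue_id=1, segment_id="k-bad",
                        coords=np.zeros(3), charge=0.0, radius=float(a))
    charge = AtomRecord(atom_name="Q", element="X", residue_name="KIR",
                        residue_id=1, segment_id="k-bad",
                        coords=np.array([float(d), 0.0, 0.0]),
                        charge=float(q), radius=0.0)
    system = SegmentedSystem(atoms=[cavity, charge],
                             segment_roles={"k-bad": ROLE_REDOX})
    meta = {"kind": "offcenter_sphere", "q": q, "a": a, "d": d,
            "eps_solvent": eps_solvent,
            "oracle_kcal": kirkwood_energy(q, a, d, eps_solvent)}
    return system, meta


#: Residue id of the toggleable (titratable-like) environment residue.
TOY_TOGGLE_RESID = 1
#: Residue id of the toy cofactor.
TOY_SITE_RESID = 100


def toy_entry() -> RedoxEntry:
    """Library entry for the four-atom toy site (couple 1-/2-)."""
    entry = RedoxEntry(
        site_names=("TOY",),
        couple=(-1, -2),
        n_electrons=1,
        dg_in=-50.0,
        dg_she=102.158,
        core_atoms=(
            AtomSpec("FE1", 1.5, 0.30, 0.05),
            AtomSpec("FE2", 1.5, 0.30, 0.05),
            AtomSpec("S1", 1.8, -0.80, -1.05),
            AtomSpec("S2", 1.8, -0.80, -1.05),
        ),
        ligand=None,
        state_resnames={"ox": "TSO", "red": "TSR"},
        provenance="synthetic toy fixture",
    )
    entry.validate()
    return entry


def make_toy_site_peptide(seed: int = 0, n_residues: int = 10,
                          toggle_charged: bool = True):
    """Desk-scale stand-in for a redox protein.

    A four-atom charged site (segment ``t-bad``) wrapped by
    ``n_residues`` three-atom polar dummy residues (segment ``t-pro``)
    on a shell around it.  Residue :data:`TOY_TOGGLE_RESID` carries a
    net +1 charge when ``toggle_charged`` (the 'protonated' state) and
    exactly zero charges otherwise, so knock-out and state-toggle paths
    can be compared bit-for-bit.  Deterministic under ``seed``.

    Returns ``(system, entry)``.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    site_xyz = np.array([[1.1, 1.1, 1.1], [-1.1, -1.1, 1.1],
                         [1.1, -1.1, -1.1], [-1.1, 1.1, -1.1]])
    entry = toy_entry()
    for spec, xyz in zip(entry.core_atoms, site_xyz):
        atoms.append(AtomRecord(
            atom_name=spec.name, element=spec.name[:2].capitalize(),
            residue_name="TOY", residue_id=TOY_SITE_RESID,
            segment_id="t-bad", coords=xyz,
            charge=spec.charge_ox, radius=spec.radius))

    # shell of dummy residues: deterministic directions, min separation
    centers = []
    attempts = 0
    while len(centers) < n_residues and attempts < 1000:
        attempts += 1
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(6.5, 8.5)
        if all(np.linalg.norm(v - c) > 3.6 for c in centers):
            centers.append(v)
    if len(centers) < n_residues:
        raise RuntimeError("could not place toy residues; lower n_residues")

    names = ("C1", "O1", "N1")
    radii = (2.0, 1.7, 1.85)
    polar = (0.25, -0.25, 0.0)
    toggle = (0.55, 0.45, 0.0) if toggle_charged else (0.0, 0.0, 0.0)
    for rid, center in enumerate(centers, start=1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        offsets = (np.zeros(3), 1.3 * axis, -1.3 * axis)
        charges = toggle if rid == TOY_TOGGLE_RESID else polar
        for name, r, q, off in zip(names, radii, charges, offsets):
            atoms.append(AtomRecord(
                atom_name=name, element=name[0], residue_name="DUM",
                residue_id=rid, segment_id="t-pro",
                coords=center + off, charge=q, radius=r))

    system = SegmentedSystem(
        atoms=atoms,
        segment_roles={"t-pro": ROLE_PROTEIN, "t-bad": ROLE_REDOX})
    return system, entry
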