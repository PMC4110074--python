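"""Cycle assembly: E0 algebra, cancellation properties, dG_out oracles."""

import dataclasses

import numpy as np
import pytest

from redoxpot.constants import COULOMB, KCAL_PER_VOLT
from redoxpot.cycle import (RedoxResult, common_grid, compute_redox,
                            delta_g_out, reduction_potential,
                            residue_contribution, state_shift)
from redoxpot.fixtures import born_energy, make_toy_site_peptide, toy_entry
from redoxpot.library import AtomSpec
from redoxpot.pb.grids import PBParams, grid_from_atoms
from redoxpot.structure.records import (AtomRecord, FourStates, RedoxState,
                                        SegmentedSystem, StructureError,
                                        ROLE_PROTEIN, ROLE_REDOX)

EPS_W = 78.54


@pytest.fixture(scope="module")
def toy():
    system, entry = make_toy_site_peptide(seed=7)
    return system, entry


@pytest.fixture(scope="module")
def toy_params():
    return PBParams(spacing_fine=0.6, eps_solvent=EPS_W, padding=12.0,
                    spacing_coarse=1.2)


class TestReductionPotential:
    def test_all_zero(self):
        assert reduction_potential(0.0, 0.0, 0.0, 1) == 0.0

    def test_unit_conversion(self):
        assert reduction_potential(-KCAL_PER_VOLT, 0.0, 0.0, 1) == \
            pytest.approx(1.000, abs=1e-12)

    def test_two_electron_scaling(self):
        one = reduction_potential(-10.0, -5.0, 2.0, 1)
        two = reduction_potential(-10.0, -5.0, 2.0, 2)
        assert two == pytest.approx(one / 2)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            reduction_potential(0.0, 0.0, 0.0, 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            reduction_potential(float("nan"), 0.0, 0.0, 1)


class TestRedoxResult:
    def test_dg_out_consistency_enforced(self):
        with pytest.raises(ValueError):
            RedoxResult(dg_solv_ox=-1.0, dg_solv_red=-2.0, dg_out=-0.5,
                        dg_in=0.0, dg_she=0.0, n_electrons=1, e0=0.0)


def _born_states(q_ox, q_red, a=2.0):
    """Single-atom redox site: FourStates with no environment."""
    def sys_with(q):
        atom = AtomRecord("ION", "X", "BRN", 1, "b-bad", np.zeros(3),
                          charge=float(q), radius=a)
        return SegmentedSystem(atoms=[atom],
                               segment_roles={"b-bad": ROLE_REDOX})
    return FourStates(
        protein_ox=sys_with(q_ox), protein_red=sys_with(q_red),
        reference_ox=sys_with(q_ox), reference_red=sys_with(q_red),
        state_ox=RedoxState("oxidized", q_ox),
        state_red=RedoxState("reduced", q_red))


class TestDeltaGOut:
    def test_identical_charge_sets_give_zero(self):
        params = PBParams(spacing_fine=0.5, eps_solvent=EPS_W)
        states = _born_states(-1, -1)
        states.state_ox = RedoxState("oxidized", -1)
        states.state_red = RedoxState("reduced", -2)  # labels only
        _, _, dg_out, _ = delta_g_out(states, params)
        assert dg_out == pytest.approx(0.0, abs=1e-9)

    def test_born_couple_equals_three_born_units(self):
        """-1 -> -2 on a 2 A Born sphere: dG_out = (4-1) * Born(1e)."""
        params = PBParams(spacing_fine=0.25, eps_solvent=EPS_W)
        states = _born_states(-1, -2)
        _, _, dg_out, _ = delta_g_out(states, params)
        expected = 3.0 * born_energy(1.0, 2.0, EPS_W)
        assert expected == pytest.approx(3 * -81.96, abs=0.03)
        assert dg_out == pytest.approx(expected, rel=0.02)

    def test_distant_external_charge_matches_screened_coulomb(self):
        """A fixed charge 30 A away shifts dG_out by k*dq*q/(eps*r)."""
        params = PBParams(spacing_fine=0.75, eps_solvent=EPS_W,
                          padding=12.0)
        q_ext, r_ext = 2.0, 30.0
        states_bare = _born_states(-1, -2)

        def with_external(states):
            out = []
            for s in (states.protein_ox, states.protein_red):
                s2 = s.copy()
                s2.atoms.append(AtomRecord(
                    "EXT", "X", "EXT", 2, "b-pro",
                    np.array([r_ext, 0.0, 0.0]), charge=q_ext, radius=1.5))
                s2.segment_roles["b-pro"] = ROLE_PROTEIN
                out.append(s2)
            return FourStates(protein_ox=out[0], protein_red=out[1],
                              reference_ox=states.reference_ox,
                              reference_red=states.reference_red,
                              state_ox=states.state_ox,
                              state_red=states.state_red)

        states_ext = with_external(states_bare)
        grid = common_grid([states_ext.protein_ox], params)
        _, _, dg_bare, _ = delta_g_out(states_bare, params, grid=grid)
        _, _, dg_ext, _ = delta_g_out(states_ext, params, grid=grid)
        analytic = COULOMB * (-1.0) * q_ext / (EPS_W * r_ext)
        assert abs((dg_ext - dg_bare) - analytic) < 0.5


class TestCancellationProperties:
    def test_shift_independent_of_library_energetics(self, toy, toy_params):
        """dG_in/dG_SHE cancel bit-for-bit in shifts and contributions."""
        system, entry = toy
        neutral, _ = make_toy_site_peptide(seed=7, toggle_charged=False)
        entry2 = dataclasses.replace(entry, dg_in=entry.dg_in + 123.456,
                                     dg_she=entry.dg_she - 77.7)
        grid = common_grid([system, neutral], toy_params)
        s1 = state_shift(neutral, system, entry, toy_params, grid=grid)
        s2 = state_shift(neutral, system, entry2, toy_params, grid=grid)
        assert s1 == s2
        c1, _ = residue_contribution(system, 1, entry, toy_params, grid=grid)
        c2, _ = residue_contribution(system, 1, entry2, toy_params,
                                     grid=grid)
        assert c1 == c2

    def test_antisymmetry(self, toy, toy_params):
        system, entry = toy
        neutral, _ = make_toy_site_peptide(seed=7, toggle_charged=False)
        grid = common_grid([system, neutral], toy_params)
        ab = state_shift(neutral, system, entry, toy_params, grid=grid)
        ba = state_shift(system, neutral, entry, toy_params, grid=grid)
        assert ab == -ba

    def test_two_path_equality(self, toy, toy_params):
        """Knock-out contribution equals the direct toggle shift exactly."""
        system, entry = toy
        neutral, _ = make_toy_site_peptide(seed=7, toggle_charged=False)
        grid = common_grid([system, neutral], toy_params)
        contribution, _ = residue_contribution(system, 1, entry, toy_params,
                                               grid=grid)
        shift = state_shift(neutral, system, entry, toy_params, grid=grid)
        assert contribution == shift

    def test_self_shift_is_zero(self, toy, toy_params):
        system, entry = toy
        grid = common_grid([system], toy_params)
        assert state_shift(system, system, entry, toy_params,
                           grid=grid) == 0.0

    def test_couple_mismatch_rejected(self, toy, toy_params):
        system, entry = toy
        other = dataclasses.replace(
            entry, couple=(-2, -3),
            core_atoms=tuple(dataclasses.replace(s, charge_ox=s.charge_red,
                                                 charge_red=s.charge_red
                                                 - 0.25)
                             for s in entry.core_atoms))
        with pytest.raises(ValueError, match="couple"):
            state_shift(system, system, entry, toy_params, entry_b=other)

    def test_zero_charge_residue_contributes_nothing(self, toy_params):
        neutral, entry = make_toy_site_peptide(seed=7, toggle_charged=False)
        grid = common_grid([neutral], toy_params)
        contribution, flag = residue_contribution(neutral, 1, entry,
                                                  toy_params, grid=grid)
        assert contribution == 0.0
        assert flag is False

    def test_knockout_of_site_refused(self, toy, toy_params):
        system, entry = toy
        with pytest.raises(StructureError, match="redox-site"):
            residue_contribution(system, 100, entry, toy_params)


class TestToyPipeline:
    def test_bare_site_reduces_to_born_like_value(self, toy_params):
        """Zeroing all environment charges: dG_out approaches the value
        for the site alone on the same grid."""
        system, entry = make_toy_site_peptide(seed=3)
        from redoxpot.structure.edits import knockout_charges
        from redoxpot.structure.segments import build_states
        bare = knockout_charges(system, "segid t-pro")
        grid = common_grid([system], toy_params)
        states = build_states(bare, entry)
        _, _, dg_out_bare, _ = delta_g_out(states, toy_params, grid=grid)

        site_only = SegmentedSystem(
            atoms=[a.copy() for a in system.atoms
                   if a.segment_id == "t-bad"],
            segment_roles={"t-bad": ROLE_REDOX})
        states_site = build_states(site_only, entry)
        _, _, dg_out_site, _ = delta_g_out(states_site, toy_params,
                                           grid=grid)
        # environment spheres still displace dielectric; tolerance is
        # physical (cavity effect), not solver noise
        assert dg_out_bare == pytest.approx(dg_out_site, rel=0.05)

    def test_grid_refinement_stability(self, toy, toy_params):
        """E0 differences between two spacings stay within 0.05 V."""
        system, entry = toy
        coarse = compute_redox(system, entry, toy_params)
        fine = compute_redox(system, entry,
                             toy_params.replace(spacing_fine=0.3))
        assert abs(fine.e0 - coarse.e0) <= 0.05

    def test_result_report_is_serializable(self, toy, toy_params):
        import json
        system, entry = toy
        result = compute_redox(system, entry, toy_params)
        doc = json.loads(json.dumps(result.to_dict()))
        assert doc["n_electrons"] == 1
        assert doc["dg_out"] == pytest.approx(result.dg_out)
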