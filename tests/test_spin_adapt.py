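"""Spin adaptation: singlet embedding, ladder closure, multiplet
truncation, and agreement between the two symmetry modes."""

import numpy as np
import pytest

from conftest import embed_to_sector

from spindmrg.integrals import hubbard_chain, random_cas
from spindmrg.mps_mpo import to_statevector
from spindmrg.oracle import (determinant_basis, s_squared,
                             sector_spin_resolved_minimum)
from spindmrg.solver import Stage, SweepSchedule, run_dmrg
from spindmrg.spin_adapt import (SpinAdaptedContext, closure_state,
                                 ladder_step_right, physical_component,
                                 random_su2_mps)
from spindmrg.symmetry import SU2, Sector, u1_dimension


def exact_schedule(d=64, sweeps=16):
    return SweepSchedule([Stage(8, 1e-10), Stage(d, 1e-10)],
                         max_sweeps=sweeps, energy_tol=1e-11)


class TestClosureState:
    @pytest.mark.parametrize("n_orb,n_elec,two_s", [
        (3, 3, 1), (4, 4, 2), (4, 5, 3), (4, 4, 0)])
    def test_embedded_reference_is_normalized_singlet(self, n_orb, n_elec,
                                                      two_s):
        state = closure_state(n_orb, n_elec, two_s)
        assert state.n_sites == n_orb + 1
        assert state.norm() == pytest.approx(1.0, abs=1e-10)
        assert state.target == Sector(n_elec, 0)

    def test_bond_bases_are_ladder_closed(self):
        """[S+, S-] on every bond basis must equal 2 Sz of the right part
        — the su(2) algebra only closes on complete multiplets."""
        state = closure_state(4, 4, 2)
        n = state.n_sites
        ctx = SpinAdaptedContext(2, 4, 4)
        rm = [dict() for _ in range(n + 1)]
        for k in range(n - 1, 0, -1):
            rm[k] = ladder_step_right(rm[k + 1], state.tensors[k],
                                      ctx.local_minus(k))
        for k in range(1, n):
            ax = state.tensors[k].axes[0]
            offs = ax.offsets()
            dim = ax.total_dim
            Rm = np.zeros((dim, dim))
            for (r, c), m in rm[k].items():
                Rm[offs[r]:offs[r] + m.shape[0],
                   offs[c]:offs[c] + m.shape[1]] = m
            comm = Rm.T @ Rm - Rm @ Rm.T
            expected = np.zeros(dim)
            for sec, d in ax.dims:
                expected[offs[sec]:offs[sec] + d] = -sec.spin2
            np.testing.assert_allclose(comm, np.diag(expected), atol=1e-10)

    def test_physical_component_is_spin_eigenstate(self):
        state = closure_state(4, 5, 3)
        phys = physical_component(state, 3)
        v = to_statevector(phys)
        v /= np.linalg.norm(v)
        basis = determinant_basis(4, 5, 3)
        sub = embed_to_sector(v, basis)
        assert s_squared(sub, basis) == pytest.approx(3.75, abs=1e-10)

    def test_random_start_is_seeded_and_spin_pure(self):
        a = random_su2_mps(4, Sector(4, 2), d=8, seed=5)
        b = random_su2_mps(4, Sector(4, 2), d=8, seed=5)
        va, vb = to_statevector(physical_component(a, 2)), \
            to_statevector(physical_component(b, 2))
        np.testing.assert_allclose(va, vb, atol=1e-12)
        basis = determinant_basis(4, 4, 2)
        sub = embed_to_sector(va / np.linalg.norm(va), basis)
        assert s_squared(sub, basis) == pytest.approx(2.0, abs=1e-8)


class TestSpinAdaptedGroundStates:
    @pytest.mark.parametrize("table,target", [
        (hubbard_chain(4, 1.0, 4.0), Sector(4, 0)),
        (random_cas(4, 3, seed=5, two_s_target=1), Sector(3, 1)),
        (random_cas(4, 4, seed=7, two_s_target=2), Sector(4, 2)),
        (random_cas(4, 5, seed=9, two_s_target=3), Sector(5, 3)),
    ], ids=["singlet", "doublet", "triplet", "quartet"])
    def test_energy_matches_spin_resolved_oracle(self, table, target):
        e, state, records, _ = run_dmrg(table, target, exact_schedule(),
                                        seed=3, mode=SU2)
        e_oracle = sector_spin_resolved_minimum(table, target.n, target.spin2)
        assert e == pytest.approx(e_oracle, abs=1e-8)

    def test_optimized_state_stays_spin_pure(self):
        table = random_cas(4, 4, seed=7, two_s_target=2)
        _, state, _, _ = run_dmrg(table, Sector(4, 2), exact_schedule(),
                                  seed=3, mode=SU2)
        phys = physical_component(state, 2)
        v = to_statevector(phys)
        v /= np.linalg.norm(v)
        basis = determinant_basis(4, 4, 2)
        sub = embed_to_sector(v, basis)
        assert s_squared(sub, basis) == pytest.approx(2.0, abs=1e-8)

    def test_multiplet_spectra_account_for_u1_dimensions(self):
        table = hubbard_chain(5, 1.0, 4.0)
        _, state, records, _ = run_dmrg(table, Sector(5, 1), exact_schedule(),
                                        seed=3, mode=SU2)
        dims = state.bond_dims()
        assert all(sp is not None for sp in state.bond_spectra)
        for sp, d in zip(state.bond_spectra, dims):
            assert u1_dimension(sp) == d
            assert sp.multiplet_count <= d
        rec = records[-1]
        assert rec.realized_D == max(sp.multiplet_count
                                     for sp in state.bond_spectra)
        assert rec.realized_D_u1 == max(dims)
        # with any S>0 multiplet retained the U(1) count strictly exceeds D
        if any(s > 0 for sp in state.bond_spectra for s, _ in sp.entries):
            assert rec.realized_D_u1 > rec.realized_D

    def test_truncated_runs_are_variational_and_monotone(self):
        table = random_cas(5, 5, seed=1, two_s_target=1)
        e_oracle = sector_spin_resolved_minimum(table, 5, 1)
        energies = []
        for cap in (2, 4, 8, 48):
            sched = SweepSchedule([Stage(cap, 1e-10)], max_sweeps=12,
                                  energy_tol=1e-11)
            e, *_ = run_dmrg(table, Sector(5, 1), sched, seed=3, mode=SU2)
            energies.append(e)
            assert e >= e_oracle - 1e-9
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))
        assert energies[-1] == pytest.approx(e_oracle, abs=1e-8)
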