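"""DMRG optimization loop: Davidson, effective Hamiltonian, sweeps."""

import numpy as np
import pytest

from conftest import det_to_codes, occ_index

from spindmrg.block_tensor import FlopLedger
from spindmrg.integrals import hubbard_chain, hubbard_dimer_singlet_energy, \
    random_cas
from spindmrg.mpo import build_mpo
from spindmrg.mps_mpo import random_mps, canonicalize, _left_edge, \
    _right_edge, _env_step_right
from spindmrg.oracle import fci_ground_state
from spindmrg.solver import (Stage, SweepRecord, SweepSchedule, VectorLayout,
                             apply_heff, benchmark_sweep_cost, davidson,
                             heff_diagonal, run_dmrg, sweep,
                             _merge_two_site)
from spindmrg.symmetry import Sector


class TestDavidson:
    def test_diagonal_operator(self):
        d = np.array([1.0, 2.0, 3.0])
        guess = np.array([0.3, 0.9, 0.1])
        val, vec, iters, conv = davidson(lambda v: d * v, guess, tol=1e-12,
                                         diag_preconditioner=d)
        assert conv and val == pytest.approx(1.0, abs=1e-11)
        assert abs(vec[0]) == pytest.approx(1.0, abs=1e-6)

    def test_random_hermitian_matches_dense_eigensolver(self, rng):
        A = rng.standard_normal((50, 50))
        A = (A + A.T) / 2
        w = np.linalg.eigvalsh(A)
        val, vec, iters, conv = davidson(lambda v: A @ v,
                                         rng.standard_normal(50),
                                         tol=1e-11,
                                         diag_preconditioner=np.diag(A))
        assert conv
        assert val == pytest.approx(w[0], abs=1e-9)
        assert np.linalg.norm(A @ vec - val * vec) < 1e-9

    def test_exact_guess_converges_immediately(self, rng):
        A = rng.standard_normal((20, 20))
        A = (A + A.T) / 2
        w, v = np.linalg.eigh(A)
        val, _, iters, conv = davidson(lambda x: A @ x, v[:, 0], tol=1e-10)
        assert conv and iters <= 2
        assert val == pytest.approx(w[0], abs=1e-10)

    def test_restart_still_converges(self, rng):
        A = np.diag(np.linspace(0, 10, 200))
        A[0, 1] = A[1, 0] = 0.1
        val, _, iters, conv = davidson(lambda v: A @ v,
                                       np.ones(200), tol=1e-10,
                                       diag_preconditioner=np.diag(A),
                                       max_space=6)
        assert conv and val == pytest.approx(np.linalg.eigvalsh(A)[0],
                                             abs=1e-9)


class TestEffectiveHamiltonian:
    def setup_problem(self, table, target):
        mpo = build_mpo(table)
        state = canonicalize(random_mps(table.n_orb, target, d=8, seed=3), 0)
        n = state.n_sites
        renv = [None] * (n + 1)
        renv[n] = _right_edge(state)
        for k in range(n - 1, 1, -1):
            renv[k] = _env_step_right(renv[k + 1], state.tensors[k],
                                      mpo.tensors[k], None, "env")
        psi2 = _merge_two_site(state.tensors[0], state.tensors[1], None)
        return mpo, state, _left_edge(state), renv[2], psi2

    def test_two_orbital_heff_is_the_sector_hamiltonian(self):
        table = hubbard_chain(2, 1.0, 4.0)
        target = Sector(2, 0)
        mpo, state, envl, envr, psi2 = self.setup_problem(table, target)
        layout = VectorLayout(psi2)
        H = np.zeros((layout.size, layout.size))
        for j in range(layout.size):
            e = np.zeros(layout.size)
            e[j] = 1.0
            H[:, j] = layout.to_flat(apply_heff(
                envl, envr, mpo.tensors[0], mpo.tensors[1],
                layout.from_flat(e)))
        ef, _ = fci_ground_state(table, 2, 0)
        assert np.linalg.eigvalsh(H)[0] == pytest.approx(ef, abs=1e-10)
        np.testing.assert_allclose(H, H.T, atol=1e-11)

    def test_linearity_and_hermiticity(self, rng):
        table = random_cas(3, 3, seed=5)
        mpo, state, envl, envr, psi2 = self.setup_problem(table, Sector(3, 1))
        layout = VectorLayout(psi2)

        def ap(v):
            return layout.to_flat(apply_heff(envl, envr, mpo.tensors[0],
                                             mpo.tensors[1],
                                             layout.from_flat(v)))
        x = rng.standard_normal(layout.size)
        y = rng.standard_normal(layout.size)
        np.testing.assert_allclose(ap(2.0 * x - 0.5 * y),
                                   2.0 * ap(x) - 0.5 * ap(y), atol=1e-10)
        assert np.dot(x, ap(y)) == pytest.approx(np.dot(ap(x), y), abs=1e-9)

    def test_diagonal_matches_materialized_heff(self):
        table = hubbard_chain(2, 1.0, 4.0)
        mpo, state, envl, envr, psi2 = self.setup_problem(table, Sector(2, 0))
        layout = VectorLayout(psi2)
        diag = layout.to_flat(heff_diagonal(envl, envr, mpo.tensors[0],
                                            mpo.tensors[1], psi2))
        for j in range(layout.size):
            e = np.zeros(layout.size)
            e[j] = 1.0
            col = layout.to_flat(apply_heff(envl, envr, mpo.tensors[0],
                                            mpo.tensors[1],
                                            layout.from_flat(e)))
            assert col[j] == pytest.approx(diag[j], abs=1e-11)


class TestSweeps:
    def schedule(self, d, sweeps=10, tol=1e-10):
        return SweepSchedule([Stage(d, 1e-10)], max_sweeps=sweeps,
                             energy_tol=tol)

    def test_dimer_one_round_trip_hits_closed_form(self):
        table = hubbard_chain(2, 1.0, 4.0)
        mpo = build_mpo(table)
        state = random_mps(2, Sector(2, 0), d=4, seed=1)
        ledger = FlopLedger()
        state, _ = sweep(state, mpo, Stage(4, 1e-12), "right", ledger)
        state, rec = sweep(state, mpo, Stage(4, 1e-12), "left", ledger)
        assert rec.energy == pytest.approx(
            hubbard_dimer_singlet_energy(1.0, 4.0), abs=1e-8)

    def test_half_sweep_energies_non_increasing(self):
        table = random_cas(4, 4, seed=2)
        mpo = build_mpo(table)
        state = random_mps(4, Sector(4, 0), d=12, seed=4)
        ledger = FlopLedger()
        energies = []
        for s in range(6):
            direction = "right" if s % 2 == 0 else "left"
            state, rec = sweep(state, mpo, Stage(12, 1e-10), direction, ledger)
            energies.append(rec.energy)
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_run_dmrg_matches_fci_at_full_bond_dimension(self):
        table = random_cas(4, 4, seed=7)
        e, state, records, ledger = run_dmrg(table, Sector(4, 0),
                                             self.schedule(64), seed=2)
        ef, _ = fci_ground_state(table, 4, 0)
        assert e == pytest.approx(ef, abs=1e-9)
        assert e >= ef - 1e-9                      # variational bound

    def test_truncated_energies_monotone_in_cap(self):
        table = random_cas(4, 4, seed=3)
        ef, _ = fci_ground_state(table, 4, 0)
        energies = []
        for cap in (2, 4, 8, 64):
            e, *_ = run_dmrg(table, Sector(4, 0), self.schedule(cap), seed=5)
            energies.append(e)
            assert e >= ef - 1e-9
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_determinism_energies_and_ledger(self):
        table = random_cas(4, 4, seed=11)
        runs = []
        for _ in range(2):
            e, _, records, ledger = run_dmrg(table, Sector(4, 0),
                                             self.schedule(16, sweeps=6),
                                             seed=9)
            runs.append(([r.energy for r in records], ledger.as_dict()))
        for e1, e2 in zip(runs[0][0], runs[1][0]):
            assert abs(e1 - e2) < 1e-12
        assert runs[0][1] == runs[1][1]
        assert all(isinstance(v, int) for v in runs[0][1].values())

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            SweepSchedule([Stage(8), Stage(4)])
        with pytest.raises(ValueError, match="at least one"):
            SweepSchedule([])
        with pytest.raises(ValueError):
            SweepRecord(0, np.nan, 0.0, 1, 1, 0)
        with pytest.raises(ValueError):
            SweepRecord(0, -1.0, 0.0, 4, 2, 0)   # D_u1 below multiplet count


class TestBenchmark:
    def test_counts_deterministic_and_increasing_in_d(self):
        table = hubbard_chain(6, 1.0, 4.0)
        res1 = benchmark_sweep_cost(table, Sector(6, 0), [8, 16], seed=2,
                                    applies_per_bond=2)
        res2 = benchmark_sweep_cost(table, Sector(6, 0), [8, 16], seed=2,
                                    applies_per_bond=2)
        assert res1 == res2
        assert res1[1][1] > res1[0][1]

    def test_bulk_restriction_requires_long_chain(self):
        table = hubbard_chain(6, 1.0, 4.0)
        with pytest.raises(ValueError, match="too short"):
            benchmark_sweep_cost(table, Sector(6, 0), [64], seed=2,
                                 bulk_only=True)
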