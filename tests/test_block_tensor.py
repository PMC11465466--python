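"""Block-sparse tensor engine: conservation, contraction, factorization,
operation accounting — all checked against dense oracles."""

import numpy as np
import pytest

from spindmrg.block_tensor import (IN, OUT, Axis, BlockTensor, FlopLedger,
                                   contract, random_block_tensor, svd_split)
from spindmrg.symmetry import Sector


def two_leg_axes(rng=None):
    a = Axis.make(IN, {Sector(0, 0): 2, Sector(1, 1): 3})
    b = Axis.make(OUT, {Sector(0, 0): 2, Sector(1, 1): 3})
    return a, b


class TestConservation:
    def test_disallowed_block_rejected(self):
        a, b = two_leg_axes()
        t = BlockTensor([a, b])
        with pytest.raises(ValueError, match="conservation"):
            t.set_block((Sector(0, 0), Sector(1, 1)), np.zeros((2, 3)))

    def test_shape_mismatch_rejected(self):
        a, b = two_leg_axes()
        t = BlockTensor([a, b])
        with pytest.raises(ValueError, match="shape"):
            t.set_block((Sector(0, 0), Sector(0, 0)), np.zeros((2, 3)))

    def test_charged_tensor_allows_shifted_keys(self):
        a, b = two_leg_axes()
        t = BlockTensor([a, b], charge=(1, 1))
        t.set_block((Sector(1, 1), Sector(0, 0)), np.ones((3, 2)))
        assert t.key_is_allowed((Sector(1, 1), Sector(0, 0)))
        assert not t.key_is_allowed((Sector(0, 0), Sector(0, 0)))


class TestContract:
    def test_single_sector_matrix_multiply_flops(self):
        ax_in = Axis.make(IN, {Sector(0, 0): 2})
        ax_out = Axis.make(OUT, {Sector(0, 0): 2})
        a = BlockTensor([ax_in, ax_out])
        a.set_block((Sector(0, 0), Sector(0, 0)), np.eye(2))
        b = a.copy()
        ledger = FlopLedger()
        contract(a, b, [1], [0], ledger, "mm")
        assert ledger.total == 16                   # 2 * m * n * k = 2*2*2*2
        assert ledger.by_phase == {"mm": 16}

    def test_matches_dense_oracle(self, rng):
        ax1 = Axis.make(IN, {Sector(0, 0): 2, Sector(1, 1): 2})
        ax2 = Axis.make(OUT, {Sector(0, 0): 3, Sector(1, 1): 1})
        ax3 = Axis.make(IN, {Sector(0, 0): 3, Sector(1, 1): 1})
        ax4 = Axis.make(OUT, {Sector(0, 0): 2, Sector(2, 0): 2})
        a = random_block_tensor([ax1, ax2], (0, 0), rng)
        b = random_block_tensor([ax3, ax4], (0, 0), rng)
        res = contract(a, b, [1], [0])
        # dense path: sectors on the contracted axis share an embedding
        dense = np.einsum("ij,jk->ik", a.to_dense(), b.to_dense())
        np.testing.assert_allclose(res.to_dense(), dense, atol=1e-12)

    def test_identity_contraction_is_identity(self, rng):
        ax1 = Axis.make(IN, {Sector(0, 0): 2, Sector(1, 1): 3})
        ax2 = Axis.make(OUT, {Sector(0, 0): 2, Sector(1, 1): 3})
        t = random_block_tensor([ax1, ax2], (0, 0), rng)
        eye = BlockTensor([ax1, ax2])
        for sec, d in ax1.dims:
            eye.set_block((sec, sec), np.eye(d))
        res = contract(t, eye, [1], [0])
        for key, blk in t.blocks.items():
            np.testing.assert_allclose(res.blocks[key], blk, atol=1e-14)

    def test_direction_mismatch_raises(self, rng):
        ax1 = Axis.make(IN, {Sector(0, 0): 2})
        t = random_block_tensor([ax1, ax1.flipped()], (0, 0), rng)
        with pytest.raises(ValueError, match="opposite directions"):
            contract(t, t, [1], [1])

    def test_ledger_reproducible_integer(self, rng):
        ax1 = Axis.make(IN, {Sector(0, 0): 3, Sector(1, 1): 2})
        ax2 = Axis.make(OUT, {Sector(0, 0): 2, Sector(1, 1): 4})
        a = random_block_tensor([ax1, ax2], (0, 0), rng)
        b = random_block_tensor([ax2.flipped(), ax1.flipped()], (0, 0), rng)
        totals = []
        for _ in range(2):
            ledger = FlopLedger()
            contract(a, b, [1, 0], [0, 1], ledger)
            totals.append(ledger.total)
        assert totals[0] == totals[1]
        assert isinstance(totals[0], int) and totals[0] > 0


class TestSvdSplit:
    def make_tensor(self, rng):
        ax1 = Axis.make(IN, {Sector(0, 0): 3, Sector(1, 1): 2})
        ax2 = Axis.make(IN, {Sector(0, 0): 1, Sector(1, 1): 1})
        ax3 = Axis.make(OUT, {Sector(0, 0): 2, Sector(1, 1): 3,
                              Sector(2, 2): 2})
        return random_block_tensor([ax1, ax2, ax3], (0, 0), rng)

    def reconstruct(self, U, Vh):
        return contract(U, Vh, [U.ndim - 1], [0])

    def test_full_rank_reconstruction(self, rng):
        t = self.make_tensor(rng)
        U, svals, Vh, dw = svd_split(t, (0, 1))
        assert dw == pytest.approx(0.0, abs=1e-24)
        rec = self.reconstruct(U, Vh)
        for key, blk in t.blocks.items():
            np.testing.assert_allclose(rec.blocks[key], blk,
                                       atol=1e-12 * np.abs(blk).max())

    def test_rank_one_product_state_keeps_zero_weight(self):
        ax1 = Axis.make(IN, {Sector(1, 1): 3})
        ax2 = Axis.make(OUT, {Sector(1, 1): 4})
        t = BlockTensor([ax1, ax2])
        u = np.arange(1.0, 4.0)
        v = np.arange(1.0, 5.0)
        t.set_block((Sector(1, 1), Sector(1, 1)), np.outer(u, v))
        for cap in (1, 2, 5):
            _, _, _, dw = svd_split(t, (0,), d_max=cap)
            assert dw == pytest.approx(0.0, abs=1e-20)

    def test_discarded_weight_matches_dense_oracle(self, rng):
        t = self.make_tensor(rng)
        # oracle: pooled singular values of the untruncated factorization
        U, svals, Vh, _ = svd_split(t, (0, 1))
        all_sv = np.sort(np.concatenate(list(svals.values())))[::-1]
        for cap in range(1, len(all_sv) + 1):
            _, _, _, dw = svd_split(t, (0, 1), d_max=cap)
            expect = (all_sv[cap:] ** 2).sum() / (all_sv ** 2).sum()
            assert dw == pytest.approx(expect, abs=1e-12)

    def test_discarded_weight_monotone_in_cap(self, rng):
        t = self.make_tensor(rng)
        dws = [svd_split(t, (0, 1), d_max=cap)[3] for cap in range(1, 8)]
        assert all(a >= b - 1e-15 for a, b in zip(dws, dws[1:]))

    def test_weight_threshold_mode(self, rng):
        t = self.make_tensor(rng)
        thr = 0.05
        U, svals, Vh, dw = svd_split(t, (0, 1), weight_threshold=thr)
        assert dw <= thr
        n_kept = sum(len(s) for s in svals.values())
        # discarding one more state must overshoot the threshold
        _, _, _, dw2 = svd_split(t, (0, 1), d_max=n_kept - 1)
        assert dw2 > thr

    def test_absorb_left_gives_orthonormal_right_factor(self, rng):
        t = self.make_tensor(rng)
        U, _, Vh, _ = svd_split(t, (0, 1), absorb="left")
        gram = contract(Vh, Vh.flip(), [1], [1])
        for (s1, s2), blk in gram.blocks.items():
            if s1 == s2:
                np.testing.assert_allclose(blk, np.eye(blk.shape[0]),
                                           atol=1e-12)

    def test_empty_tensor_rejected(self):
        ax1 = Axis.make(IN, {Sector(0, 0): 2})
        t = BlockTensor([ax1, ax1.flipped()])
        with pytest.raises(ValueError, match="empty"):
            svd_split(t, (0,))


class TestDenseEquivalence:
    def test_scatter_then_contract_commutes(self, rng):
        # tensors under 100 total entries: dense and blocked paths agree
        ax1 = Axis.make(IN, {Sector(0, 0): 2, Sector(1, 1): 2})
        ax2 = Axis.make(OUT, {Sector(0, 0): 2, Sector(1, -1): 2})
        ax3 = Axis.make(IN, {Sector(0, 0): 2, Sector(1, -1): 2})
        ax4 = Axis.make(OUT, {Sector(1, 1): 2, Sector(2, 0): 2})
        for charge_a, charge_b in [((0, 0), (1, 1)), ((1, 1), (0, 0))]:
            a = random_block_tensor([ax1, ax2], charge_a, rng)
            b = random_block_tensor([ax3, ax4], charge_b, rng)
            res = contract(a, b, [1], [0])
            dense = a.to_dense() @ b.to_dense()
            np.testing.assert_allclose(res.to_dense(), dense, atol=1e-12)
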