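"""Matrix product states over spinful orbitals, and Hamiltonian MPOs.

An :class:`MPS` is the chain of order-3 site tensors A^{i_n} with shape
(D_{n-1}, 4, D_n); the boundary bonds are one-dimensional (vacuum on the
left, the target (N, 2Sz) sector on the right), so the first and last
tensors are effectively matrices.  Bond sectors carry the cumulative
quantum numbers of the sites to their left; the tensors conserve
q_left + q_phys = q_right blockwise.

The Hamiltonian MPO construction lives in :mod:`.mpo` and is re-exported
here (:func:`build_mpo`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .block_tensor import (IN, OUT, Axis, BlockTensor, FlopLedger, contract,
                           apply_axis_operator, svd_split)
from .mpo import (MPO, PHYS_SECTORS, S_MINUS, S_PLUS, build_mpo,  # noqa: F401
                  mpo_to_dense)
from .symmetry import SU2, U1, MultipletSpectrum, Sector

VACUUM = Sector(0, 0)

_PHYS_DIMS = {s: 1 for s in PHYS_SECTORS}


class TargetError(ValueError):
    """The requested (N, spin) target is not reachable on the chain."""


@dataclass
class MPS:
    """Matrix product state with a canonical-center gauge.

    ``target`` is the total (N, 2Sz) sector of the represented state —
    in spin-adapted runs the highest-weight component 2Sz = 2S.
    ``bond_spectra`` (filled by the spin-adapted solver) describes each
    internal bond as SU(2) multiplets.
    """

    tensors: List[BlockTensor]
    target: Sector
    mode: str = U1
    center: Optional[int] = None
    bond_spectra: List[Optional[MultipletSpectrum]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.tensors)

    def copy(self) -> "MPS":
        return MPS([t.copy() for t in self.tensors], self.target, self.mode,
                   self.center, list(self.bond_spectra))

    def bond_dims(self) -> List[int]:
        """Total (U(1)-state) dimension of each internal bond."""
        return [self.tensors[k].axes[2].total_dim for k in range(self.n_sites - 1)]

    def bond_axis(self, bond: int) -> Axis:
        """The axis of internal bond ``bond`` (between sites bond, bond+1)."""
        return self.tensors[bond].axes[2]

    def norm(self) -> float:
        return float(np.sqrt(max(overlap(self, self), 0.0)))

    def normalized(self) -> "MPS":
        out = self.copy()
        c = out.center if out.center is not None else 0
        out.tensors[c] = out.tensors[c] * (1.0 / out.norm())
        return out


def _site_tensor_axes(left_dims, right_dims) -> List[Axis]:
    return [Axis.make(IN, left_dims), Axis.make(IN, _PHYS_DIMS),
            Axis.make(OUT, right_dims)]


def occupation_sector(code: int) -> Sector:
    return PHYS_SECTORS[code]


def product_state_mps(occupations: Sequence[int], mode: str = U1) -> MPS:
    """Bond-dimension-1 determinant state from local occupation codes
    (0 empty, 1 up, 2 down, 3 doubly occupied)."""
    cum = VACUUM
    tensors = []
    for code in occupations:
        p = PHYS_SECTORS[code]
        nxt = Sector(cum.n + p.n, cum.spin2 + p.spin2)
        t = BlockTensor(_site_tensor_axes({cum: 1}, {nxt: 1}))
        t.set_block((cum, p, nxt), np.ones((1, 1, 1)))
        tensors.append(t)
        cum = nxt
    return MPS(tensors, cum, mode, center=0,
               bond_spectra=[None] * (len(occupations) - 1))


def _reachable_bond_sectors(n_orb: int, target: Sector, cap: int
                            ) -> List[Dict[Sector, int]]:
    """Per-bond sector->dimension maps of the full fusion tree, capped."""
    fwd: List[Dict[Sector, int]] = [{VACUUM: 1}]
    for _ in range(n_orb):
        nxt: Dict[Sector, int] = {}
        for sec, d in fwd[-1].items():
            for p in PHYS_SECTORS:
                s = Sector(sec.n + p.n, sec.spin2 + p.spin2)
                nxt[s] = min(nxt.get(s, 0) + d, cap)
        fwd.append(nxt)
    bwd: List[Dict[Sector, int]] = [{target: 1}]
    for _ in range(n_orb):
        nxt = {}
        for sec, d in bwd[-1].items():
            for p in PHYS_SECTORS:
                s = Sector(sec.n - p.n, sec.spin2 - p.spin2)
                nxt[s] = min(nxt.get(s, 0) + d, cap)
        bwd.append(nxt)
    bwd.reverse()
    out = []
    for k in range(n_orb + 1):
        common = {s: min(fwd[k][s], bwd[k][s])
                  for s in set(fwd[k]) & set(bwd[k])}
        if not common:
            raise TargetError(f"target {target} unreachable: no sectors at bond {k}")
        out.append(common)
    return out


def random_mps(n_orb: int, target: Sector, d: int, seed: int,
               mode: str = U1) -> MPS:
    """Seeded random right-canonical MPS in the target sector.

    In SU(2) mode the target spin label is 2S and the state is built
    spin-pure (total spin exactly S) by the spin-adapted layer.
    """
    if mode == SU2:
        from .spin_adapt import random_su2_mps
        return random_su2_mps(n_orb, target, d, seed)
    if not (0 <= target.n <= 2 * n_orb):
        raise TargetError(f"target {target} not reachable on {n_orb} orbitals")
    rng = np.random.default_rng(seed)
    bonds = _reachable_bond_sectors(n_orb, target, cap=max(d, 1))
    tensors = []
    for k in range(n_orb):
        t = BlockTensor(_site_tensor_axes(bonds[k], bonds[k + 1]))
        for key in t.allowed_keys():
            t.set_block(key, rng.standard_normal(t.block_shape(key)))
        tensors.append(t)
    state = MPS(tensors, target, mode, center=None,
                bond_spectra=[None] * (n_orb - 1))
    state = canonicalize(state, 0)
    nrm = state.norm()
    if nrm == 0.0:
        raise TargetError(f"target {target} unreachable on {n_orb} orbitals")
    state.tensors[0] = state.tensors[0] * (1.0 / nrm)
    return state


def sector_saturated_mps(n_orb: int, target: Sector, d: int, seed: int) -> MPS:
    """Random state whose bond bases fill every reachable symmetry sector
    in proportion to its full fusion rank ("saturated" structure).

    Ordinary truncation concentrates weight in few sectors at small D;
    this constructor instead allocates ``min(d, full rank)`` states per
    bond proportionally across sectors (largest-remainder rounding),
    which is the bond-basis structure of a large-D run where every
    sector is populated.  Used for cost benchmarking.
    """
    full = _reachable_bond_sectors(n_orb, target, cap=10 ** 7)
    bonds: List[Dict[Sector, int]] = []
    for k in range(n_orb + 1):
        ranks = full[k]
        total_full = sum(ranks.values())
        total = min(d, total_full) if 0 < k < n_orb else total_full
        quota = {q: total * r / total_full for q, r in ranks.items()}
        alloc = {q: int(np.floor(v)) for q, v in quota.items()}
        short = total - sum(alloc.values())
        order = sorted(quota, key=lambda q: (-(quota[q] - alloc[q]), q))
        for q in order[:short]:
            alloc[q] += 1
        bonds.append({q: min(v, ranks[q]) for q, v in alloc.items() if v > 0})
    rng = np.random.default_rng(seed)
    tensors = []
    for k in range(n_orb):
        t = BlockTensor(_site_tensor_axes(bonds[k], bonds[k + 1]))
        for key in t.allowed_keys():
            t.set_block(key, rng.standard_normal(t.block_shape(key)))
        tensors.append(t)
    state = MPS(tensors, target, U1, center=None,
                bond_spectra=[None] * (n_orb - 1))
    state = canonicalize(state, 0)
    nrm = state.norm()
    if nrm == 0:
        raise TargetError(f"target {target} unreachable on {n_orb} orbitals")
    state.tensors[0] = state.tensors[0] * (1.0 / nrm)
    return state


# -- gauge -----------------------------------------------------------------


def canonicalize(state: MPS, center: int) -> MPS:
    """Bring the chain into mixed-canonical form with the given center.

    Left of the center every tensor is a left isometry, right of it a
    right isometry; the physical state is unchanged.
    """
    if not 0 <= center < state.n_sites:
        raise ValueError(f"center {center} outside chain of {state.n_sites} sites")
    out = state.copy()
    start = out.center if out.center is not None else None
    lo = 0 if start is None else min(start, center)
    hi = out.n_sites - 1 if start is None else max(start, center)
    for k in range(lo, center):
        U, _, Vh, _ = svd_split(out.tensors[k], (0, 1), absorb="right")
        out.tensors[k] = U
        out.tensors[k + 1] = contract(Vh, out.tensors[k + 1], [1], [0])
    for k in range(hi, center, -1):
        U, _, Vh, _ = svd_split(out.tensors[k], (0,), absorb="left")
        out.tensors[k] = Vh
        out.tensors[k - 1] = contract(out.tensors[k - 1], U, [2], [0])
    out.center = center
    return out


def overlap(a: MPS, b: MPS) -> float:
    """<a|b> via the transfer contraction (real tensors)."""
    if a.n_sites != b.n_sites:
        raise ValueError("length mismatch")
    env: Optional[BlockTensor] = None
    for ka, kb in zip(a.tensors, b.tensors):
        bra = ka.flip()
        if env is None:
            env = contract(bra, kb, [0, 1], [0, 1])   # (bra_r IN, ket_r OUT)
        else:
            tmp = contract(env, kb, [1], [0])          # (bra_r, p, r)
            env = contract(bra, tmp, [0, 1], [0, 1])
    tot = 0.0
    for blk in env.blocks.values():
        tot += float(blk.reshape(-1).sum())
    return tot


def expectation(state: MPS, op: MPO, ledger: Optional[FlopLedger] = None) -> float:
    """<psi|H|psi> as a real scalar (states are kept normalized).

    The contraction cost is tallied under phase ``"expectation"``.
    """
    if state.n_sites != op.n_orb:
        raise ValueError(f"state has {state.n_sites} sites, operator {op.n_orb}")
    env = _left_edge(state)
    for k in range(state.n_sites):
        env = _env_step_left(env, state.tensors[k], op.tensors[k], ledger,
                             phase="expectation")
    tot = 0.0
    for blk in env.blocks.values():
        tot += float(blk.reshape(-1).sum())
    return tot


def _left_edge(state: MPS) -> BlockTensor:
    """Left boundary environment with axes (bra IN, mpo OUT, ket OUT)."""
    lax = state.tensors[0].axes[0]
    env = BlockTensor([Axis.make(IN, lax.dim_map),
                       Axis.make(OUT, {VACUUM: 1}),
                       Axis.make(OUT, lax.dim_map)])
    for sec, d in lax.dims:
        env.set_block((sec, VACUUM, sec), np.eye(d).reshape(d, 1, d))
    return env


def _right_edge(state: MPS) -> BlockTensor:
    """Right boundary environment with axes (bra OUT, mpo IN, ket IN)."""
    rax = state.tensors[-1].axes[2]
    env = BlockTensor([Axis.make(OUT, rax.dim_map),
                       Axis.make(IN, {VACUUM: 1}),
                       Axis.make(IN, rax.dim_map)])
    for sec, d in rax.dims:
        env.set_block((sec, VACUUM, sec), np.eye(d).reshape(d, 1, d))
    return env


def _env_step_left(env: BlockTensor, a: BlockTensor, w: BlockTensor,
                   ledger: Optional[FlopLedger], phase: str) -> BlockTensor:
    """Grow a left environment (bra, mpo, ket) by one site."""
    t1 = contract(env, a, [2], [0], ledger, phase)          # (bra, w, p, r)
    t2 = contract(t1, w, [1, 2], [0, 2], ledger, phase)     # (bra, r, pbra, wr)
    bra = a.flip()
    t3 = contract(bra, t2, [0, 1], [0, 2], ledger, phase)   # (bra_r, ket_r, wr)
    return t3.transpose((0, 2, 1))


def _env_step_right(env: BlockTensor, a: BlockTensor, w: BlockTensor,
                    ledger: Optional[FlopLedger], phase: str) -> BlockTensor:
    """Grow a right environment (bra, mpo, ket) by one site leftwards."""
    t1 = contract(a, env, [2], [2], ledger, phase)          # (l, p, bra, w)
    t2 = contract(t1, w, [1, 3], [2, 3], ledger, phase)     # (l, bra, wl, pbra)
    bra = a.flip()
    t3 = contract(bra, t2, [1, 2], [3, 1], ledger, phase)   # (bra_l, ket_l, wl)
    return t3.transpose((0, 2, 1))


def truncate_bond(state: MPS, bond: int,
                  d_max: Optional[int] = None,
                  weight_threshold: Optional[float] = None,
                  ledger: Optional[FlopLedger] = None) -> Tuple[MPS, float]:
    """Truncate one bond to at most ``d_max`` states (U(1) counting).

    The chain is first brought to mixed-canonical form with the center
    adjacent to the bond, so the discarded weight is the exact reduced
    density-matrix weight; the state norm is restored to 1 afterwards.
    """
    if not 0 <= bond < state.n_sites - 1:
        raise ValueError(f"bond {bond} out of range")
    out = canonicalize(state, bond)
    theta = contract(out.tensors[bond], out.tensors[bond + 1],
                     [2], [0], ledger, "truncate")
    U, _, Vh, dw = svd_split(theta, (0, 1), d_max=d_max,
                             weight_threshold=weight_threshold,
                             ledger=ledger)
    nrm = Vh.norm()
    out.tensors[bond] = U
    out.tensors[bond + 1] = Vh * (1.0 / nrm) if nrm > 0 else Vh
    out.center = bond + 1
    return out, dw


# -- chain arithmetic (used by the spin-adapted layer) --------------------


def mps_add(states: Sequence[MPS]) -> MPS:
    """Direct-sum superposition of states with a common target sector."""
    if not states:
        raise ValueError("empty sum")
    n = states[0].n_sites
    target = states[0].target
    for s in states[1:]:
        if s.n_sites != n or s.target != target:
            raise ValueError("summands live on different chains/targets")
    return _direct_sum(states, merge_boundaries=True)


def mps_stack(states: Sequence[MPS]) -> MPS:
    """Direct sum keeping each component's right-boundary sector.

    The result is a chain-shaped isometry bundle (its right boundary can
    span several sectors); used to build multiplet-complete bond bases.
    """
    return _direct_sum(states, merge_boundaries=False)


def _direct_sum(states: Sequence[MPS], merge_boundaries: bool) -> MPS:
    n = states[0].n_sites
    out_tensors: List[BlockTensor] = []
    for k in range(n):
        parts = [s.tensors[k] for s in states]
        left_off: List[Dict[Sector, int]] = []
        right_off: List[Dict[Sector, int]] = []
        ldims: Dict[Sector, int] = {}
        rdims: Dict[Sector, int] = {}
        for t in parts:
            if k == 0:
                left_off.append({sec: 0 for sec, _ in t.axes[0].dims})
                for sec, d in t.axes[0].dims:
                    ldims[sec] = max(ldims.get(sec, 0), d)
            else:
                off = {}
                for sec, d in t.axes[0].dims:
                    off[sec] = ldims.get(sec, 0)
                    ldims[sec] = ldims.get(sec, 0) + d
                left_off.append(off)
            if k == n - 1 and merge_boundaries:
                right_off.append({sec: 0 for sec, _ in t.axes[2].dims})
                for sec, d in t.axes[2].dims:
                    rdims[sec] = max(rdims.get(sec, 0), d)
            else:
                off = {}
                for sec, d in t.axes[2].dims:
                    off[sec] = rdims.get(sec, 0)
                    rdims[sec] = rdims.get(sec, 0) + d
                right_off.append(off)
        if any(t.axes[1] != parts[0].axes[1] for t in parts[1:]):
            raise ValueError("summands disagree on the local basis")
        new = BlockTensor((Axis.make(IN, ldims), parts[0].axes[1],
                           Axis.make(OUT, rdims)))
        for i, t in enumerate(parts):
            for key, blk in t.blocks.items():
                lsec, psec, rsec = key
                lo = left_off[i][lsec]
                ro = right_off[i][rsec]
                if key not in new.blocks:
                    new.blocks[key] = np.zeros(new.block_shape(key))
                new.blocks[key][lo:lo + blk.shape[0], :, ro:ro + blk.shape[2]] += blk
        out_tensors.append(new)
    return MPS(out_tensors, states[0].target, states[0].mode, center=None,
               bond_spectra=[None] * (n - 1))


def _relabel_axis(t: BlockTensor, axis: int, delta: Tuple[int, int]) -> BlockTensor:
    ax = t.axes[axis]
    new_ax = Axis.make(ax.direction,
                       {Sector(s.n + delta[0], s.spin2 + delta[1]): d
                        for s, d in ax.dims})
    # relabeling shifts the conservation sum by direction * delta
    charge = (t.charge[0] + ax.direction * delta[0],
              t.charge[1] + ax.direction * delta[1])
    out = BlockTensor(t.axes[:axis] + (new_ax,) + t.axes[axis + 1:], charge)
    for key, blk in t.blocks.items():
        s = key[axis]
        nk = key[:axis] + (Sector(s.n + delta[0], s.spin2 + delta[1]),) + key[axis + 1:]
        out.blocks[nk] = blk.copy()
    return out


def apply_site_spin_lowering(state: MPS, site: int) -> MPS:
    """s^-, applied at one site; bond labels right of the site are shifted
    so the result is again a well-formed MPS with 2Sz lowered by 2."""
    out = state.copy()
    op_blocks = {}
    for i in range(4):
        for j in range(4):
            if abs(S_MINUS[i, j]) > 1e-14:
                op_blocks[(PHYS_SECTORS[i], PHYS_SECTORS[j])] = \
                    np.array([[S_MINUS[i, j]]])
    t = apply_axis_operator(out.tensors[site], 1, op_blocks, new_dims=_PHYS_DIMS)
    t = _relabel_axis(t, 2, (0, -2))
    assert t.charge == (0, 0)
    out.tensors[site] = t
    for k in range(site + 1, out.n_sites):
        tk = _relabel_axis(out.tensors[k], 0, (0, -2))
        tk = _relabel_axis(tk, 2, (0, -2))
        out.tensors[k] = tk
    out.target = Sector(out.target.n, out.target.spin2 - 2)
    out.center = None
    return out


def apply_total_spin_lowering(state: MPS, compress_tol: float = 1e-12) -> MPS:
    """S_total^- |psi> as an exact MPS (sum of one-site lowerings),
    compacted by a lossless rank-revealing sweep."""
    parts = []
    for k in range(state.n_sites):
        lowered = apply_site_spin_lowering(state, k)
        if any(np.abs(b).max() > 1e-14 for b in lowered.tensors[k].blocks.values()):
            parts.append(lowered)
    if not parts:
        raise ValueError("state is annihilated by S^- (lowest-weight component)")
    total = mps_add(parts)
    total = canonicalize(total, 0)
    return total


def to_statevector(state: MPS) -> np.ndarray:
    """Dense amplitude vector in occupation order (site 0 slowest), with
    local basis (empty, up, down, double).  Test-scale utility."""
    n = state.n_sites
    if 4 ** n > 2 ** 16:
        raise ValueError("dense conversion limited to small chains")
    sec_order = sorted(range(4), key=lambda i: PHYS_SECTORS[i])
    inv = np.argsort(sec_order)
    cur = None
    for t in state.tensors:
        d = t.to_dense()            # (Dl, 4, Dr), phys in sector-sorted order
        d = d[:, inv, :]
        if cur is None:
            cur = d
        else:
            cur = np.tensordot(cur, d, axes=(cur.ndim - 1, 0))
    return cur[0, ..., 0].reshape(-1)
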