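"""SU(2) spin adaptation of the DMRG sweep via singlet embedding.

To target total spin S the chain is extended by one auxiliary
"spectator" site carrying a single spin-S multiplet (local sectors
(0, 2m), m = -S..S) on which the Hamiltonian acts as the identity.  The
solver then optimizes the *total singlet* of physical chain plus
spectator: coupling the physical state to the spin-S spectator into a
singlet forces the physical total spin to be exactly S, and the
physical energy is untouched because the spectator is inert.

Working with a global singlet makes the spin bookkeeping exact and
local:

* **Ladder environments.**  The matrix elements of the left-part and
  right-part spin-lowering operators in the current bond bases are
  carried along the sweep by transfer-matrix recursion.  They give an
  exact total-S^2 operator on every two-site variational space as long
  as each bond basis is closed under the ladder action, i.e. consists
  of complete multiplets.

* **Spin projection in Davidson.**  Every Davidson vector is projected
  onto the total-singlet eigenspace with a Löwdin product over the
  other total-spin values, so the optimization never leaves the
  spin-pure manifold.

* **Multiplet-complete truncation.**  For a global singlet the reduced
  density matrix of either side of a bond commutes with that side's
  spin operators, so its eigenvectors organize into complete
  multiplets.  The highest-weight members are extracted per sector as
  the kernel of the part-raising operator, their partners are generated
  by exact ladder lowering, and truncation keeps whole multiplets
  ranked by density-matrix weight.  The bond dimension D counts SU(2)
  multiplets; recorded spectra convert to D_U(1) through the (2S+1)
  rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg as sla

from .block_tensor import (IN, OUT, Axis, BlockTensor, contract,
                           apply_axis_operator)
from .mpo import MPO, PHYS_SECTORS, S_MINUS, S_PLUS
from .mps_mpo import (MPS, TargetError, apply_total_spin_lowering,
                      canonicalize, mps_add, product_state_mps)
from .symmetry import SU2, MultipletSpectrum, Sector

OpBlocks = Dict[Tuple[Sector, Sector], np.ndarray]

_PHYS_DIMS = {s: 1 for s in PHYS_SECTORS}


def _local_op_blocks(mat: np.ndarray) -> OpBlocks:
    out: OpBlocks = {}
    for i in range(4):
        for j in range(4):
            if abs(mat[i, j]) > 1e-14:
                out[(PHYS_SECTORS[i], PHYS_SECTORS[j])] = np.array([[mat[i, j]]])
    return out


SMINUS_LOCAL = _local_op_blocks(S_MINUS)
SPLUS_LOCAL = _local_op_blocks(S_PLUS)


def aux_sectors(two_s: int) -> Dict[Sector, int]:
    """Local sectors of the spin-S spectator site."""
    return {Sector(0, m2): 1 for m2 in range(-two_s, two_s + 1, 2)}


def aux_lowering(two_s: int) -> OpBlocks:
    """S^- on the spectator multiplet."""
    out: OpBlocks = {}
    s = two_s / 2.0
    for m2 in range(-two_s + 2, two_s + 1, 2):
        m = m2 / 2.0
        fac = sqrt(s * (s + 1.0) - m * (m - 1.0))
        out[(Sector(0, m2 - 2), Sector(0, m2))] = np.array([[fac]])
    return out


def op_transpose(op: OpBlocks) -> OpBlocks:
    return {(c, r): m.T.copy() for (r, c), m in op.items()}


def _apply_ladder(t: BlockTensor, ops: Sequence[Tuple[int, OpBlocks]]
                  ) -> BlockTensor:
    """Sum of single-axis ladder applications, staying in the same bond
    bases (requires ladder-closed bases)."""
    acc: Optional[BlockTensor] = None
    for axis, blocks in ops:
        if not blocks:
            continue
        r = apply_axis_operator(t, axis, blocks,
                                new_dims=t.axes[axis].dim_map)
        acc = r if acc is None else acc + r
    if acc is None:
        raise ValueError("ladder application with no active operators")
    return acc


# -- ladder-environment recursions ----------------------------------------


def _extract_matrix(t2: BlockTensor) -> OpBlocks:
    return {(k[0], k[1]): blk.copy() for k, blk in t2.blocks.items()
            if np.abs(blk).max(initial=0.0) > 1e-14}


def ladder_step_left(lm: OpBlocks, tensor: BlockTensor,
                     local_minus: OpBlocks = SMINUS_LOCAL) -> OpBlocks:
    """Left-part S^- on the next bond basis, from a left-isometric tensor."""
    acc: Optional[BlockTensor] = None
    bra = tensor.flip()
    if lm:
        tm = apply_axis_operator(tensor, 0, lm, new_dims=tensor.axes[0].dim_map)
        acc = contract(bra, tm, [0, 1], [0, 1])
    if local_minus:
        tm = apply_axis_operator(tensor, 1, local_minus,
                                 new_dims=tensor.axes[1].dim_map)
        r = contract(bra, tm, [0, 1], [0, 1])
        acc = r if acc is None else acc + r
    return _extract_matrix(acc) if acc is not None else {}


def ladder_step_right(rm_next: OpBlocks, tensor: BlockTensor,
                      local_minus: OpBlocks = SMINUS_LOCAL) -> OpBlocks:
    """Right-part S^- on the previous bond basis, from a right isometry."""
    acc: Optional[BlockTensor] = None
    bra = tensor.flip()
    if rm_next:
        tm = apply_axis_operator(tensor, 2, rm_next,
                                 new_dims=tensor.axes[2].dim_map)
        acc = contract(bra, tm, [1, 2], [1, 2])
    if local_minus:
        tm = apply_axis_operator(tensor, 1, local_minus,
                                 new_dims=tensor.axes[1].dim_map)
        r = contract(bra, tm, [1, 2], [1, 2])
        acc = r if acc is None else acc + r
    return _extract_matrix(acc) if acc is not None else {}


# -- part spaces (bond x site or site x bond) ------------------------------


@dataclass
class _Combo:
    secs: Tuple[Sector, Sector]
    dims: Tuple[int, int]
    offset: int

    @property
    def size(self) -> int:
        return self.dims[0] * self.dims[1]


class _PartSpace:
    """The product of two legs (one bond, one physical), grouped by the
    part charge, with dense part-ladder matrices per group.

    The "part spin projection" of a group ``g`` is ``sign * g.spin2``:
    +1 for a left part labelled by its own cumulative charge, -1 for a
    right part of the global singlet (whose Sz is minus the cumulative
    label).
    """

    def __init__(self, ax_a: Axis, ax_b: Axis,
                 sign_a: int, sign_b: int,
                 raise_a: OpBlocks, raise_b: OpBlocks,
                 lower_a: OpBlocks, lower_b: OpBlocks,
                 raise_group_delta: int, part_spin2_sign: int):
        self.sign = (sign_a, sign_b)
        self.raise_ops = (raise_a, raise_b)
        self.lower_ops = (lower_a, lower_b)
        self.raise_group_delta = raise_group_delta
        self.part_spin2_sign = part_spin2_sign
        self.groups: Dict[Sector, List[_Combo]] = {}
        self.combo_index: Dict[Tuple[Sector, Sector], _Combo] = {}
        for sa, da in ax_a.dims:
            for sb, db in ax_b.dims:
                g = self.group_of(sa, sb)
                combos = self.groups.setdefault(g, [])
                off = sum(c.size for c in combos)
                c = _Combo((sa, sb), (da, db), off)
                combos.append(c)
                self.combo_index[(sa, sb)] = c

    def group_of(self, sa: Sector, sb: Sector) -> Sector:
        return Sector(self.sign[0] * sa.n + self.sign[1] * sb.n,
                      self.sign[0] * sa.spin2 + self.sign[1] * sb.spin2)

    def group_dim(self, g: Sector) -> int:
        return sum(c.size for c in self.groups.get(g, ()))

    def part_spin2(self, g: Sector) -> int:
        return self.part_spin2_sign * g.spin2

    def ladder_matrix(self, g: Sector, kind: str) -> Tuple[np.ndarray, Sector]:
        """Dense part-ladder matrix from group ``g``; kind '+' or '-'."""
        delta = self.raise_group_delta if kind == "+" else -self.raise_group_delta
        g2 = Sector(g.n, g.spin2 + delta)
        src = self.groups.get(g, [])
        nsrc = self.group_dim(g)
        ndst = self.group_dim(g2)
        M = np.zeros((ndst, nsrc))
        ops = self.raise_ops if kind == "+" else self.lower_ops
        for c in src:
            sa, sb = c.secs
            da, db = c.dims
            for (ra, ca), mat in ops[0].items():
                if ca != sa:
                    continue
                tgt = self.combo_index.get((ra, sb))
                if tgt is None or self.group_of(ra, sb) != g2:
                    continue
                M[tgt.offset:tgt.offset + tgt.size,
                  c.offset:c.offset + c.size] += np.kron(mat, np.eye(db))
            for (rb, cb), mat in ops[1].items():
                if cb != sb:
                    continue
                tgt = self.combo_index.get((sa, rb))
                if tgt is None or self.group_of(sa, rb) != g2:
                    continue
                M[tgt.offset:tgt.offset + tgt.size,
                  c.offset:c.offset + c.size] += np.kron(np.eye(da), mat)
        return M, g2


# -- the sweep-side context ------------------------------------------------


class SpinAdaptedContext:
    """Ladder bookkeeping shared between the solver's sweeps.

    Operates on the singlet-embedded chain of ``n_sites`` = n_orb + 1
    tensors; ``lm[k]``/``rm[k]`` hold the left-part/right-part
    spin-lowering matrix on the bond-k basis (bond k sits left of site
    k).  The last site is the spectator with its own ladder matrices.
    """

    def __init__(self, two_s: int, n_orb: int, n_elec: int):
        self.two_s = two_s
        self.n_orb = n_orb
        self.n_sites = n_orb + 1
        self.n_elec = n_elec
        # largest total spin reachable at Sz = 0 (physical + spectator)
        self.two_s_max = min(n_elec, 2 * n_orb - n_elec) + two_s
        self.lm: List[OpBlocks] = [{} for _ in range(self.n_sites + 1)]
        self.rm: List[OpBlocks] = [{} for _ in range(self.n_sites + 1)]
        self.aux_minus = aux_lowering(two_s)

    def local_minus(self, site: int) -> OpBlocks:
        return self.aux_minus if site == self.n_sites - 1 else SMINUS_LOCAL

    # environment upkeep ---------------------------------------------------

    def prepare_sweep(self, state: MPS, direction: str) -> None:
        n = state.n_sites
        if direction == "right":
            self.rm[n] = {}
            for k in range(n - 1, 0, -1):
                self.rm[k] = ladder_step_right(self.rm[k + 1], state.tensors[k],
                                               self.local_minus(k))
            self.lm[0] = {}
        else:
            self.lm[0] = {}
            for k in range(0, n - 1):
                self.lm[k + 1] = ladder_step_left(self.lm[k], state.tensors[k],
                                                  self.local_minus(k))
            self.rm[n] = {}

    def advance(self, state: MPS, bond: int, direction: str) -> None:
        if direction == "right":
            self.lm[bond + 1] = ladder_step_left(self.lm[bond],
                                                 state.tensors[bond],
                                                 self.local_minus(bond))
        else:
            self.rm[bond + 1] = ladder_step_right(self.rm[bond + 2],
                                                  state.tensors[bond + 1],
                                                  self.local_minus(bond + 1))

    # spin algebra on the two-site space -----------------------------------

    def _two_site_ops(self, k: int):
        m1 = self.local_minus(k)
        m2 = self.local_minus(k + 1)
        minus = [(0, self.lm[k]), (1, m1), (2, m2), (3, self.rm[k + 2])]
        plus = [(0, op_transpose(self.lm[k])), (1, op_transpose(m1)),
                (2, op_transpose(m2)), (3, op_transpose(self.rm[k + 2]))]
        return minus, plus

    def apply_s2(self, t: BlockTensor, k: int) -> BlockTensor:
        """Total S^2 on a two-site tensor of the Sz = 0 embedded chain."""
        minus, plus = self._two_site_ops(k)
        return _apply_ladder(_apply_ladder(t, plus), minus)

    def project_spin(self, t: BlockTensor, k: int) -> BlockTensor:
        """Löwdin projector onto the total singlet on the two-site space."""
        minus, plus = self._two_site_ops(k)
        v = t
        for two_sp in range(2, self.two_s_max + 1, 2):
            cp = (two_sp / 2.0) * (two_sp / 2.0 + 1.0)
            s2v = _apply_ladder(_apply_ladder(v, plus), minus)
            v = (s2v - cp * v) * (1.0 / (0.0 - cp))
        return v

    def projector(self, k: int, layout):
        def proj(vec: np.ndarray) -> np.ndarray:
            t = layout.from_flat(vec)
            if not t.blocks:
                return np.zeros_like(vec)
            return layout.to_flat(self.project_spin(t, k))
        return proj

    # multiplet-complete truncation ----------------------------------------

    def split(self, psi: BlockTensor, k: int, direction: str, d_max: int,
              state: MPS) -> Tuple[BlockTensor, BlockTensor, float]:
        """Split the optimized two-site singlet tensor with whole-multiplet
        truncation; records the bond spectrum on ``state``."""
        if direction == "right":
            rho = contract(psi, psi.flip(), [2, 3], [2, 3])
            space = _PartSpace(psi.axes[0], psi.axes[1], +1, +1,
                               op_transpose(self.lm[k]),
                               op_transpose(self.local_minus(k)),
                               self.lm[k], self.local_minus(k),
                               raise_group_delta=+2, part_spin2_sign=+1)
        else:
            rho = contract(psi, psi.flip(), [0, 1], [0, 1])
            # right part of the singlet: Sz = -(cumulative label)
            space = _PartSpace(psi.axes[2], psi.axes[3], -1, +1,
                               op_transpose(self.local_minus(k + 1)),
                               op_transpose(self.rm[k + 2]),
                               self.local_minus(k + 1), self.rm[k + 2],
                               raise_group_delta=-2, part_spin2_sign=-1)

        dense_rho: Dict[Sector, np.ndarray] = {}
        for g, combos in space.groups.items():
            dim = space.group_dim(g)
            if dim:
                dense_rho[g] = np.zeros((dim, dim))
        for key, blk in rho.blocks.items():
            row, col = key[:2], key[2:]
            cr = space.combo_index.get(row)
            cc = space.combo_index.get(col)
            if cr is None or cc is None:
                continue
            g = space.group_of(*row)
            if space.group_of(*col) != g:
                continue
            dense_rho[g][cr.offset:cr.offset + cr.size,
                         cc.offset:cc.offset + cc.size] += \
                blk.reshape(cr.size, cc.size)

        total_weight = sum(np.trace(m) for m in dense_rho.values())
        found = []   # (weight, group, highest-weight vector)
        for g in sorted(dense_rho):
            two_sp = space.part_spin2(g)
            if two_sp < 0:
                continue
            plus_mat, _ = space.ladder_matrix(g, "+")
            if plus_mat.shape[0] == 0:
                K = np.eye(space.group_dim(g))
            else:
                K = sla.null_space(plus_mat, rcond=1e-10)
            if K.shape[1] == 0:
                continue
            sub = K.T @ dense_rho[g] @ K
            sub = 0.5 * (sub + sub.T)
            w, vecs = np.linalg.eigh(sub)
            for i in range(len(w) - 1, -1, -1):
                if w[i] > 1e-28:
                    found.append((float(w[i]), g, K @ vecs[:, i]))
        found.sort(key=lambda e: (-e[0], e[1]))
        kept = found[:d_max]
        kept_weight = sum((space.part_spin2(g) + 1) * w for w, g, _ in kept)
        dw = 1.0 - kept_weight / total_weight if total_weight > 0 else 0.0

        # generate multiplet partners by exact lowering
        members: Dict[Sector, List[np.ndarray]] = {}
        spectrum_entries = []
        for w, g, vec in kept:
            two_sp = space.part_spin2(g)
            spectrum_entries.append((two_sp, 1))
            sp = two_sp / 2.0
            cur_g, cur = g, vec
            members.setdefault(cur_g, []).append(cur)
            for j in range(two_sp):
                mp = sp - j
                fac = sp * (sp + 1.0) - mp * (mp - 1.0)
                low_mat, g_dn = space.ladder_matrix(cur_g, "-")
                cur = (low_mat @ cur) / sqrt(fac)
                cur_g = g_dn
                members.setdefault(cur_g, []).append(cur)

        # per-sector symmetric orthonormalization (numerical safety)
        iso_cols: Dict[Sector, np.ndarray] = {}
        for g, cols in members.items():
            V = np.column_stack(cols)
            G = V.T @ V
            dev = np.abs(G - np.eye(G.shape[0])).max()
            if dev > 1e-6:
                raise AssertionError(
                    f"multiplet basis lost orthonormality ({dev:.2e}) at bond {k}")
            V = V @ np.linalg.inv(sla.sqrtm(G).real)
            iso_cols[g] = V

        bond_dims = {}
        if direction == "right":
            bond_dims = {g: V.shape[1] for g, V in iso_cols.items()}
            iso = BlockTensor((psi.axes[0], psi.axes[1],
                               Axis.make(OUT, bond_dims)))
            for g, V in iso_cols.items():
                for c in space.groups[g]:
                    sub = V[c.offset:c.offset + c.size, :]
                    if np.abs(sub).max(initial=0.0) < 1e-14:
                        continue
                    iso.set_block((c.secs[0], c.secs[1], g),
                                  sub.reshape(c.dims[0], c.dims[1], V.shape[1]))
            center = contract(iso.flip(), psi, [0, 1], [0, 1])
            nrm = center.norm()
            if nrm > 0:
                center = center * (1.0 / nrm)
            left_t, right_t = iso, center
        else:
            # cumulative bond label q of a member satisfies q + p = r, i.e.
            # it equals the group charge g = r - p
            def bond_sec(g: Sector) -> Sector:
                return g
            bond_dims = {bond_sec(g): V.shape[1] for g, V in iso_cols.items()}
            iso = BlockTensor((Axis.make(IN, bond_dims), psi.axes[2],
                               psi.axes[3]))
            for g, V in iso_cols.items():
                for c in space.groups[g]:
                    sub = V[c.offset:c.offset + c.size, :]
                    if np.abs(sub).max(initial=0.0) < 1e-14:
                        continue
                    iso.set_block((bond_sec(g), c.secs[0], c.secs[1]),
                                  sub.reshape(c.dims[0], c.dims[1], V.shape[1])
                                  .transpose(2, 0, 1))
            center = contract(psi, iso.flip(), [2, 3], [1, 2])
            nrm = center.norm()
            if nrm > 0:
                center = center * (1.0 / nrm)
            left_t, right_t = center, iso
        state.bond_spectra[k] = MultipletSpectrum(spectrum_entries)
        return left_t, right_t, float(max(dw, 0.0))


# -- singlet embedding plumbing -------------------------------------------


def embed_mpo(op: MPO, two_s: int) -> MPO:
    """Extend an MPO by an identity tensor on the spectator site."""
    last_axis = op.tensors[-1].axes[3]
    aux = BlockTensor((Axis.make(IN, last_axis.dim_map),
                       Axis.make(IN, aux_sectors(two_s)),
                       Axis.make(OUT, aux_sectors(two_s)),
                       Axis.make(OUT, last_axis.dim_map)))
    for wsec, wd in last_axis.dims:
        for psec in aux_sectors(two_s):
            aux.set_block((wsec, psec, psec, wsec),
                          np.eye(wd).reshape(wd, 1, 1, wd))
    return MPO(op.tensors + [aux], op.n_orb + 1, op.bond_dims + [last_axis.total_dim],
               op.term_count)


def su2_reference_occupations(n_orb: int, n_elec: int, two_s: int) -> List[int]:
    n_paired = (n_elec - two_s) // 2
    if n_paired < 0 or n_paired + two_s > n_orb:
        raise TargetError(f"target (N={n_elec}, 2S={two_s}) not reachable "
                          f"on {n_orb} orbitals")
    return [3] * n_paired + [1] * two_s + [0] * (n_orb - n_paired - two_s)


def _attach_aux(phys: MPS, two_s: int, aux_m2: int, coeff: float) -> MPS:
    """Append the spectator site in state |S, m> to a physical chain."""
    bound = phys.tensors[-1].axes[2]
    (bsec, _), = bound.dims
    t = BlockTensor((Axis.make(IN, bound.dim_map),
                     Axis.make(IN, aux_sectors(two_s)),
                     Axis.make(OUT, {Sector(bsec.n, bsec.spin2 + aux_m2): 1})))
    t.set_block((bsec, Sector(0, aux_m2), Sector(bsec.n, bsec.spin2 + aux_m2)),
                np.full((1, 1, 1), coeff))
    out = MPS([x.copy() for x in phys.tensors] + [t],
              Sector(bsec.n, bsec.spin2 + aux_m2), SU2, center=None,
              bond_spectra=[None] * phys.n_sites)
    return out


def closure_state(n_orb: int, n_elec: int, two_s: int) -> MPS:
    """Exact singlet embedding of the high-spin reference determinant.

    The determinant with all singles up is an exact S = Sz = S
    eigenstate; its projection partners |S, m> are generated by exact
    total-S^- application, each is paired with the spectator state
    |S, -m> with the singlet Clebsch-Gordan weight
    (-1)^(S-m)/sqrt(2S+1), and the sum is canonicalized.  The resulting
    bond bases are spans of an exact singlet's Schmidt vectors, hence
    multiplet-complete from the start.
    """
    occ = su2_reference_occupations(n_orb, n_elec, two_s)
    phys = product_state_mps(occ, mode=SU2)
    comps = []
    cur = phys
    for j in range(two_s + 1):
        m2 = two_s - 2 * j          # 2m of the physical component
        sign = -1.0 if ((two_s - m2) // 2) % 2 else 1.0
        coeff = sign / sqrt(two_s + 1.0)
        comps.append(_attach_aux(cur, two_s, -m2, coeff))
        if j < two_s:
            cur = apply_total_spin_lowering(cur)
            cur = canonicalize(cur, 0)
            cur.tensors[0] = cur.tensors[0] * (1.0 / cur.norm())
    state = comps[0] if len(comps) == 1 else mps_add(comps)
    # the round trip trims the direct-sum bond bases to the exact Schmidt
    # support of the singlet, which is guaranteed multiplet-complete; a
    # single pass would keep spectator directions with no support on the
    # other side of the bond, breaking ladder closure
    state = canonicalize(canonicalize(state, state.n_sites - 1), 0)
    nrm = state.norm()
    if not np.isclose(nrm, 1.0, atol=1e-8):
        raise AssertionError(f"singlet construction lost norm: {nrm}")
    state.tensors[0] = state.tensors[0] * (1.0 / nrm)
    state.mode = SU2
    return state


def random_su2_mps(n_orb: int, target: Sector, d: int, seed: int) -> MPS:
    """Seeded spin-pure starting state on the singlet-embedded chain: the
    closure bases of the high-spin reference with a randomized,
    singlet-projected center tensor."""
    n_elec, two_s = target.n, target.spin2
    if not (0 <= n_elec <= 2 * n_orb) or two_s < 0 \
            or two_s > min(n_elec, 2 * n_orb - n_elec) \
            or (n_elec - two_s) % 2 != 0:
        raise TargetError(f"target {target} not reachable on {n_orb} orbitals")
    state = closure_state(n_orb, n_elec, two_s)
    rng = np.random.default_rng(seed)
    ctx = SpinAdaptedContext(two_s, n_orb, n_elec)
    n = state.n_sites
    ctx.rm[n] = {}
    for k in range(n - 1, 0, -1):
        ctx.rm[k] = ladder_step_right(ctx.rm[k + 1], state.tensors[k],
                                      ctx.local_minus(k))
    c0 = state.tensors[0]
    rand = BlockTensor(c0.axes, c0.charge)
    for key in rand.allowed_keys():
        rand.set_block(key, rng.standard_normal(rand.block_shape(key)))
    minus = [(1, SMINUS_LOCAL), (2, ctx.rm[1])]
    plus = [(1, SPLUS_LOCAL), (2, op_transpose(ctx.rm[1]))]
    v = rand
    for two_sp in range(2, ctx.two_s_max + 1, 2):
        cp = (two_sp / 2.0) * (two_sp / 2.0 + 1.0)
        s2v = _apply_ladder(_apply_ladder(v, plus), minus)
        v = (s2v - cp * v) * (1.0 / (0.0 - cp))
    nrm = v.norm()
    if nrm < 1e-8:
        return state
    state.tensors[0] = v * (1.0 / nrm)
    return state


def physical_component(state: MPS, two_s: int) -> MPS:
    """Strip the spectator site, returning the physical highest-weight
    (Sz = S) component as a normalized n_orb-site MPS."""
    n = state.n_sites
    phys_tensors = [t.copy() for t in state.tensors[:n - 1]]
    aux = state.tensors[n - 1]
    # spectator in |S, -S> pairs with the physical Sz = +S component
    proj: Dict[Sector, np.ndarray] = {}
    for (l, p, r), blk in aux.blocks.items():
        if p == Sector(0, -two_s):
            proj[l] = blk[:, 0, :].sum(axis=1)
    last = phys_tensors[-1]
    bound_sec = None
    for (l, p, r) in last.blocks:
        if r in proj:
            bound_sec = r
            break
    if bound_sec is None:
        raise ValueError("state has no highest-weight physical component")
    out_axis = Axis.make(OUT, {bound_sec: 1})
    new_last = BlockTensor((last.axes[0], last.axes[1], out_axis))
    for (l, p, r), blk in last.blocks.items():
        vec = proj.get(r)
        if vec is None:
            continue
        new_last.add_to_block((l, p, bound_sec),
                              (blk @ vec)[:, :, None])
    phys_tensors[-1] = new_last
    out = MPS(phys_tensors, bound_sec, SU2, center=None,
              bond_spectra=[None] * (len(phys_tensors) - 1))
    out = canonicalize(out, 0)
    nrm = out.norm()
    if nrm == 0:
        raise ValueError("vanishing highest-weight component")
    out.tensors[0] = out.tensors[0] * (1.0 / nrm)
    return out
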