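"""Symmetry-conserving block-sparse tensors with operation accounting.

A :class:`BlockTensor` stores one dense array per combination of
symmetry sectors (one sector per axis) that satisfies the conservation
law

    sum_i direction_i * charge_i == tensor charge     (componentwise),

with charges the additive ``(N, 2Sz)`` labels of :mod:`.symmetry`.
Incoming axes have direction +1, outgoing axes -1.  The tensor-level
``charge`` lets operators that change particle number or spin projection
(ladder operators, creation doublets) live in the same framework.

Floating-point work is tallied in a :class:`FlopLedger` using the
matrix-multiply convention 2*m*n*k per dense block multiply;
factorizations are deliberately counted as zero (retained-state counts
are reported separately), so ledger totals are exact platform-independent
integers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .symmetry import Sector

Charge = Tuple[int, int]
BlockKey = Tuple[Sector, ...]

IN = +1
OUT = -1


@dataclass
class FlopLedger:
    """Monotone tally of floating-point operations, split by phase name."""

    total: int = 0
    by_phase: Dict[str, int] = field(default_factory=dict)

    def add(self, phase: str, count: int) -> None:
        if count < 0:
            raise ValueError("flop count must be non-negative")
        self.total += count
        self.by_phase[phase] = self.by_phase.get(phase, 0) + count

    def snapshot(self) -> "FlopLedger":
        return FlopLedger(self.total, dict(self.by_phase))

    def as_dict(self) -> Dict[str, int]:
        return {"total": self.total, **self.by_phase}


@dataclass(frozen=True)
class Axis:
    """One tensor leg: a direction and a sector -> dimension map."""

    direction: int
    dims: Tuple[Tuple[Sector, int], ...]

    def __post_init__(self) -> None:
        if self.direction not in (IN, OUT):
            raise ValueError("axis direction must be +1 (in) or -1 (out)")

    @staticmethod
    def make(direction: int, dims: Dict[Sector, int] | Iterable[Tuple[Sector, int]]) -> "Axis":
        items = dims.items() if isinstance(dims, dict) else dims
        return Axis(direction, tuple(sorted((Sector(*s), int(d)) for s, d in items)))

    @property
    def dim_map(self) -> Dict[Sector, int]:
        return dict(self.dims)

    def dim(self, sec: Sector) -> int:
        for s, d in self.dims:
            if s == sec:
                return d
        raise KeyError(sec)

    @property
    def total_dim(self) -> int:
        return sum(d for _, d in self.dims)

    def flipped(self) -> "Axis":
        return Axis(-self.direction, self.dims)

    def offsets(self) -> Dict[Sector, int]:
        """Sector -> offset in the dense (sorted-sector) embedding."""
        off, out = 0, {}
        for s, d in self.dims:
            out[s] = off
            off += d
        return out


def _add_charge(a: Charge, b: Charge) -> Charge:
    return (a[0] + b[0], a[1] + b[1])


def _neg_charge(a: Charge) -> Charge:
    return (-a[0], -a[1])


class BlockTensor:
    """Block-sparse tensor over (N, 2Sz) sectors with a conservation law."""

    __slots__ = ("axes", "charge", "blocks")

    def __init__(self, axes: Sequence[Axis], charge: Charge = (0, 0)):
        self.axes: Tuple[Axis, ...] = tuple(axes)
        self.charge: Charge = (int(charge[0]), int(charge[1]))
        self.blocks: Dict[BlockKey, np.ndarray] = {}

    # -- structure ---------------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def key_is_allowed(self, key: BlockKey) -> bool:
        tot = (0, 0)
        for ax, sec in zip(self.axes, key):
            tot = (tot[0] + ax.direction * sec.n, tot[1] + ax.direction * sec.spin2)
        return tot == self.charge

    def allowed_keys(self) -> List[BlockKey]:
        out = []
        for combo in itertools.product(*[[s for s, _ in ax.dims] for ax in self.axes]):
            if self.key_is_allowed(combo):
                out.append(combo)
        return out

    def block_shape(self, key: BlockKey) -> Tuple[int, ...]:
        return tuple(ax.dim(sec) for ax, sec in zip(self.axes, key))

    def set_block(self, key: Sequence[Sector], array: np.ndarray) -> None:
        key = tuple(Sector(*s) for s in key)
        if len(key) != self.ndim:
            raise ValueError("block key rank mismatch")
        if not self.key_is_allowed(key):
            raise ValueError(f"sector key {key} violates the conservation law "
                             f"(charge {self.charge})")
        shape = self.block_shape(key)
        array = np.asarray(array, dtype=np.float64)
        if array.shape != shape:
            raise ValueError(f"block shape {array.shape} does not match axis "
                             f"dimensions {shape} for key {key}")
        self.blocks[key] = array

    def add_to_block(self, key: Sequence[Sector], array: np.ndarray) -> None:
        key = tuple(Sector(*s) for s in key)
        if key in self.blocks:
            self.blocks[key] = self.blocks[key] + array
        else:
            self.set_block(key, array)

    def copy(self) -> "BlockTensor":
        out = BlockTensor(self.axes, self.charge)
        out.blocks = {k: v.copy() for k, v in self.blocks.items()}
        return out

    def drop_zero_blocks(self, tol: float = 0.0) -> "BlockTensor":
        out = BlockTensor(self.axes, self.charge)
        for k, v in self.blocks.items():
            if np.abs(v).max(initial=0.0) > tol:
                out.blocks[k] = v
        return out

    # -- algebra -----------------------------------------------------------

    def __mul__(self, alpha: float) -> "BlockTensor":
        out = BlockTensor(self.axes, self.charge)
        out.blocks = {k: alpha * v for k, v in self.blocks.items()}
        return out

    __rmul__ = __mul__

    def __add__(self, other: "BlockTensor") -> "BlockTensor":
        self._check_same_space(other)
        out = self.copy()
        for k, v in other.blocks.items():
            if k in out.blocks:
                out.blocks[k] = out.blocks[k] + v
            else:
                out.blocks[k] = v.copy()
        return out

    def __sub__(self, other: "BlockTensor") -> "BlockTensor":
        return self + (-1.0) * other

    def _check_same_space(self, other: "BlockTensor") -> None:
        if self.axes != other.axes or self.charge != other.charge:
            raise ValueError("tensors live in different spaces")

    def dot(self, other: "BlockTensor") -> float:
        """Euclidean inner product of two tensors in the same space."""
        self._check_same_space(other)
        tot = 0.0
        for k, v in self.blocks.items():
            w = other.blocks.get(k)
            if w is not None:
                tot += float(np.vdot(v, w))
        return tot

    def norm(self) -> float:
        return float(np.sqrt(max(self.dot(self), 0.0)))

    def transpose(self, perm: Sequence[int]) -> "BlockTensor":
        perm = tuple(perm)
        out = BlockTensor([self.axes[p] for p in perm], self.charge)
        for k, v in self.blocks.items():
            out.blocks[tuple(k[p] for p in perm)] = np.ascontiguousarray(
                np.transpose(v, perm))
        return out

    def flip(self) -> "BlockTensor":
        """Dual tensor: all axis directions reversed, charge negated.

        For the real tensors used here this is the complex conjugate in
        the charge bookkeeping sense (values unchanged).
        """
        out = BlockTensor([ax.flipped() for ax in self.axes], _neg_charge(self.charge))
        out.blocks = {k: v.copy() for k, v in self.blocks.items()}
        return out

    # -- dense embedding (oracle for tests, tiny tensors only) -------------

    def to_dense(self) -> np.ndarray:
        shape = tuple(ax.total_dim for ax in self.axes)
        dense = np.zeros(shape)
        offs = [ax.offsets() for ax in self.axes]
        for key, blk in self.blocks.items():
            idx = tuple(slice(offs[i][key[i]], offs[i][key[i]] + blk.shape[i])
                        for i in range(self.ndim))
            dense[idx] += blk
        return dense


def random_block_tensor(axes: Sequence[Axis], charge: Charge, rng: np.random.Generator) -> BlockTensor:
    """Dense-in-every-allowed-sector random tensor (test utility)."""
    t = BlockTensor(axes, charge)
    for key in t.allowed_keys():
        t.set_block(key, rng.standard_normal(t.block_shape(key)))
    return t


# -- contraction -----------------------------------------------------------


def contract(a: BlockTensor, b: BlockTensor,
             axes_a: Sequence[int], axes_b: Sequence[int],
             ledger: Optional[FlopLedger] = None, phase: str = "contract") -> BlockTensor:
    """Sector-wise tensor contraction over paired axes.

    Paired axes must have opposite directions and identical dimensions on
    every sector present in both; the ledger (if given) is incremented by
    2*m*n*k for every contributing pair of dense blocks.
    """
    axes_a = tuple(axes_a)
    axes_b = tuple(axes_b)
    if len(axes_a) != len(axes_b):
        raise ValueError("axes_a and axes_b must have equal length")
    for ia, ib in zip(axes_a, axes_b):
        axa, axb = a.axes[ia], b.axes[ib]
        if axa.direction != -axb.direction:
            raise ValueError(f"paired axes {ia},{ib} do not have opposite directions")
        da, db = axa.dim_map, axb.dim_map
        for sec in set(da) & set(db):
            if da[sec] != db[sec]:
                raise ValueError(f"paired axes {ia},{ib} disagree on sector {sec}: "
                                 f"{da[sec]} vs {db[sec]}")
    free_a = [i for i in range(a.ndim) if i not in axes_a]
    free_b = [i for i in range(b.ndim) if i not in axes_b]
    out = BlockTensor([a.axes[i] for i in free_a] + [b.axes[i] for i in free_b],
                      _add_charge(a.charge, b.charge))

    b_index: Dict[Tuple[Sector, ...], List[BlockKey]] = {}
    for kb in b.blocks:
        b_index.setdefault(tuple(kb[i] for i in axes_b), []).append(kb)

    flops = 0
    for ka, blk_a in a.blocks.items():
        ckey = tuple(ka[i] for i in axes_a)
        for kb in b_index.get(ckey, ()):
            blk_b = b.blocks[kb]
            res = np.tensordot(blk_a, blk_b, axes=(axes_a, axes_b))
            m = 1
            for i in free_a:
                m *= blk_a.shape[i]
            n = 1
            for i in free_b:
                n *= blk_b.shape[i]
            k = 1
            for i in axes_a:
                k *= blk_a.shape[i]
            flops += 2 * m * n * k
            okey = tuple(ka[i] for i in free_a) + tuple(kb[i] for i in free_b)
            if okey in out.blocks:
                out.blocks[okey] = out.blocks[okey] + res
            else:
                out.blocks[okey] = res
    if ledger is not None:
        ledger.add(phase, flops)
    return out


def apply_axis_operator(t: BlockTensor, axis: int,
                        op_blocks: Dict[Tuple[Sector, Sector], np.ndarray],
                        new_dims: Optional[Dict[Sector, int]] = None) -> BlockTensor:
    """Apply a one-axis operator ``O[out, in]`` along ``axis``.

    ``op_blocks`` maps (sector_out, sector_in) to a dense matrix of shape
    (dim_out, dim_in).  The operator must shift the axis sector by a
    uniform charge delta; the tensor charge is updated by
    ``direction * delta`` so conservation keeps holding.
    """
    if not op_blocks:
        dims = new_dims if new_dims is not None else {}
        ax = t.axes[axis]
        out = BlockTensor(t.axes[:axis] + (Axis.make(ax.direction, dims),) + t.axes[axis + 1:],
                          t.charge)
        return out
    deltas = {(so.n - si.n, so.spin2 - si.spin2) for so, si in op_blocks}
    if len(deltas) != 1:
        raise ValueError(f"axis operator has mixed charge deltas {deltas}")
    (delta,) = deltas
    ax = t.axes[axis]
    if new_dims is None:
        new_dims = {}
        for (so, si), mat in op_blocks.items():
            new_dims.setdefault(so, mat.shape[0])
    new_axis = Axis.make(ax.direction, new_dims)
    new_charge = (t.charge[0] + ax.direction * delta[0],
                  t.charge[1] + ax.direction * delta[1])
    out = BlockTensor(t.axes[:axis] + (new_axis,) + t.axes[axis + 1:], new_charge)
    by_in: Dict[Sector, List[Tuple[Sector, np.ndarray]]] = {}
    for (so, si), mat in op_blocks.items():
        by_in.setdefault(si, []).append((so, mat))
    for key, blk in t.blocks.items():
        si = key[axis]
        for so, mat in by_in.get(si, ()):
            moved = np.moveaxis(blk, axis, 0)
            res = np.moveaxis(np.tensordot(mat, moved, axes=(1, 0)), 0, axis)
            okey = key[:axis] + (so,) + key[axis + 1:]
            if okey in out.blocks:
                out.blocks[okey] = out.blocks[okey] + res
            else:
                out.blocks[okey] = res
    return out


# -- factorization ---------------------------------------------------------


def _bond_charge(t: BlockTensor, key: BlockKey, left_axes: Sequence[int]) -> Sector:
    n = s2 = 0
    for i in left_axes:
        n += t.axes[i].direction * key[i].n
        s2 += t.axes[i].direction * key[i].spin2
    return Sector(n, s2)


def svd_split(t: BlockTensor, left_axes: Sequence[int],
              d_max: Optional[int] = None,
              weight_threshold: Optional[float] = None,
              ledger: Optional[FlopLedger] = None,
              rank_tol: float = 1e-14,
              absorb: str = "right"):
    """Per-sector SVD across a bipartition of the axes.

    Returns ``(U, svals, Vh, discarded_weight)`` where ``U`` carries the
    left axes plus a new outgoing bond axis, ``Vh`` the matching incoming
    bond axis plus the right axes, and ``svals`` maps bond sector to the
    kept singular values.  With ``absorb="right"`` (default) ``U`` is an
    isometry and the singular values are folded into ``Vh``; with
    ``absorb="left"`` the rows of ``Vh`` are orthonormal instead.  Either
    way the (truncated) tensor is recovered by contracting ``U`` with
    ``Vh`` over the bond.  The retained basis is chosen by globally
    sorting squared singular values across sectors and keeping the top
    ``d_max`` states and/or the smallest set whose discarded relative
    weight does not exceed ``weight_threshold``; ties are broken toward
    the lexicographically smaller sector label.  ``discarded_weight`` is
    the discarded fraction of the total squared singular values.

    Factorization work is, by convention, not added to the ledger.
    """
    left_axes = tuple(left_axes)
    right_axes = tuple(i for i in range(t.ndim) if i not in left_axes)
    if not left_axes or not right_axes:
        raise ValueError("bipartition must leave axes on both sides")
    if not t.blocks:
        raise ValueError("cannot factorize an empty tensor")
    if absorb not in ("left", "right"):
        raise ValueError("absorb must be 'left' or 'right'")

    # group blocks by bond charge; build dense matrices with row/col maps
    groups: Dict[Sector, Dict[str, object]] = {}
    for key in t.blocks:
        qb = _bond_charge(t, key, left_axes)
        g = groups.setdefault(qb, {"rows": {}, "cols": {}, "keys": []})
        lsec = tuple(key[i] for i in left_axes)
        rsec = tuple(key[i] for i in right_axes)
        if lsec not in g["rows"]:
            dim = 1
            for i in left_axes:
                dim *= t.axes[i].dim(key[i])
            g["rows"][lsec] = dim
        if rsec not in g["cols"]:
            dim = 1
            for i in right_axes:
                dim *= t.axes[i].dim(key[i])
            g["cols"][rsec] = dim
        g["keys"].append(key)

    factor: Dict[Sector, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    entries: List[Tuple[float, Sector, int]] = []
    for qb in sorted(groups):
        g = groups[qb]
        row_order = sorted(g["rows"])
        col_order = sorted(g["cols"])
        row_off, off = {}, 0
        for rs in row_order:
            row_off[rs] = off
            off += g["rows"][rs]
        nrow = off
        col_off, off = {}, 0
        for cs in col_order:
            col_off[cs] = off
            off += g["cols"][cs]
        ncol = off
        mat = np.zeros((nrow, ncol))
        for key in g["keys"]:
            lsec = tuple(key[i] for i in left_axes)
            rsec = tuple(key[i] for i in right_axes)
            blk = np.transpose(t.blocks[key], left_axes + right_axes)
            blk = blk.reshape(g["rows"][lsec], g["cols"][rsec])
            mat[row_off[lsec]:row_off[lsec] + blk.shape[0],
                col_off[rsec]:col_off[rsec] + blk.shape[1]] = blk
        u, s, vh = np.linalg.svd(mat, full_matrices=False)
        factor[qb] = (u, s, vh)
        for i, sv in enumerate(s):
            entries.append((float(sv) ** 2, qb, i))

    total_weight = sum(w for w, _, _ in entries)
    # global sort: weight descending, then smaller sector label, then index
    order = sorted(range(len(entries)),
                   key=lambda j: (-entries[j][0], entries[j][1], entries[j][2]))
    cut = (rank_tol * max(np.sqrt(total_weight), 1.0)) ** 2
    # numerically-zero states are never kept
    n_nonzero = sum(1 for j in order if entries[j][0] > cut)
    n_keep = n_nonzero
    if d_max is not None:
        n_keep = min(n_keep, d_max)
    if weight_threshold is not None and total_weight > 0:
        # smallest kept count whose discarded relative weight stays within bound
        suffix = 0.0
        n_by_weight = n_nonzero
        for rank in range(n_nonzero, 0, -1):
            suffix += entries[order[rank - 1]][0]
            if suffix / total_weight <= weight_threshold:
                n_by_weight = rank - 1
            else:
                break
        n_keep = min(n_keep, max(n_by_weight, 1))
    kept: Dict[Sector, List[int]] = {}
    for j in order[:n_keep]:
        _, qb, i = entries[j]
        kept.setdefault(qb, []).append(i)
    discarded = sum(entries[j][0] for j in order[n_keep:])
    discarded_weight = discarded / total_weight if total_weight > 0 else 0.0

    bond_dims = {qb: len(ix) for qb, ix in kept.items()}
    u_axes = tuple(t.axes[i] for i in left_axes) + (Axis.make(OUT, bond_dims),)
    v_axes = (Axis.make(IN, bond_dims),) + tuple(t.axes[i] for i in right_axes)
    U = BlockTensor(u_axes, (0, 0))
    Vh = BlockTensor(v_axes, t.charge)
    svals: Dict[Sector, np.ndarray] = {}
    for qb, ix in kept.items():
        ix = sorted(ix)
        u, s, vh = factor[qb]
        svals[qb] = s[ix]
        g = groups[qb]
        for lsec, rdim in g["rows"].items():
            roff = 0
            row_order = sorted(g["rows"])
            row_off = {}
            for rs in row_order:
                row_off[rs] = roff
                roff += g["rows"][rs]
            sub = u[row_off[lsec]:row_off[lsec] + rdim, :][:, ix]
            if absorb == "left":
                sub = sub * s[ix][None, :]
            shape = tuple(t.axes[i].dim(lsec[j]) for j, i in enumerate(left_axes))
            U.blocks[lsec + (qb,)] = np.ascontiguousarray(sub.reshape(shape + (len(ix),)))
        for rsec, cdim in g["cols"].items():
            col_order = sorted(g["cols"])
            coff = 0
            col_off = {}
            for cs in col_order:
                col_off[cs] = coff
                coff += g["cols"][cs]
            sub = vh[ix, :][:, col_off[rsec]:col_off[rsec] + cdim]
            if absorb == "right":
                sub = s[ix, None] * sub
            shape = tuple(t.axes[i].dim(rsec[j]) for j, i in enumerate(right_axes))
            Vh.blocks[(qb,) + rsec] = np.ascontiguousarray(sub.reshape((len(ix),) + shape))
    return U, svals, Vh, discarded_weight
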