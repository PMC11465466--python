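"""Brute-force full-CI reference for small active spaces.

The reference space is the set of Slater determinants with fixed
particle number N and projection Sz, factorized into alpha/beta
occupation strings.  Matrix elements are generated by applying the
spin-summed excitation operators E_pq = sum_s a+_ps a_qs determinant by
determinant, with fermionic signs from explicit Jordan-Wigner parity
counting over the mode order (orb0 up, orb0 dn, orb1 up, ...) — the same
convention the MPO engine uses, which is what makes the two code paths
comparable element by element.

This module never touches the tensor-network machinery; it is the
independent oracle the solver is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .integrals import IntegralTable

#: hard cap on the determinant count (keeps one-CPU runs comfortable)
MAX_DETERMINANTS = 100_000

#: switch from dense eigh to iterative Lanczos above this basis size
DENSE_CUTOFF = 2000


@dataclass(frozen=True)
class DeterminantBasis:
    """Ordered (N, Sz) determinant basis as alpha/beta orbital bitmasks."""

    n_orb: int
    n_elec: int
    two_sz: int
    determinants: Tuple[Tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.determinants)

    def index(self) -> Dict[Tuple[int, int], int]:
        return {d: i for i, d in enumerate(self.determinants)}


def determinant_basis(n_orb: int, n_elec: int, two_sz: int) -> DeterminantBasis:
    if (n_elec + two_sz) % 2 != 0:
        raise ValueError(f"(n_elec + 2Sz) must be even, got {n_elec}, {two_sz}")
    n_a = (n_elec + two_sz) // 2
    n_b = (n_elec - two_sz) // 2
    if not (0 <= n_a <= n_orb and 0 <= n_b <= n_orb):
        raise ValueError(f"no determinants with N={n_elec}, 2Sz={two_sz} "
                         f"in {n_orb} orbitals")
    from math import comb
    count = comb(n_orb, n_a) * comb(n_orb, n_b)
    if count > MAX_DETERMINANTS:
        raise ValueError(f"determinant basis of size {count} exceeds the "
                         f"{MAX_DETERMINANTS} cap")
    a_strings = [sum(1 << i for i in occ) for occ in combinations(range(n_orb), n_a)]
    b_strings = [sum(1 << i for i in occ) for occ in combinations(range(n_orb), n_b)]
    dets = tuple((a, b) for a in a_strings for b in b_strings)
    return DeterminantBasis(n_orb, n_elec, two_sz, dets)


def _full_mask(a: int, b: int, n_orb: int) -> int:
    """Interleave alpha/beta orbital masks into the 2n-mode JW mask."""
    m = 0
    for i in range(n_orb):
        if a >> i & 1:
            m |= 1 << (2 * i)
        if b >> i & 1:
            m |= 1 << (2 * i + 1)
    return m


def _apply_a_dag_a(mask: int, mode_create: int, mode_annih: int):
    """a+_c a_a on a JW mode mask; returns (new_mask, sign) or None."""
    if not mask >> mode_annih & 1:
        return None
    sign = 1 if ((mask & ((1 << mode_annih) - 1)).bit_count() % 2 == 0) else -1
    mask ^= 1 << mode_annih
    if mask >> mode_create & 1:
        return None
    if (mask & ((1 << mode_create) - 1)).bit_count() % 2 == 1:
        sign = -sign
    mask |= 1 << mode_create
    return mask, sign


def _mask_to_ab(mask: int, n_orb: int) -> Tuple[int, int]:
    a = b = 0
    for i in range(n_orb):
        if mask >> (2 * i) & 1:
            a |= 1 << i
        if mask >> (2 * i + 1) & 1:
            b |= 1 << i
    return a, b


def _excitation_matrix(basis_to: DeterminantBasis, basis_from: DeterminantBasis,
                       pairs: List[Tuple[int, int]]) -> List[sp.csr_matrix]:
    """Sparse matrices of sum_s a+_{p s} a_{q s} (or a single spin channel)
    between two (N, Sz) bases, one per (mode_create, mode_annih) pair set."""
    idx_to = basis_to.index()
    n = basis_from.n_orb
    mats = []
    for mode_c, mode_a in pairs:
        rows, cols, vals = [], [], []
        for j, (a, b) in enumerate(basis_from.determinants):
            mask = _full_mask(a, b, n)
            res = _apply_a_dag_a(mask, mode_c, mode_a)
            if res is None:
                continue
            new_mask, sign = res
            key = _mask_to_ab(new_mask, n)
            i = idx_to.get(key)
            if i is not None:
                rows.append(i)
                cols.append(j)
                vals.append(float(sign))
        mats.append(sp.csr_matrix((vals, (rows, cols)),
                                  shape=(basis_to.size, basis_from.size)))
    return mats


def spin_summed_excitations(basis: DeterminantBasis) -> Dict[Tuple[int, int], sp.csr_matrix]:
    """E_pq = sum over spin of a+_ps a_qs within one (N, Sz) sector."""
    n = basis.n_orb
    out = {}
    for p in range(n):
        for q in range(n):
            up, dn = _excitation_matrix(basis, basis,
                                        [(2 * p, 2 * q), (2 * p + 1, 2 * q + 1)])
            out[(p, q)] = (up + dn).tocsr()
    return out


def sector_hamiltonian(table: IntegralTable, n_elec: int, two_sz: int
                       ) -> Tuple[sp.csr_matrix, DeterminantBasis]:
    """Explicit sparse Hamiltonian in the (N, Sz) determinant sector.

    H = E_core + sum h_pq E_pq
        + 1/2 sum_pqrs (pq|rs) (E_pq E_rs - delta_qr E_ps).
    """
    basis = determinant_basis(table.n_orb, n_elec, two_sz)
    E = spin_summed_excitations(basis)
    n = table.n_orb
    dim = basis.size
    H = sp.csr_matrix((dim, dim))
    g = table.two_body
    h_eff = table.one_body - 0.5 * np.einsum("pqqs->ps", g)
    for p in range(n):
        for q in range(n):
            if h_eff[p, q] != 0.0:
                H = H + h_eff[p, q] * E[(p, q)]
    for p in range(n):
        for q in range(n):
            K = sp.csr_matrix((dim, dim))
            any_term = False
            for r in range(n):
                for s in range(n):
                    if g[p, q, r, s] != 0.0:
                        K = K + g[p, q, r, s] * E[(r, s)]
                        any_term = True
            if any_term:
                H = H + 0.5 * (E[(p, q)] @ K)
    H = H + table.core_energy * sp.identity(dim, format="csr")
    return H.tocsr(), basis


def fci_ground_state(table: IntegralTable, n_elec: int, two_sz: int
                     ) -> Tuple[float, np.ndarray]:
    """Lowest eigenpair of H in the (N, Sz) sector (dense below
    ``DENSE_CUTOFF`` determinants, Lanczos above)."""
    H, basis = sector_hamiltonian(table, n_elec, two_sz)
    if basis.size == 1:
        return float(H[0, 0]), np.ones(1)
    if basis.size <= DENSE_CUTOFF:
        w, v = np.linalg.eigh(H.toarray())
        return float(w[0]), v[:, 0]
    w, v = spla.eigsh(H, k=1, which="SA", maxiter=5000, tol=0.0)
    return float(w[0]), v[:, 0]


def fci_spectrum(table: IntegralTable, n_elec: int, two_sz: int, k: int = 4
                 ) -> np.ndarray:
    """Lowest k sector eigenvalues (dense path only, for small fixtures)."""
    H, basis = sector_hamiltonian(table, n_elec, two_sz)
    if basis.size <= DENSE_CUTOFF:
        return np.linalg.eigh(H.toarray())[0][:k]
    return np.sort(spla.eigsh(H, k=k, which="SA")[0])


def s_plus_matrix(basis: DeterminantBasis) -> Tuple[sp.csr_matrix, DeterminantBasis]:
    """S+ = sum_p a+_{p up} a_{p dn}, mapping (N, Sz) -> (N, Sz + 1)."""
    target = determinant_basis(basis.n_orb, basis.n_elec, basis.two_sz + 2)
    mats = _excitation_matrix(target, basis,
                              [(2 * p, 2 * p + 1) for p in range(basis.n_orb)])
    total = mats[0]
    for m in mats[1:]:
        total = total + m
    return total.tocsr(), target


def s_squared(vector: np.ndarray, basis: DeterminantBasis) -> float:
    """Total-spin expectation <S^2> = |S+ v|^2 + Sz(Sz + 1) of a normalized
    sector vector; equals S(S+1) on spin eigenstates."""
    vector = np.asarray(vector, dtype=np.float64)
    nrm = np.linalg.norm(vector)
    if not np.isclose(nrm, 1.0, atol=1e-8):
        raise ValueError(f"vector is not normalized (|v| = {nrm:.3e})")
    sz = basis.two_sz / 2.0
    n_a = (basis.n_elec + basis.two_sz) // 2
    if n_a == basis.n_orb:  # no room to raise Sz
        splus_norm2 = 0.0
    else:
        sp_mat, _ = s_plus_matrix(basis)
        splus_norm2 = float(np.linalg.norm(sp_mat @ vector) ** 2)
    return splus_norm2 + sz * (sz + 1.0)


def sector_spin_resolved_minimum(table: IntegralTable, n_elec: int, two_s: int
                                 ) -> float:
    """Lowest energy among sector states with total spin exactly S.

    Diagonalizes the (N, Sz=S) sector and picks the lowest eigenvector
    whose <S^2> matches S(S+1); used to label oracle states when the
    sector minimum has higher spin than S.
    """
    H, basis = sector_hamiltonian(table, n_elec, two_s)
    if basis.size > DENSE_CUTOFF:
        raise ValueError("spin-resolved scan is a dense-path utility")
    w, v = np.linalg.eigh(H.toarray())
    target = (two_s / 2.0) * (two_s / 2.0 + 1.0)
    for i in range(len(w)):
        if abs(s_squared(v[:, i], basis) - target) < 1e-6:
            return float(w[i])
    raise ValueError(f"no spin-{two_s}/2 state found in sector")
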