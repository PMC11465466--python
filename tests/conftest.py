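"""Shared fixtures and dense-space helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

try:
    from hypothesis import settings
    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:
    pass

from spindmrg.integrals import hubbard_chain, random_cas
from spindmrg.oracle import DeterminantBasis


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def hubbard4():
    return hubbard_chain(4, 1.0, 4.0)


@pytest.fixture(scope="session")
def rcas3():
    return random_cas(3, 3, seed=3, two_s_target=1)


def occ_index(codes) -> int:
    """Flatten per-orbital occupation codes (site 0 slowest) to a dense
    Fock-space index, matching ``to_statevector`` ordering."""
    idx = 0
    for c in codes:
        idx = idx * 4 + c
    return idx


def det_to_codes(alpha: int, beta: int, n_orb: int):
    return [(1 if alpha >> i & 1 else 0) + (2 if beta >> i & 1 else 0)
            for i in range(n_orb)]


def sector_indices(basis: DeterminantBasis):
    """Dense Fock-space indices of a determinant basis, in basis order."""
    return [occ_index(det_to_codes(a, b, basis.n_orb))
            for a, b in basis.determinants]


def embed_to_sector(vec_full: np.ndarray, basis: DeterminantBasis) -> np.ndarray:
    """Restrict a dense Fock-space vector to a determinant sector basis,
    checking that no weight is lost."""
    idx = sector_indices(basis)
    sub = vec_full[idx]
    lost = np.linalg.norm(vec_full) ** 2 - np.linalg.norm(sub) ** 2
    assert abs(lost) < 1e-16 or lost < 1e-10 * np.linalg.norm(vec_full) ** 2
    return sub
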