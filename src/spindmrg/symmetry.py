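"""Quantum-number algebra for particle number and spin.

Two symmetry modes are supported throughout the package:

``"u1"``
    U(1)_N x U(1)_Sz.  A sector is ``(n, 2*Sz)``; fusion is additive.
``"su2"``
    U(1)_N x SU(2)_S.  A sector is ``(n, 2*S)`` with ``2S >= 0``; fusion
    follows the Clebsch-Gordan series.

Spin labels are stored as *twice* the spin (``2S`` or ``2Sz``) so that
half-integer spins stay exact integers.  A retained bond basis in the
spin-adapted mode is described by a :class:`MultipletSpectrum`, whose
:func:`u1_dimension` gives the equivalent number of U(1) states — the
accounting rule that relates the reported multiplet bond dimension D to
the (larger) D_U(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Sequence, Tuple

U1 = "u1"
SU2 = "su2"
MODES = (U1, SU2)


class Sector(NamedTuple):
    """A symmetry sector: particle count and spin label (2Sz or 2S)."""

    n: int
    spin2: int


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown symmetry mode {mode!r}; expected one of {MODES}")


def validate_sector(sec: Sector, mode: str) -> None:
    """Raise ValueError if ``sec`` is not a valid sector in ``mode``.

    In SU(2) mode the spin label must be non-negative, and in both modes
    the parity of the spin label must match the parity of the particle
    count (an odd number of electrons has half-integer spin).
    """
    _check_mode(mode)
    n, s2 = sec
    if n < 0:
        raise ValueError(f"negative particle count in sector {sec}")
    if mode == SU2 and s2 < 0:
        raise ValueError(f"negative 2S in SU(2) sector {sec}")
    if (n - s2) % 2 != 0:
        raise ValueError(f"parity mismatch in sector {sec}: n and spin label "
                         "must have equal parity")


def fuse(a: Sector, b: Sector, mode: str) -> List[Sector]:
    """Fuse two sectors.

    U(1): a single sector with added charges.  SU(2): the Clebsch-Gordan
    series ``|S_a - S_b| .. S_a + S_b`` at added particle number.
    """
    validate_sector(a, mode)
    validate_sector(b, mode)
    n = a.n + b.n
    if mode == U1:
        return [Sector(n, a.spin2 + b.spin2)]
    lo, hi = abs(a.spin2 - b.spin2), a.spin2 + b.spin2
    return [Sector(n, s2) for s2 in range(lo, hi + 1, 2)]


def local_basis(mode: str) -> List[Tuple[Sector, int]]:
    """Sectors and dimensions of one spinful orbital (local dimension 4).

    U(1): four one-dimensional sectors (empty, up, down, doubly occupied).
    SU(2): three multiplets; the singly-occupied doublet has U(1)
    dimension 2, so the U(1)-equivalent local dimension is again 4.
    """
    _check_mode(mode)
    if mode == U1:
        return [(Sector(0, 0), 1), (Sector(1, 1), 1),
                (Sector(1, -1), 1), (Sector(2, 0), 1)]
    return [(Sector(0, 0), 1), (Sector(1, 1), 1), (Sector(2, 0), 1)]


@dataclass
class MultipletSpectrum:
    """The retained bond basis of a spin-adapted run, as (2S, multiplicity).

    Entries with duplicate 2S are merged on construction; multiplicities
    must be positive.
    """

    entries: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[int, int] = {}
        for two_s, mult in self.entries:
            if mult < 1:
                raise ValueError(f"non-positive multiplicity {mult} for 2S={two_s}")
            if two_s < 0:
                raise ValueError(f"negative 2S={two_s}")
            merged[two_s] = merged.get(two_s, 0) + mult
        self.entries = sorted(merged.items())

    @property
    def multiplet_count(self) -> int:
        return sum(m for _, m in self.entries)

    def concat(self, other: "MultipletSpectrum") -> "MultipletSpectrum":
        return MultipletSpectrum(self.entries + other.entries)


def u1_dimension(spec: MultipletSpectrum) -> int:
    """Number of U(1) states spanned by a multiplet spectrum.

    Each spin-S multiplet contributes its 2S+1 projection states, so the
    total is ``sum(multiplicity * (2S + 1))``.  This is the rule behind
    quoting a multiplet bond dimension D alongside a larger D_U(1).
    """
    return sum(mult * (two_s + 1) for two_s, mult in spec.entries)


def spectrum_from_sectors(sectors: Sequence[Tuple[Sector, int]]) -> MultipletSpectrum:
    """Build a MultipletSpectrum from SU(2)-labelled (sector, count) pairs."""
    return MultipletSpectrum([(sec.spin2, cnt) for sec, cnt in sectors])
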