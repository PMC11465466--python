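"""Active-space Hamiltonians: FCIDUMP IO and model generators.

An :class:`IntegralTable` holds the second-quantized active-space
Hamiltonian

    H = E_core + sum_pq h[p,q] E_pq
             + 1/2 sum_pqrs (pq|rs) sum_st a+_ps a+_rt a_st a_qs

with ``h`` the one-electron integrals, ``(pq|rs)`` the two-electron
integrals in chemists' notation with the full 8-fold permutational
symmetry, and all energies in Hartree.  Indices are 0-based internally
and converted to the 1-based convention only at the FCIDUMP boundary.

The file dialect is the Molpro-style FCIDUMP: a ``&FCI`` namelist header
(NORB, NELEC, MS2, optionally ORBSYM/ISYM, which are parsed but ignored)
followed by ``value p q r s`` records — two-body for pqrs > 0, one-body
for ``p q 0 0``, core energy for ``0 0 0 0``.  Only one representative
per symmetry orbit is stored; unlisted integrals are zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

#: largest permitted symmetry violation in a file before it is rejected
SYMMETRY_TOL = 1e-10


class FcidumpParseError(ValueError):
    """Malformed FCIDUMP content; the message names the offending line."""


@dataclass
class IntegralTable:
    """Core energy plus one- and two-electron integrals of a CAS Hamiltonian."""

    n_orb: int
    n_elec: int
    two_s_target: int
    core_energy: float
    one_body: np.ndarray          # (n_orb, n_orb), Hartree
    two_body: np.ndarray          # (n_orb,)*4, chemists' (pq|rs), Hartree
    orbital_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.one_body = np.asarray(self.one_body, dtype=np.float64)
        self.two_body = np.asarray(self.two_body, dtype=np.float64)
        self.validate()

    def validate(self, tol: float = SYMMETRY_TOL) -> None:
        n = self.n_orb
        if self.one_body.shape != (n, n):
            raise ValueError(f"one_body shape {self.one_body.shape} != ({n},{n})")
        if self.two_body.shape != (n, n, n, n):
            raise ValueError(f"two_body shape {self.two_body.shape} != ({n},)*4")
        if not (np.all(np.isfinite(self.one_body)) and np.all(np.isfinite(self.two_body))
                and np.isfinite(self.core_energy)):
            raise ValueError("non-finite integral entries")
        if not 0 <= self.n_elec <= 2 * n:
            raise ValueError(f"n_elec={self.n_elec} outside [0, {2 * n}]")
        if self.two_s_target < 0 or (self.n_elec - self.two_s_target) % 2 != 0 \
                or self.n_elec < self.two_s_target:
            raise ValueError(f"invalid spin target 2S={self.two_s_target} for "
                             f"n_elec={self.n_elec}")
        err = np.abs(self.one_body - self.one_body.T).max(initial=0.0)
        if err > tol:
            raise ValueError(f"one-body matrix not symmetric (max deviation {err:.3e})")
        g = self.two_body
        worst = 0.0
        worst_perm = None
        for perm, name in (((1, 0, 2, 3), "g[qprs]"), ((0, 1, 3, 2), "g[pqsr]"),
                           ((2, 3, 0, 1), "g[rspq]")):
            dev = np.abs(g - np.transpose(g, perm))
            m = dev.max(initial=0.0)
            if m > worst:
                worst = m
                worst_perm = (name, np.unravel_index(int(dev.argmax()), dev.shape))
        if worst > tol:
            name, quad = worst_perm
            raise ValueError(
                f"two-body integrals violate 8-fold symmetry: |g[pqrs] - {name}| = "
                f"{worst:.3e} at pqrs={tuple(int(i) for i in quad)} (tolerance {tol:g})")

    def symmetrized_two_body(self) -> np.ndarray:
        """Average of g over its 8-element permutation orbit."""
        return symmetrize_two_body(self.two_body)


def symmetrize_two_body(g: np.ndarray) -> np.ndarray:
    # sequential pairwise averaging over the three commuting generators is
    # *exactly* symmetric in floating point (addition is commutative), which
    # a single 8-term orbit average is not
    g = np.asarray(g, dtype=np.float64)
    for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
        g = (g + np.transpose(g, perm)) / 2.0
    return g


# -- FCIDUMP ---------------------------------------------------------------

_NAMELIST_ITEM = re.compile(r"([A-Za-z0-9_]+)\s*=\s*([^=]*?)(?=(?:,\s*[A-Za-z0-9_]+\s*=)|$)")


def _parse_header(header: str, lineno_hint: int) -> dict:
    body = header.strip()
    if body.startswith("&"):
        body = body[1:]
    for tag in ("FCI", "fci"):
        if body.startswith(tag):
            body = body[len(tag):]
            break
    body = body.strip().rstrip("/").replace("&END", "").replace("&end", "").strip()
    fields = {}
    for m in _NAMELIST_ITEM.finditer(body):
        key = m.group(1).upper()
        val = m.group(2).strip().rstrip(",").strip()
        fields[key] = val
    out = {}
    for key in ("NORB", "NELEC", "MS2"):
        if key not in fields:
            raise FcidumpParseError(
                f"line {lineno_hint}: FCIDUMP header is missing {key}")
        try:
            out[key] = int(fields[key].split(",")[0])
        except ValueError as exc:
            raise FcidumpParseError(
                f"line {lineno_hint}: cannot parse {key}={fields[key]!r}") from exc
    return out


def read_fcidump(path) -> IntegralTable:
    """Read a Molpro-dialect FCIDUMP file into a validated IntegralTable.

    Symmetry-equivalent integral entries are filled in from the stored
    representative; a file whose duplicated entries disagree beyond
    ``SYMMETRY_TOL`` is rejected.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header = ""
    data_start = None
    for i, line in enumerate(lines):
        header += " " + line.strip()
        if "/" in line or "&END" in line.upper():
            data_start = i + 1
            break
    if data_start is None:
        raise FcidumpParseError("line 1: no namelist terminator '/' found in header")
    hdr = _parse_header(header, data_start)
    n = hdr["NORB"]
    if n < 1:
        raise FcidumpParseError(f"line 1: NORB={n} must be positive")
    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    g_set = np.zeros((n, n, n, n), dtype=bool)
    h_set = np.zeros((n, n), dtype=bool)
    core = 0.0
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FcidumpParseError(
                f"line {lineno}: expected 'value p q r s', got {line!r}")
        try:
            val = float(parts[0].replace("D", "E").replace("d", "e"))
            p, q, r, s = (int(x) for x in parts[1:])
        except ValueError as exc:
            raise FcidumpParseError(f"line {lineno}: cannot parse {line!r}") from exc
        if min(p, q, r, s) < 0 or max(p, q, r, s) > n:
            raise FcidumpParseError(
                f"line {lineno}: orbital index outside 1..{n} in {line!r}")
        if p == q == r == s == 0:
            core = val
        elif r == s == 0:
            if p == 0 or q == 0:
                raise FcidumpParseError(f"line {lineno}: bad one-body record {line!r}")
            for a, b in ((p - 1, q - 1), (q - 1, p - 1)):
                if h_set[a, b] and abs(h[a, b] - val) > SYMMETRY_TOL:
                    raise FcidumpParseError(
                        f"line {lineno}: inconsistent duplicate h[{a + 1},{b + 1}] "
                        f"({h[a, b]:.12g} vs {val:.12g})")
                h[a, b] = val
                h_set[a, b] = True
        elif 0 in (p, q, r, s):
            raise FcidumpParseError(f"line {lineno}: mixed zero indices in {line!r}")
        else:
            pp, qq, rr, ss = p - 1, q - 1, r - 1, s - 1
            for a, b, c, d in _orbit(pp, qq, rr, ss):
                if g_set[a, b, c, d] and abs(g[a, b, c, d] - val) > SYMMETRY_TOL:
                    raise FcidumpParseError(
                        f"line {lineno}: inconsistent duplicate "
                        f"({a + 1}{b + 1}|{c + 1}{d + 1}) "
                        f"({g[a, b, c, d]:.12g} vs {val:.12g})")
                g[a, b, c, d] = val
                g_set[a, b, c, d] = True
    return IntegralTable(n_orb=n, n_elec=hdr["NELEC"], two_s_target=abs(hdr["MS2"]),
                         core_energy=core, one_body=h, two_body=g)


def _orbit(p, q, r, s):
    return {(p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
            (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p)}


def write_fcidump(table: IntegralTable, path) -> None:
    """Write a Molpro-dialect FCIDUMP with one representative per orbit.

    Zeros are omitted; the table is re-validated first so a symmetry
    violation refuses to write.
    """
    table.validate()
    n = table.n_orb
    lines = [f"&FCI NORB={n},NELEC={table.n_elec},MS2={table.two_s_target},",
             " ORBSYM=" + ",".join(["1"] * n) + ",",
             " ISYM=1,",
             "&END"]
    g = table.two_body
    seen = set()
    for p in range(n):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = q if r == p else r
                for s in range(smax + 1):
                    if (p, q, r, s) in seen:
                        continue
                    seen.update(_orbit(p, q, r, s))
                    if g[p, q, r, s] != 0.0:
                        lines.append(f"{g[p, q, r, s]:23.16E} {p + 1:3d} {q + 1:3d} "
                                     f"{r + 1:3d} {s + 1:3d}")
    for p in range(n):
        for q in range(p + 1):
            if table.one_body[p, q] != 0.0:
                lines.append(f"{table.one_body[p, q]:23.16E} {p + 1:3d} {q + 1:3d}   0   0")
    if table.core_energy != 0.0:
        lines.append(f"{table.core_energy:23.16E}   0   0   0   0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- model generators ------------------------------------------------------


def hubbard_chain(n_sites: int, t: float, u: float,
                  n_elec: Optional[int] = None,
                  two_s_target: int = 0) -> IntegralTable:
    """Open-boundary Hubbard chain as an integral table.

    Nearest-neighbour hopping ``h[i,i+1] = -t`` and on-site repulsion
    ``(ii|ii) = u``; in the spin-summed Hamiltonian the latter yields
    exactly ``u * n_up * n_dn`` per site.  Half filling unless
    ``n_elec`` is overridden.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    h = np.zeros((n_sites, n_sites))
    for i in range(n_sites - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    g = np.zeros((n_sites,) * 4)
    for i in range(n_sites):
        g[i, i, i, i] = u
    if n_elec is None:
        n_elec = n_sites
    if (n_elec - two_s_target) % 2 != 0:
        two_s_target = n_elec % 2
    return IntegralTable(n_orb=n_sites, n_elec=n_elec, two_s_target=two_s_target,
                         core_energy=0.0, one_body=h, two_body=g)


def hubbard_dimer_singlet_energy(t: float, u: float) -> float:
    """Closed-form ground-state energy of the half-filled Hubbard dimer,
    ``(U - sqrt(U^2 + 16 t^2)) / 2``."""
    return (u - np.sqrt(u * u + 16.0 * t * t)) / 2.0


def random_cas(n_orb: int, n_elec: int, seed: int, scale: float = 1.0,
               two_s_target: Optional[int] = None) -> IntegralTable:
    """Seeded random integral table projected onto the 8-fold-symmetric
    subspace (the projection makes the symmetry exact, not approximate).

    Intended at test scale (a handful of orbitals); stands in for CAS
    Hamiltonians whose integral files are not available.
    """
    rng = np.random.default_rng(seed)
    h = rng.standard_normal((n_orb, n_orb)) * scale
    h = (h + h.T) / 2.0
    g = symmetrize_two_body(rng.standard_normal((n_orb,) * 4) * scale)
    if two_s_target is None:
        two_s_target = n_elec % 2
    return IntegralTable(n_orb=n_orb, n_elec=n_elec, two_s_target=two_s_target,
                         core_energy=0.0, one_body=h, two_body=g)


def near_degenerate_spin_chain(n_sites: int = 5, t: float = 0.25,
                               u: float = 10.0,
                               delta_t: float = 0.15) -> IntegralTable:
    """A small odd-electron chain with close-lying doublet/quartet states.

    A weakly dimerized half-filled Hubbard chain with an odd site count
    deep in the local-moment regime: the superexchange scale 4t^2/U
    (25 mHartree at the defaults) separates the lowest doublet and
    quartet by only tens of mHartree — a desk-scale stand-in for
    near-degenerate metal-centre spin states.  ``delta_t`` alternates
    the hopping as ``t (1 +/- delta_t)``.
    """
    if n_sites % 2 == 0:
        raise ValueError("n_sites must be odd for an odd-electron chain")
    table = hubbard_chain(n_sites, t, u)
    for i in range(n_sites - 1):
        mod = 1.0 + (delta_t if i % 2 == 0 else -delta_t)
        table.one_body[i, i + 1] = table.one_body[i + 1, i] = -t * mod
    table.validate()
    return table
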