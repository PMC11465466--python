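"""Post-processing of DMRG runs.

Three analyses mirror how finite-bond-dimension results are reported in
the quantum-chemistry DMRG literature:

* polynomial extrapolation of converged energies against 1/D to the
  truncation-free D -> infinity limit (second order by default), with D
  counted in SU(2) multiplets for spin-adapted runs;
* spin gaps in mHartree between the extrapolated limits of two spin
  states;
* log-log first-order fits of computational cost against bond
  dimension, whose slope identifies the D^3 regime of the two-site
  update once all symmetry sectors are saturated.

Fits are unweighted least squares; residuals are reported so the reader
can judge the fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .solver import SweepRecord

#: sweep-convergence threshold used in production-scale practice
PRODUCTION_ENERGY_TOL = 1e-5


@dataclass
class ExtrapolationFit:
    """Polynomial fit of E(D) in powers of 1/D.

    ``coefficients[0]`` (a0) is the D -> infinity energy estimate in
    Hartree.  For a variational, monotonically improving series the
    extrapolated limit must not sit above the best computed energy; the
    constructor enforces this up to a slack set by the fit residuals.
    """

    order: int
    coefficients: np.ndarray          # a0..a_order
    residuals: np.ndarray             # per input point, Hartree
    d_values: np.ndarray              # SU(2) multiplet counts (or D_U(1), labelled)
    energies: np.ndarray              # Hartree
    d_convention: str = "su2"         # "su2" multiplets or "u1" states

    @property
    def a0(self) -> float:
        return float(self.coefficients[0])

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        self.residuals = np.asarray(self.residuals, dtype=np.float64)
        self.d_values = np.asarray(self.d_values)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if len(self.d_values) < self.order + 1:
            raise ValueError("need at least order+1 points")
        if np.any(np.diff(self.d_values) <= 0):
            raise ValueError("D values must be strictly increasing")
        slack = max(1e-9, 10.0 * float(np.sqrt(np.mean(self.residuals ** 2))))
        if self.a0 > float(self.energies.min()) + slack:
            raise ValueError(
                f"extrapolated energy {self.a0:.8f} lies above the best "
                f"computed energy {self.energies.min():.8f} beyond slack "
                f"{slack:.2e}; the series is not variational/monotone")

    def predict(self, d: np.ndarray) -> np.ndarray:
        x = 1.0 / np.asarray(d, dtype=np.float64)
        return sum(c * x ** i for i, c in enumerate(self.coefficients))


def extrapolate_vs_inverse_d(d_values: Sequence[float],
                             energies: Sequence[float],
                             order: int = 2,
                             d_convention: str = "su2") -> ExtrapolationFit:
    """Least-squares polynomial in x = 1/D; a0 estimates E(D -> infinity)."""
    d = np.asarray(d_values, dtype=np.float64)
    e = np.asarray(energies, dtype=np.float64)
    if d.ndim != 1 or d.shape != e.shape:
        raise ValueError("d_values and energies must be equal-length 1-D")
    if len(set(d.tolist())) != len(d):
        raise ValueError("duplicated D values make the fit rank-deficient")
    if len(d) < order + 1:
        raise ValueError(f"need at least {order + 1} points for order {order}")
    x = 1.0 / d
    A = np.vander(x, order + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(A, e, rcond=None)
    resid = A @ coeffs - e
    idx = np.argsort(d)
    return ExtrapolationFit(order=order, coefficients=coeffs,
                            residuals=resid[idx], d_values=d[idx],
                            energies=e[idx], d_convention=d_convention)


def spin_gap(fit_a: ExtrapolationFit, fit_b: ExtrapolationFit) -> float:
    """Extrapolated spin gap 1000*(a0_b - a0_a) in mHartree; positive when
    state b lies above state a."""
    return 1000.0 * (fit_b.a0 - fit_a.a0)


@dataclass
class ScalingFit:
    """First-order log-log fit of cost vs bond dimension."""

    exponent: float
    prefactor: float
    window: Tuple[float, float]
    residual: float
    d_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("non-finite exponent")


def fit_scaling_exponent(d_values: Sequence[float], costs: Sequence[float],
                         window: Optional[Tuple[float, float]] = None
                         ) -> ScalingFit:
    """Slope of log(cost) vs log(D) restricted to an explicit D window.

    The window is user input by design: the cost curve has a low-D
    regime where sectors are still filling up and a saturated regime
    with the asymptotic exponent, and the split point is a judgement
    call, not something this routine guesses.
    """
    d = np.asarray(d_values, dtype=np.float64)
    c = np.asarray(costs, dtype=np.float64)
    if d.shape != c.shape or d.ndim != 1:
        raise ValueError("d_values and costs must be equal-length 1-D")
    if np.any(c <= 0):
        raise ValueError("costs must be positive for a log-log fit")
    if window is None:
        window = (float(d.min()), float(d.max()))
    mask = (d >= window[0]) & (d <= window[1])
    if mask.sum() < 2:
        raise ValueError("need at least 2 points inside the window")
    ld, lc = np.log(d[mask]), np.log(c[mask])
    slope, intercept = np.polyfit(ld, lc, 1)
    resid = float(np.sqrt(np.mean((np.polyval([slope, intercept], ld) - lc) ** 2)))
    return ScalingFit(exponent=float(slope), prefactor=float(np.exp(intercept)),
                      window=window, residual=resid, d_values=d[mask])


def sweep_report(records: Sequence[SweepRecord],
                 energy_tol: Optional[float] = None) -> pd.DataFrame:
    """Tabular per-sweep summary with convergence flags.

    Columns: sweep, energy, abs_delta_e, max_discarded_weight, D, D_u1,
    davidson_iterations, heff_flops (cumulative), plus boolean flags for
    the first sweep where |dE| falls below the production threshold
    (1e-5 Hartree) and below ``energy_tol`` if given.
    """
    if not records:
        raise ValueError("no sweep records")
    rows = []
    prev = None
    for r in records:
        de = np.nan if prev is None else abs(r.energy - prev)
        rows.append({"sweep": r.index, "energy": r.energy, "abs_delta_e": de,
                     "max_discarded_weight": r.max_discarded_weight,
                     "D": r.realized_D, "D_u1": r.realized_D_u1,
                     "davidson_iterations": r.davidson_iterations,
                     "heff_flops": r.ledger.get("heff", 0)})
        prev = r.energy
    df = pd.DataFrame(rows)

    def first_below(threshold: Optional[float]) -> pd.Series:
        flags = pd.Series(False, index=df.index)
        if threshold is None:
            return flags
        hit = df.index[df["abs_delta_e"] < threshold]
        if len(hit):
            flags.loc[hit[0]] = True
        return flags

    df["converged_production"] = first_below(PRODUCTION_ENERGY_TOL)
    df["converged_target"] = first_below(energy_tol)
    return df


# -- plots -----------------------------------------------------------------


def plot_extrapolation(fits, labels, path) -> None:
    """Energy vs 1/D with the fitted curves (one panel)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for fit, label in zip(fits, labels):
        x = 1.0 / fit.d_values
        ax.plot(x, fit.energies, "o", label=label)
        xs = np.linspace(0, x.max() * 1.05, 200)[1:]
        ax.plot(np.concatenate([[0.0], xs]),
                np.concatenate([[fit.a0], fit.predict(1.0 / xs)]), "-")
        ax.plot([0.0], [fit.a0], "s", mfc="none")
    ax.set_xlabel("1 / D")
    ax.set_ylabel("Energy (Hartree)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scaling(d_values, costs, fits, path) -> None:
    """log-log cost vs D with fitted power laws."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(d_values, costs, "o", label="measured")
    for fit in fits:
        d = np.asarray(fit.d_values, dtype=np.float64)
        if d.size == 0:
            continue
        ax.loglog(d, fit.prefactor * d ** fit.exponent, "-",
                  label=f"slope {fit.exponent:.2f}")
    ax.set_xlabel("bond dimension D")
    ax.set_ylabel("operation count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
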