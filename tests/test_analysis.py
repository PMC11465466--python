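"""Extrapolation, spin gaps, scaling fits and sweep reports."""

import numpy as np
import pytest

from spindmrg.analysis import (ExtrapolationFit, extrapolate_vs_inverse_d,
                               fit_scaling_exponent, spin_gap, sweep_report)
from spindmrg.solver import SweepRecord


class TestExtrapolation:
    def test_exact_polynomial_recovered_to_machine_precision(self):
        ds = np.array([100.0, 200.0, 400.0, 800.0])
        e = -10.0 + 2.0 / ds + 5.0 / ds ** 2
        fit = extrapolate_vs_inverse_d(ds, e, order=2)
        assert fit.a0 == pytest.approx(-10.0, abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(2.0, abs=1e-7)
        assert fit.coefficients[2] == pytest.approx(5.0, abs=1e-4)
        assert np.abs(fit.residuals).max() < 1e-12

    def test_constant_series(self):
        ds = np.array([10.0, 20.0, 40.0, 80.0])
        fit = extrapolate_vs_inverse_d(ds, np.full(4, -3.5), order=2)
        assert fit.a0 == pytest.approx(-3.5, abs=1e-12)
        np.testing.assert_allclose(fit.coefficients[1:], 0.0, atol=1e-9)

    def test_seeded_noise_recovery_within_bound(self):
        # 100 seeded noise realizations, sigma = 1e-5: at least 95 recover
        # the limit within 1e-4 Hartree (all 100 do; 95th pct approx 3e-5)
        ds = np.array([100.0, 150.0, 200.0, 300.0, 400.0, 800.0])
        clean = -10.0 + 2.0 / ds + 5.0 / ds ** 2
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            fit = extrapolate_vs_inverse_d(
                ds, clean + rng.normal(0.0, 1e-5, size=ds.size), order=2)
            hits += abs(fit.a0 + 10.0) < 1e-4
        assert hits >= 95

    def test_input_validation(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            extrapolate_vs_inverse_d([100, 100, 200], [-1, -1, -2])
        with pytest.raises(ValueError, match="at least"):
            extrapolate_vs_inverse_d([100, 200], [-1.0, -1.1], order=2)

    def test_non_variational_series_rejected(self):
        # an "extrapolation" rising above the best computed energy is a
        # red flag for the monotone, variational series this models
        ds = np.array([100.0, 200.0, 400.0, 800.0])
        e = -10.0 - 2.0 / ds           # energies BELOW the limit
        with pytest.raises(ValueError, match="variational"):
            extrapolate_vs_inverse_d(ds, e, order=1)


class TestSpinGap:
    def make_fit(self, a0):
        ds = np.array([100.0, 200.0, 400.0])
        return extrapolate_vs_inverse_d(ds, a0 + 1.0 / ds, order=1)

    def test_identical_fits_give_zero(self):
        f = self.make_fit(-10.0)
        assert spin_gap(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_millihartree_conversion_and_sign(self):
        a = self.make_fit(-10.000)
        b = self.make_fit(-9.999)
        assert spin_gap(a, b) == pytest.approx(1.0, abs=1e-6)
        assert spin_gap(b, a) == pytest.approx(-1.0, abs=1e-6)

    def test_translation_invariance(self):
        a, b = self.make_fit(-10.0), self.make_fit(-9.99)
        a2, b2 = self.make_fit(-110.0), self.make_fit(-109.99)
        assert spin_gap(a, b) == pytest.approx(spin_gap(a2, b2), abs=1e-9)


class TestScalingFit:
    def test_pure_power_laws(self):
        d = np.array([8.0, 16.0, 32.0, 64.0, 128.0])
        assert fit_scaling_exponent(d, 3.0 * d ** 3).exponent == \
            pytest.approx(3.0, abs=1e-12)
        assert fit_scaling_exponent(d, 0.5 * d).exponent == \
            pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_cost_rescaling(self):
        d = np.array([8.0, 16.0, 32.0, 64.0])
        c = d ** 2.5 + d
        e1 = fit_scaling_exponent(d, c).exponent
        e2 = fit_scaling_exponent(d, 77.0 * c).exponent
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_window_restriction(self):
        d = np.array([2.0, 4.0, 64.0, 128.0, 256.0])
        c = np.where(d < 10, d, d ** 3)
        fit = fit_scaling_exponent(d, c, window=(64, 256))
        assert fit.exponent == pytest.approx(3.0, abs=1e-12)
        assert fit.window == (64, 256)

    def test_rejects_nonpositive_costs_and_thin_windows(self):
        with pytest.raises(ValueError, match="positive"):
            fit_scaling_exponent([2.0, 4.0], [1.0, 0.0])
        with pytest.raises(ValueError, match="window"):
            fit_scaling_exponent([2.0, 4.0, 8.0], [1, 2, 3], window=(3, 3.5))


class TestSweepReport:
    def make_records(self, energies, dws=None):
        dws = dws or [0.0] * len(energies)
        return [SweepRecord(i, e, dw, 4, 6, 10, {"heff": 100 * (i + 1)})
                for i, (e, dw) in enumerate(zip(energies, dws))]

    def test_single_record_has_blank_delta(self):
        df = sweep_report(self.make_records([-1.0]))
        assert len(df) == 1
        assert np.isnan(df["abs_delta_e"].iloc[0])

    def test_monotone_deltas_and_flags(self):
        energies = [-1.0, -1.5, -1.50002, -1.5000201, -1.50002011]
        df = sweep_report(self.make_records(energies), energy_tol=1e-8)
        deltas = df["abs_delta_e"].to_numpy()[1:]
        assert all(a >= b for a, b in zip(deltas, deltas[1:]))
        # production threshold (1e-5) first crossed at sweep 3
        assert df["converged_production"].tolist() == \
            [False, False, False, True, False]
        assert df["converged_target"].tolist() == \
            [False, False, False, False, True]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sweep_report([])
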