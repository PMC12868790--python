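"""Phasor transform, universal circle, calibration, and phase lifetime."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skinphasor as sp


def make_field(stack, cal=None):
    field = sp.phasor_transform(stack)
    return sp.apply_calibration(field, cal) if cal is not None else field


class TestPhasorTransform:
    def test_delta_in_bin_zero_on_unit_circle(self, acq_clean):
        counts = np.zeros((2, 2, acq_clean.n_bins))
        counts[..., 0] = 50.0
        field = sp.phasor_transform(sp.DecayStack(counts, acq_clean))
        t0 = acq_clean.bin_width / 2
        for n in (1, 2):
            assert field.g[n][0, 0] == pytest.approx(np.cos(n * acq_clean.omega * t0), abs=1e-12)
            assert field.s[n][0, 0] == pytest.approx(np.sin(n * acq_clean.omega * t0), abs=1e-12)

    def test_uniform_counts_have_zero_phasor(self, acq_clean):
        counts = np.full((3, 3, acq_clean.n_bins), 7.0)
        field = sp.phasor_transform(sp.DecayStack(counts, acq_clean))
        for n in (1, 2):
            assert np.abs(field.g[n]).max() < 1e-12
            assert np.abs(field.s[n]).max() < 1e-12

    def test_intensity_equals_time_sum_exactly(self, acq_default):
        stack = sp.make_monoexponential_stack(1.1, (16, 16), 100.0, acq_default, seed=3)
        field = sp.phasor_transform(stack)
        np.testing.assert_array_equal(field.intensity, stack.counts.sum(axis=2))

    def test_zero_photon_pixels_flagged_undefined(self, acq_clean):
        counts = np.zeros((2, 2, acq_clean.n_bins))
        counts[0, 0, 3] = 10.0
        field = sp.phasor_transform(sp.DecayStack(counts, acq_clean))
        assert field.defined[0, 0]
        assert not field.defined[1, 1]
        assert np.isnan(field.g[1][1, 1])

    def test_harmonic_beyond_nyquist_rejected(self, acq_clean):
        stack = sp.make_monoexponential_stack(1.0, (2, 2), 10.0, acq_clean, noise=False)
        with pytest.raises(ValueError, match="harmonic"):
            sp.phasor_transform(stack, harmonics=(1, 16))

    def test_matches_direct_summation_oracle(self, acq_clean):
        """Uncalibrated phasor of a noiseless decay equals an independently
        coded double loop over bins."""
        stack = sp.make_monoexponential_stack(
            2.5, (2, 2), 225.0, acq_clean, noise=False, sampling="integrated",
            distort=False,
        )
        field = sp.phasor_transform(stack)
        c = stack.counts[0, 0]
        num_g = num_s = den = 0.0
        for k in range(acq_clean.n_bins):
            tk = (k + 0.5) * acq_clean.bin_width
            num_g += c[k] * np.cos(acq_clean.omega * tk)
            num_s += c[k] * np.sin(acq_clean.omega * tk)
            den += c[k]
        assert field.g[1][0, 0] == pytest.approx(num_g / den, abs=1e-12)
        assert field.s[1][0, 0] == pytest.approx(num_s / den, abs=1e-12)


class TestAnalyticPhasor:
    def test_limits(self, acq_clean):
        assert sp.analytic_phasor(0.0, 1, acq_clean) == (1.0, 0.0)
        g, s = sp.analytic_phasor(1e9, 1, acq_clean)
        assert abs(g) < 1e-6 and abs(s) < 1e-3

    def test_coumarin_value(self, acq_clean):
        g, s = sp.analytic_phasor(2.5, 1, acq_clean)
        assert g == pytest.approx(0.38773, abs=1e-5)
        assert s == pytest.approx(0.48723, abs=1e-5)

    def test_cross_check_numeric_fourier_integral(self, acq_clean):
        tau, n = 2.5, 1
        t = np.linspace(0, 200 * tau, 2_000_001)
        decay = np.exp(-t / tau)
        g_num = np.trapezoid(decay * np.cos(n * acq_clean.omega * t), t)
        s_num = np.trapezoid(decay * np.sin(n * acq_clean.omega * t), t)
        norm = np.trapezoid(decay, t)
        g, s = sp.analytic_phasor(tau, n, acq_clean)
        assert g == pytest.approx(g_num / norm, abs=1e-6)
        assert s == pytest.approx(s_num / norm, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tau=st.floats(0.0, 50.0), n=st.integers(1, 2))
    def test_always_on_universal_circle(self, tau, n):
        acq = sp.AcquisitionModel(irf_sigma=0.0)
        g, s = sp.analytic_phasor(tau, n, acq)
        assert abs(g * g + s * s - g) < 1e-12


class TestCalibration:
    def test_identity_reference_gives_identity_factors(self, acq_clean):
        ref = sp.make_monoexponential_stack(2.5, (8, 8), 100.0, acq_clean, noise=False)
        cal = sp.compute_calibration(ref, 2.5)
        for n in (1, 2):
            assert cal.modulation[n] == pytest.approx(1.0, abs=1e-12)
            assert cal.phase[n] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_distortion(self, acq_distorted):
        ref = sp.make_monoexponential_stack(
            2.5, (8, 8), 100.0, acq_distorted, noise=False
        )
        # isolate phase/modulation by comparing against the IRF-only chain
        cal = sp.compute_calibration(ref, 2.5)
        irf_only = sp.AcquisitionModel(irf_sigma=acq_distorted.irf_sigma)
        base = sp.compute_calibration(
            sp.make_monoexponential_stack(2.5, (8, 8), 100.0, irf_only, noise=False),
            2.5,
        )
        assert cal.phase[1] - base.phase[1] == pytest.approx(0.3, abs=1e-6)
        assert cal.modulation[1] / base.modulation[1] == pytest.approx(
            1 / 0.8, abs=1e-6
        )

    def test_cross_standard_round_trip(self, acq_distorted):
        """Calibrate on Coumarin 6 (2.5 ns), read POPOP at 1.45 ns, and
        vice versa -- the reference-dye workflow closes to 0.01 ns."""
        cou = sp.make_monoexponential_stack(2.5, (8, 8), 225.0, acq_distorted, noise=False)
        pop = sp.make_monoexponential_stack(1.45, (8, 8), 225.0, acq_distorted, noise=False)
        for ref_stack, ref_tau, probe, expected in (
            (cou, 2.5, pop, 1.45),
            (pop, 1.45, cou, 2.5),
        ):
            cal = sp.compute_calibration(ref_stack, ref_tau)
            tau_map = sp.phase_lifetime(make_field(probe, cal))
            assert np.nanmedian(tau_map) == pytest.approx(expected, abs=0.01)

    def test_unmodulated_reference_rejected(self, acq_clean):
        counts = np.full((2, 2, acq_clean.n_bins), 5.0)
        with pytest.raises(ValueError, match="unmodulated"):
            sp.compute_calibration(sp.DecayStack(counts, acq_clean), 2.5)

    def test_empty_reference_rejected(self, acq_clean):
        counts = np.zeros((2, 2, acq_clean.n_bins))
        with pytest.raises(ValueError):
            sp.compute_calibration(sp.DecayStack(counts, acq_clean), 2.5)

    def test_double_calibration_rejected(self, acq_distorted, coumarin_cal_distorted):
        stack = sp.make_monoexponential_stack(1.1, (4, 4), 50.0, acq_distorted, noise=False)
        field = make_field(stack, coumarin_cal_distorted)
        with pytest.raises(ValueError, match="calibrated"):
            sp.apply_calibration(field, coumarin_cal_distorted)

    def test_apply_calibration_is_complex_rotation(self, acq_clean):
        field = sp.PhasorField(
            g={1: np.array([[1.0]]), 2: np.array([[0.5]])},
            s={1: np.array([[0.0]]), 2: np.array([[0.0]])},
            intensity=np.array([[10.0]]),
            harmonics=(1, 2),
            acquisition=acq_clean,
        )
        cal = sp.CalibrationFactors(
            modulation={1: 1.0, 2: 2.0}, phase={1: np.pi / 2, 2: 0.0}
        )
        out = sp.apply_calibration(field, cal)
        assert out.g[1][0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.s[1][0, 0] == pytest.approx(1.0, abs=1e-12)
        assert out.g[2][0, 0] == pytest.approx(1.0, abs=1e-12)
        assert out.calibrated

    @pytest.mark.parametrize("tau", [0.4, 1.1, 3.4])
    def test_calibration_invariance(self, tau):
        """Calibrated phasors match the analytic value regardless of the
        instrument distortion used during generation."""
        for phase, mod in ((0.0, 1.0), (0.3, 0.8), (-1.1, 0.55)):
            acq = sp.AcquisitionModel(phase_offset=phase, mod_loss=mod)
            ref = sp.make_monoexponential_stack(2.5, (4, 4), 100.0, acq, noise=False)
            cal = sp.compute_calibration(ref, 2.5)
            stack = sp.make_monoexponential_stack(tau, (4, 4), 100.0, acq, noise=False)
            field = make_field(stack, cal)
            for n in (1, 2):
                g_ref, s_ref = sp.analytic_phasor(tau, n, acq)
                assert abs(field.g[n][0, 0] - g_ref) < 1e-6
                assert abs(field.s[n][0, 0] - s_ref) < 1e-6


class TestPhaseLifetime:
    def test_requires_calibration(self, acq_clean):
        stack = sp.make_monoexponential_stack(1.0, (2, 2), 10.0, acq_clean, noise=False)
        with pytest.raises(ValueError, match="calibrat"):
            sp.phase_lifetime(sp.phasor_transform(stack))

    def test_point_values(self, acq_clean):
        field = sp.PhasorField(
            g={1: np.array([[1.0, 0.5, -0.2]])},
            s={1: np.array([[0.0, 0.5, 0.5]])},
            intensity=np.array([[1.0, 1.0, 1.0]]),
            harmonics=(1,),
            acquisition=acq_clean,
            calibrated=True,
        )
        tau = sp.phase_lifetime(field, n=1)
        assert tau[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert tau[0, 1] == pytest.approx(1 / acq_clean.omega, rel=1e-9)
        assert tau[0, 1] == pytest.approx(1.98944, abs=1e-5)
        assert np.isnan(tau[0, 2])  # g <= 0 is flagged, not extrapolated

    def test_monotone_along_universal_circle(self, acq_clean):
        taus = np.linspace(0.0, 20.0, 200)
        phases = []
        lifetimes = []
        for t in taus:
            g, s = sp.analytic_phasor(t, 1, acq_clean)
            phases.append(np.arctan2(s, g))
            lifetimes.append(np.tan(np.arctan2(s, g)) / acq_clean.omega)
        assert np.all(np.diff(phases) > 0)
        np.testing.assert_allclose(lifetimes, taus, atol=1e-9)

    def test_pure_keratin_region_reads_its_lifetime(
        self, acq_distorted, coumarin_cal_distorted
    ):
        stack = sp.make_monoexponential_stack(
            1.1, (8, 8), 225.0, acq_distorted, noise=False
        )
        tau = sp.phase_lifetime(make_field(stack, coumarin_cal_distorted))
        assert np.nanmedian(tau) == pytest.approx(1.1, abs=0.02)


class TestLinearity:
    def test_mixture_phasor_is_photon_weighted_vertex_sum(
        self, components, acq_distorted, coumarin_cal_distorted
    ):
        fractions = np.array([0.1, 0.2, 0.3, 0.4])
        basis = np.stack(
            [
                sp.decay_model(c.tau, acq_distorted, sampling="bandlimited", apply_irf=False)
                for c in components
            ]
        )
        counts = (fractions @ basis)[None, None, :] * 300.0
        stack = sp.apply_instrument_distortion(sp.DecayStack(counts, acq_distorted))
        field = make_field(stack, coumarin_cal_distorted)
        for n in (1, 2):
            expected = sum(
                f * complex(*c.phasor(n, acq_distorted))
                for f, c in zip(fractions, components)
            )
            assert abs(field.complex(n)[0, 0] - expected) < 1e-6
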