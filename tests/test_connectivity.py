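"""MVAR fitting, transfer matrices, DTF, cross-spectra, iCOH and wPLI."""

import numpy as np
import pytest

from relconn.cohort import GroundTruthSpec, generate_mvar_recording
from relconn.connectivity import (CrossSpectrum, MVARModel, analytic_dtf,
                                  coherence_magnitude, cross_spectrum,
                                  default_freq_grid, dtf, dtf_spectrum,
                                  fit_mvar, icoh, transfer_matrix, wpli,
                                  wpli_from_epoch)
from relconn.preprocessing import BANDS, Epoch


def _simulate(coeffs, n_samples, rng, burn=300):
    p, n, _ = coeffs.shape
    x = np.zeros((n_samples + burn, n))
    e = rng.standard_normal((n_samples + burn, n))
    for t in range(p, n_samples + burn):
        x[t] = e[t] + sum(coeffs[k] @ x[t - k - 1] for k in range(p))
    return x[burn:].T


class TestFitMVAR:
    A2 = np.array([[[0.5, 0.3], [0.0, 0.4]],
                   [[-0.2, 0.0], [0.1, -0.25]]])

    def test_recovers_order_two(self):
        hits = 0
        for seed in range(20):
            x = _simulate(self.A2, 3000, np.random.default_rng(seed))
            m = fit_mvar(x, 1, 8)
            hits += m.order == 2
        assert hits >= 18

    def test_recovers_coefficients(self):
        x = _simulate(self.A2, 20000, np.random.default_rng(0))
        m = fit_mvar(x, 2, 2)
        np.testing.assert_allclose(m.coeffs, self.A2, atol=0.03)
        np.testing.assert_allclose(m.noise_cov, np.eye(2), atol=0.05)

    def test_white_noise_selects_minimum_order(self):
        rng = np.random.default_rng(3)
        m = fit_mvar(rng.standard_normal((3, 3000)), 1, 6)
        assert m.order == 1

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_mvar(np.zeros((4, 100)), 1, 30)

    def test_rank_deficient_input_still_fits(self, rng):
        x = rng.standard_normal((3, 2000))
        x[2] = x[0] + x[1]          # exactly dependent channel
        m = fit_mvar(x, 1, 4)
        assert m.stable
        H = transfer_matrix(m, default_freq_grid(), 500.0)
        assert np.all(np.isfinite(H.H))


class TestTransferMatrix:
    def test_zero_coefficients_give_identity(self):
        m = MVARModel(1, np.zeros((1, 3, 3)), np.eye(3), 0.0, True)
        H = transfer_matrix(m, np.array([0.0, 5.0, 20.0]), 100.0)
        for h in H.H:
            np.testing.assert_allclose(h, np.eye(3), atol=1e-14)

    def test_scalar_ar_dc_gain(self):
        m = MVARModel(1, np.array([[[0.5]]]), np.eye(1), 0.0, True)
        H = transfer_matrix(m, np.array([0.0]), 100.0)
        assert abs(H.H[0, 0, 0]) == pytest.approx(2.0)

    def test_matches_bruteforce_polynomial_inversion(self, rng):
        A = np.array([[[0.4, 0.2], [-0.1, 0.3]],
                      [[0.0, -0.15], [0.05, 0.1]]])
        fs = 100.0
        freqs = np.linspace(1, 45, 23)
        m = MVARModel(2, A, np.eye(2), 0.0, True)
        H = transfer_matrix(m, freqs, fs)
        for fi, f in enumerate(freqs):
            z1 = np.exp(-2j * np.pi * f / fs)
            M = np.eye(2) - A[0] * z1 - A[1] * z1**2
            np.testing.assert_allclose(H.H[fi], np.linalg.inv(M), atol=1e-12)


class TestDTF:
    def test_identity_transfer_gives_self_inflow_only(self):
        m = MVARModel(1, np.zeros((1, 4, 4)), np.eye(4), 0.0, True)
        H = transfer_matrix(m, default_freq_grid(), 500.0)
        W = dtf(H, BANDS["alpha"]).W
        np.testing.assert_allclose(np.diag(W), 1.0)
        np.testing.assert_allclose(W - np.diag(np.diag(W)), 0.0, atol=1e-14)

    def test_inflow_normalization_sums_to_one(self, stable_coeffs):
        m = MVARModel(stable_coeffs.shape[0], stable_coeffs,
                      np.eye(stable_coeffs.shape[1]), 0.0, True)
        H = transfer_matrix(m, default_freq_grid(), 500.0)
        D = dtf_spectrum(H)                      # (f, sink, source)
        np.testing.assert_allclose(D.sum(axis=2), 1.0, atol=1e-10)

    def test_unidirectional_coupling_resolved_by_analytic_dtf(self, unidir_spec):
        W = analytic_dtf(unidir_spec.coefficient_array(), 500.0, BANDS["alpha"])
        assert W[0, 1] > W[1, 0]
        assert W[1, 0] < 0.05

    def test_band_outside_grid_rejected(self):
        from relconn.preprocessing import BandDefinition

        m = MVARModel(1, np.zeros((1, 2, 2)), np.eye(2), 0.0, True)
        H = transfer_matrix(m, np.array([1.0, 2.0]), 100.0)
        with pytest.raises(ValueError, match="no\\s+bins"):
            dtf(H, BandDefinition("x", 30.0, 40.0))


class TestCrossSpectrum:
    def test_hermitian_and_nonnegative_auto(self, rng):
        x = rng.standard_normal((3, 2000))
        S = cross_spectrum(x, fs=500.0)
        for s in S.S:
            np.testing.assert_allclose(s, s.conj().T, atol=1e-12)
            assert np.all(np.real(np.diag(s)) >= 0)

    def test_identical_channels_have_unit_coherence(self, rng):
        x = rng.standard_normal(3000)
        S = cross_spectrum(np.vstack([x, x]), fs=500.0)
        coh = coherence_magnitude(S, BANDS["alpha"])
        assert coh[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_channels_coherence_shrinks_with_segments(self, rng):
        x = rng.standard_normal((2, 30000))
        coh_few = coherence_magnitude(
            cross_spectrum(x[:, :3000], fs=500.0), BANDS["full"])[0, 1]
        coh_many = coherence_magnitude(
            cross_spectrum(x, fs=500.0), BANDS["full"])[0, 1]
        assert coh_many < coh_few
        assert coh_many < 0.15

    def test_parseval_auto_spectrum_integrates_to_variance(self, rng):
        x = rng.standard_normal((1, 60000))
        S = cross_spectrum(x, fs=500.0, seg_s=1.0)
        df = S.freqs[1] - S.freqs[0]
        power = np.real(S.S[:, 0, 0]).sum() * df
        assert power == pytest.approx(np.var(x), rel=0.02)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            cross_spectrum(np.zeros((2, 400)), fs=500.0, seg_s=1.0)


def _delayed_sine_pair(freq=10.0, fs=500.0, n=3000, delay_samples=13, seed=0):
    """10 Hz sinusoid plus tiny noise; channel 2 is a delayed copy (~T/4)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x1 = np.sin(2 * np.pi * freq * t) + 0.01 * rng.standard_normal(n)
    x2 = np.roll(x1, delay_samples)
    return np.vstack([x1, x2])


class TestICoh:
    def test_zero_lag_copy_gives_zero(self, rng):
        x = rng.standard_normal(3000)
        S = cross_spectrum(np.vstack([x, x]), fs=500.0)
        W = icoh(S, BANDS["alpha"]).W
        assert W[0, 1] < 1e-10

    def test_quarter_period_delay_maximal(self):
        S = cross_spectrum(_delayed_sine_pair(), fs=500.0)
        W = icoh(S, BANDS["alpha"]).W
        assert W[0, 1] > 0.9

    def test_antiphase_gives_zero(self, rng):
        x = rng.standard_normal(3000)
        S = cross_spectrum(np.vstack([x, -x]), fs=500.0)
        W = icoh(S, BANDS["alpha"]).W
        assert W[0, 1] < 1e-10


class TestWPLI:
    def test_zero_lag_mixture_vanishes_with_segments(self, rng):
        # zero-lag mixing gives a real cross-spectrum in expectation; the
        # finite-sample wPLI shrinks like 1/sqrt(n_segments)
        s = rng.standard_normal((2, 150000))
        mix = np.array([[1.0, 0.6], [0.6, 1.0]])
        _, segs = cross_spectrum(mix @ s, fs=500.0, return_segments=True)
        W = wpli(segs, BANDS["alpha"]).W
        assert W[0, 1] < 0.08

    def test_consistent_lag_gives_one(self):
        _, segs = cross_spectrum(_delayed_sine_pair(), fs=500.0,
                                 return_segments=True)
        W = wpli(segs, BANDS["alpha"]).W
        assert W[0, 1] > 0.99

    def test_balanced_sign_flips_shrink_wpli(self):
        # alternate the lag direction between segments: Im S changes sign
        rng = np.random.default_rng(4)
        segs = []
        nf, n = 10, 2
        for k in range(40):
            S = np.zeros((nf, n, n), complex)
            im = (1.0 if k % 2 == 0 else -1.0) * (1 + 0.1 * rng.random(nf))
            S[:, 0, 1] = 1j * im
            S[:, 1, 0] = -1j * im
            S[:, 0, 0] = S[:, 1, 1] = 1.0
            segs.append(CrossSpectrum(S, np.linspace(8, 12.5, nf), 1))
        W = wpli(segs, BANDS["alpha"]).W
        assert W[0, 1] < 0.1

    def test_vanishing_imaginary_part_defined_as_zero(self):
        segs = []
        nf = 5
        for _ in range(3):
            S = np.ones((nf, 2, 2), complex)
            segs.append(CrossSpectrum(S, np.linspace(9, 11, nf), 1))
        W = wpli(segs, BANDS["alpha"]).W
        assert W[0, 1] == 0.0


class TestVolumeConductionRobustness:
    def test_zero_lag_mixing_spares_icoh_and_wpli_not_coherence(self):
        # two independent AR(1) sources, observed through zero-lag mixing;
        # independent (non-overlapping) segments so the finite-sample wPLI
        # floor is well below the robustness bound
        from scipy.signal import lfilter

        rng = np.random.default_rng(8)
        s = lfilter([1.0], [1.0, -0.6], rng.standard_normal((2, 2400000)),
                    axis=-1)
        mix = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = mix @ s
        S, segs = cross_spectrum(x, fs=500.0, overlap=0.0,
                                 return_segments=True)
        assert coherence_magnitude(S, BANDS["alpha"])[0, 1] > 0.5
        assert icoh(S, BANDS["alpha"]).W[0, 1] < 0.05
        assert wpli(segs, BANDS["alpha"]).W[0, 1] < 0.05


class TestInvariances:
    def test_estimators_are_permutation_equivariant(self, rng):
        x = _simulate(np.array([[[0.5, 0.3, 0.0],
                                 [0.0, 0.4, 0.2],
                                 [0.1, 0.0, 0.3]]]), 4000, rng)
        perm = np.array([2, 0, 1])
        xp = x[perm]
        ep = Epoch(x, 500.0, 1)
        epp = Epoch(xp, 500.0, 1)
        for estimate in (
            lambda e: dtf(transfer_matrix(fit_mvar(e, 1, 3),
                                          default_freq_grid(), 500.0),
                          BANDS["alpha"]).W,
            lambda e: icoh(cross_spectrum(e), BANDS["alpha"]).W,
            lambda e: wpli_from_epoch(e, BANDS["alpha"]).W,
        ):
            W = estimate(ep)
            Wp = estimate(epp)
            np.testing.assert_allclose(Wp, W[np.ix_(perm, perm)], atol=1e-8)

    def test_long_recording_dtf_matches_analytic_ground_truth(self):
        spec = GroundTruthSpec(
            n_channels=3, mvar_order=1,
            coupling=[(0, 0, (0.5,)), (1, 1, (0.5,)), (2, 2, (0.5,)),
                      (0, 1, (0.35,)), (1, 2, (0.3,))],
            seed=5)
        rec = generate_mvar_recording(spec, 120.0, 500.0)
        m = fit_mvar(rec.data, 1, 3)
        W_est = dtf(transfer_matrix(m, default_freq_grid(), 500.0),
                    BANDS["full"]).W
        W_true = analytic_dtf(spec.coefficient_array(), 500.0, BANDS["full"])
        r = np.corrcoef(W_est.ravel(), W_true.ravel())[0, 1]
        assert r > 0.95
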