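"""MVAR estimation and generalized partial directed coherence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimnet.connectivity import (
    MVAR,
    band_mean_gpdc,
    fit_mvar,
    gpdc,
    gpdc_surrogate_null,
    phase_randomized,
    spectral_transfer,
)
from stimnet.containers import DEFAULT_BANDS, BandDefinition, MVARModel
from stimnet.synthetic import simulate_mvar


def random_model(seed, k=3, p=2, fs=500.0):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        a = rng.normal(0, 0.15, size=(p, k, k))
        sig = np.diag(rng.uniform(0.5, 2.0, size=k))
        model = MVARModel(A=a, Sigma=sig, fs_hz=fs)
        if model.spectral_radius() < 0.95:
            return model
    raise RuntimeError


class TestFitMVAR:
    def test_recovers_known_coefficients(self, random_stable_mvar):
        rec = simulate_mvar(random_stable_mvar, 20_000, seed=1)
        model = fit_mvar(rec, order=3)
        assert np.abs(model.A - random_stable_mvar.A).max() < 0.05

    def test_statsmodels_var_oracle_agreement(self, random_stable_mvar):
        # Independent estimator: statsmodels VAR on the same realization.
        from statsmodels.tsa.api import VAR

        rec = simulate_mvar(random_stable_mvar, 8000, seed=2)
        mine = fit_mvar(rec, order=3)
        sm_fit = VAR(rec.data.T).fit(maxlags=3, trend="n")
        assert np.allclose(mine.A, sm_fit.coefs, atol=1e-6)

    def test_white_channels_have_no_cross_structure(self, rng):
        from stimnet.containers import MultichannelRecording

        n = 20_000
        rec = MultichannelRecording(data=rng.standard_normal((4, n)),
                                    fs_hz=500.0, labels=tuple("abcd"))
        model = fit_mvar(rec, order=2)
        se = 3.0 / np.sqrt(n)
        off = model.A[:, ~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3 * se  # generous null bound

    def test_order_zero_rejected(self, rng):
        from stimnet.containers import MultichannelRecording

        rec = MultichannelRecording(data=rng.standard_normal((2, 1000)),
                                    fs_hz=500.0, labels=("a", "b"))
        with pytest.raises(ValueError):
            fit_mvar(rec, order=0)

    def test_bic_selects_true_order(self, random_stable_mvar):
        rec = simulate_mvar(random_stable_mvar, 20_000, seed=3)
        model = fit_mvar(rec, order="bic", max_order=8)
        assert model.p == random_stable_mvar.p


class TestSpectralTransfer:
    def test_zero_frequency_closed_form(self, random_stable_mvar):
        abar = spectral_transfer(random_stable_mvar, np.array([0.0]))
        expected = np.eye(5) - random_stable_mvar.A.sum(axis=0)
        assert np.allclose(abar[0], expected)

    def test_no_coefficients_gives_identity(self):
        model = MVARModel(A=np.zeros((2, 3, 3)), Sigma=np.eye(3), fs_hz=500.0)
        abar = spectral_transfer(model, np.array([10.0, 50.0, 200.0]))
        assert np.allclose(abar, np.eye(3)[None])

    def test_univariate_hand_value(self):
        # AR(1), a=0.5, fs=500, f=125: Abar = 1 - 0.5 e^{-i pi/2} = 1 + 0.5i.
        model = MVARModel(A=np.array([[[0.5]]]), Sigma=np.eye(1), fs_hz=500.0)
        abar = spectral_transfer(model, np.array([125.0]))
        assert abar[0, 0, 0] == pytest.approx(1 + 0.5j, abs=1e-12)


class TestGPDC:
    def test_diagonal_model_has_no_cross_flow(self):
        a = np.zeros((1, 3, 3))
        np.fill_diagonal(a[0], [0.5, -0.3, 0.2])
        model = MVARModel(A=a, Sigma=np.diag([1.0, 2.0, 0.5]), fs_hz=500.0)
        spec = gpdc(model)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(spec.pi_abs[off], 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_column_normalization_invariant(self, seed):
        spec = gpdc(random_model(seed))
        col = np.sum(spec.pi_abs**2, axis=0)
        assert np.abs(col - 1.0).max() < 1e-10
        assert spec.pi_abs.min() >= 0.0
        assert spec.pi_abs.max() <= 1.0 + 1e-12

    def test_bivariate_hand_evaluation_at_f0(self):
        # Coupling 2->1 (a12=0.4), diagonals 0.5, unit innovations.
        # Abar(0) = [[0.5, -0.4], [0, 0.5]];
        # |pi_12| = 0.4/sqrt(0.16+0.25), |pi_22| = 0.5/sqrt(0.41).
        a = np.array([[[0.5, 0.4], [0.0, 0.5]]])
        model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0)
        spec = gpdc(model, freqs=np.array([0.0]))
        assert spec.pi_abs[0, 1, 0] == pytest.approx(0.4 / np.sqrt(0.41), abs=1e-12)
        assert spec.pi_abs[1, 1, 0] == pytest.approx(0.5 / np.sqrt(0.41), abs=1e-12)
        assert spec.pi_abs[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert spec.pi_abs[1, 0, 0] == 0.0

    def test_unidirectional_coupling_zero_reverse(self):
        a = np.array([[[0.5, 0.4], [0.0, 0.5]]])
        model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0)
        spec = gpdc(model)
        assert np.all(spec.pi_abs[1, 0] == 0.0)  # 1 -> 2 never flows
        assert np.all(spec.pi_abs[0, 1] > 0.0)

    def test_scale_invariance_of_sparsity_pattern(self):
        # Rescaling one channel's data rescales its row of A and its sigma;
        # the zero/nonzero pattern of gPDC must not change.
        a = np.array([[[0.5, 0.4], [0.0, 0.5]]])
        m1 = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0)
        c = 10.0
        a2 = a.copy()
        a2[0, 0, 1] = a[0, 0, 1] * c  # row 1 now sees channel-2 units scaled
        m2 = MVARModel(A=a2, Sigma=np.diag([c**2, 1.0]), fs_hz=500.0)
        s1, s2 = gpdc(m1), gpdc(m2)
        assert np.array_equal(s1.pi_abs == 0, s2.pi_abs == 0)

    def test_zero_innovation_variance_rejected(self):
        model = MVARModel(A=np.zeros((1, 2, 2)), Sigma=np.diag([1.0, 0.0]),
                          fs_hz=500.0)
        with pytest.raises(ValueError):
            gpdc(model)


class TestBandMean:
    def test_constant_spectrum_mean(self):
        a = np.array([[[0.5, 0.4], [0.0, 0.5]]])
        model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0,
                          labels=("x", "y"))
        spec = gpdc(model, freqs=np.array([22.0, 25.0, 28.0]))
        table = band_mean_gpdc(spec, DEFAULT_BANDS["high_beta"])
        got = table.set_index(["source", "target"])["gpdc"]
        assert got[("y", "x")] == pytest.approx(spec.pi_abs[0, 1].mean())

    def test_empty_band_rejected(self):
        model = MVARModel(A=np.zeros((1, 2, 2)) + 0.1 * np.eye(2),
                          Sigma=np.eye(2), fs_hz=500.0)
        spec = gpdc(model, freqs=np.array([50.0]))
        with pytest.raises(ValueError):
            band_mean_gpdc(spec, BandDefinition("hb", 21.0, 30.0))

    def test_self_pairs_rejected(self):
        model = MVARModel(A=0.1 * np.eye(2)[None], Sigma=np.eye(2),
                          fs_hz=500.0, labels=("x", "y"))
        spec = gpdc(model)
        with pytest.raises(ValueError):
            band_mean_gpdc(spec, DEFAULT_BANDS["high_beta"], [("x", "x")])


class TestSurrogates:
    def test_phase_randomization_preserves_amplitude_spectrum(self, rng):
        x = rng.standard_normal((2, 4096))
        surr = phase_randomized(x, rng)
        assert np.allclose(np.abs(np.fft.rfft(surr, axis=-1)),
                           np.abs(np.fft.rfft(x, axis=-1)), atol=1e-8)

    def test_reverse_direction_below_surrogate_null(self):
        # Unidirectional 2->1 coupling: the reverse band-mean gPDC must sit
        # below the 95th percentile of the phase-randomized null.
        a = np.zeros((2, 2, 2))
        a[0] = [[0.5, 0.0], [0.0, 0.5]]
        a[1, 0, 1] = 0.35
        model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0,
                          labels=("tgt", "src"))
        rec = simulate_mvar(model, 20_000, seed=6)
        fitted = fit_mvar(rec, order=2)
        spec = gpdc(fitted)
        band = DEFAULT_BANDS["high_beta"]
        fwd = band_mean_gpdc(spec, band, [("src", "tgt")])["gpdc"][0]
        rev = band_mean_gpdc(spec, band, [("tgt", "src")])["gpdc"][0]
        null = gpdc_surrogate_null(rec, band, [("tgt", "src")], order=2,
                                   n_surrogates=60, seed=7)
        assert rev < null[("tgt", "src")]
        assert fwd > null[("tgt", "src")]
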