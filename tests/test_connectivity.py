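"""Phase lag index: analytic phase, phase differences, matrices and the
480-feature vector, each checked against independent scalar oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plistack.connectivity import (
    analytic_phase,
    connectivity_matrix,
    feature_names,
    feature_vector,
    phase_difference,
    pli,
    pli_signed,
)
from plistack.montage import CANONICAL_BANDS, DEFAULT_MONTAGE, band_by_name
from plistack.preprocess import BandEpoch

RATE = 125.0


def _epoch(samples, band="beta", montage=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    montage = montage or DEFAULT_MONTAGE[: samples.shape[0]]
    return BandEpoch(samples=samples, rate=RATE, band=band_by_name(band),
                     window_length=samples.shape[1] / RATE, window_index=0,
                     subject_id="s", group="HC", montage=tuple(montage))


def _tone(freq, duration=4.0, phase=0.0):
    t = np.arange(0, duration, 1 / RATE)
    return np.cos(2 * np.pi * freq * t + phase)


def _fft_hilbert_oracle(x):
    """Independent frequency-domain analytic-signal construction."""
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1
    if n % 2 == 0:
        h[n // 2] = 1
        h[1:n // 2] = 2
    else:
        h[1:(n + 1) // 2] = 2
    return np.angle(np.fft.ifft(X * h))


def _pli_oracle(sa, sb):
    """Naive per-sample scalar-loop PLI."""
    za = np.array([complex(r, i) for r, i in
                   zip(sa, np.imag(__import__("scipy.signal", fromlist=["hilbert"]).hilbert(sa)))])
    zb = np.array([complex(r, i) for r, i in
                   zip(sb, np.imag(__import__("scipy.signal", fromlist=["hilbert"]).hilbert(sb)))])
    total = 0.0
    for a, b in zip(za, zb):
        d = np.angle(a * np.conj(b))
        total += np.sign(d)
    return abs(total / len(za))


class TestAnalyticPhase:
    def test_cosine_constant_phase_increment(self):
        x = _tone(10.0)
        phase = np.unwrap(analytic_phase(x))
        inc = np.diff(phase)[10:-10]
        assert np.allclose(inc, 2 * np.pi * 10.0 / RATE, atol=1e-6)

    def test_quadrature_pair(self):
        t = np.arange(0, 4, 1 / RATE)
        pa = analytic_phase(np.sin(2 * np.pi * 10 * t))
        pb = analytic_phase(np.cos(2 * np.pi * 10 * t))
        d = phase_difference(pa, pb)[10:-10]
        assert np.allclose(d, -np.pi / 2, atol=1e-3)

    def test_matches_fft_oracle(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [13, 30], btype="bandpass", fs=RATE, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(1000))
        assert np.allclose(analytic_phase(x), _fft_hilbert_oracle(x), atol=1e-9)

    def test_all_zero_flagged(self):
        with pytest.warns(RuntimeWarning, match="all-zero"):
            out = analytic_phase(np.zeros(100))
        assert np.isnan(out).all()
        with pytest.warns(RuntimeWarning):
            assert pli(np.zeros(100), _tone(10)) == 0.0


class TestPhaseDifference:
    def test_identical_series_zero(self, rng):
        p = rng.uniform(-np.pi, np.pi, 200)
        assert np.all(phase_difference(p, p) == 0.0)

    def test_constant_offset(self, rng):
        p = rng.uniform(-np.pi, np.pi, 200)
        q = np.pi - np.mod(np.pi - (p - np.pi / 4), 2 * np.pi)
        d = phase_difference(p, q)
        assert np.allclose(d, np.pi / 4, atol=1e-12)

    def test_matches_atan2_oracle(self, rng):
        pa = rng.uniform(-np.pi, np.pi, 500)
        pb = rng.uniform(-np.pi, np.pi, 500)
        oracle = np.array([np.angle(np.exp(1j * a) * np.conj(np.exp(1j * b)))
                           for a, b in zip(pa, pb)])
        # both wrap to the same value up to the (-π, π] boundary convention
        d = phase_difference(pa, pb)
        assert np.allclose(np.exp(1j * d), np.exp(1j * oracle), atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            phase_difference(np.zeros(3), np.zeros(4))


class TestPLI:
    def test_lagged_sinusoids_give_one(self):
        assert pli(_tone(10.0), _tone(10.0, phase=-np.pi / 4)) == 1.0

    def test_self_pli_zero(self):
        x = _tone(10.0)
        assert pli(x, x) == 0.0

    def test_alternating_sign_cancels(self):
        # phases alternating ±0.1 around a common carrier cancel exactly
        pa = np.zeros(100)
        pb = np.where(np.arange(100) % 2 == 0, 0.1, -0.1)
        d = phase_difference(pa, pb)
        assert abs(np.mean(np.sign(d))) == 0.0

    def test_independent_white_noise_small(self, rng):
        sa = rng.standard_normal(15_000)
        sb = rng.standard_normal(15_000)
        assert pli(sa, sb) < 0.05

    def test_signed_and_absolute_consistent(self, rng):
        sa, sb = rng.standard_normal(500), rng.standard_normal(500)
        assert pli(sa, sb) == abs(pli_signed(sa, sb))
        assert pli(sa, sb) == pli(sb, sa)

    def test_global_phase_offset_invariance(self):
        sa, sb = _tone(10.0), _tone(10.0, phase=-0.8)
        sa2, sb2 = _tone(10.0, phase=0.3), _tone(10.0, phase=-0.5)
        assert pli(sa, sb) == pli(sa2, sb2) == 1.0


class TestConnectivityMatrix:
    def test_copied_channels_zero(self):
        x = _tone(20.0)
        mat = connectivity_matrix(_epoch(np.tile(x, (4, 1)))).values
        assert np.allclose(mat, 0.0)

    def test_planted_lagged_pair(self, rng):
        n_ch = 5
        sig = np.vstack([rng.standard_normal(500) * 0.0 + _tone(20.0, phase=rng.uniform(0, 2 * np.pi))
                         for _ in range(n_ch)])
        sig[1] = _tone(20.0)
        sig[3] = _tone(20.0, phase=-1.0)
        mat = connectivity_matrix(_epoch(sig)).values
        assert mat[1, 3] == mat[3, 1] == 1.0
        assert np.allclose(np.diag(mat), 0.0)

    def test_matches_pairwise_oracle(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [13, 30], btype="bandpass", fs=RATE, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal((6, 400)), axis=1)
        mat = connectivity_matrix(_epoch(x)).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(mat[i, j] - _pli_oracle(x[i], x[j])) < 1e-12

    def test_vectorized_equals_naive_on_random_epochs(self, rng):
        """50 random epochs: matrix builder equals the scalar-loop oracle."""
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8, 10], btype="bandpass", fs=RATE, output="sos")
        for _ in range(50):
            x = sosfiltfilt(sos, rng.standard_normal((3, 250)), axis=1)
            mat = connectivity_matrix(_epoch(x)).values
            for i in range(3):
                for j in range(i + 1, 3):
                    assert abs(mat[i, j] - _pli_oracle(x[i], x[j])) < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            connectivity_matrix(_epoch(_tone(20.0)))


class TestFeatureVector:
    @pytest.fixture()
    def four_band_epochs(self, rng):
        return {
            b.name: _epoch(rng.standard_normal((16, 250)), band=b.name)
            for b in CANONICAL_BANDS
        }

    def test_length_480(self, four_band_epochs):
        vec = feature_vector(four_band_epochs)
        assert vec.shape == (480,)
        assert np.all((vec >= 0) & (vec <= 1))
        assert len(feature_names()) == 480

    def test_missing_band_rejected(self, four_band_epochs):
        del four_band_epochs["beta"]
        with pytest.raises(ValueError, match="missing"):
            feature_vector(four_band_epochs)

    def test_band_slices_reproduce_matrices(self, four_band_epochs):
        vec = feature_vector(four_band_epochs)
        iu = np.triu_indices(16, k=1)
        for k, band in enumerate(("theta", "alpha1", "alpha2", "beta")):
            mat = connectivity_matrix(four_band_epochs[band]).values
            assert np.array_equal(vec[k * 120:(k + 1) * 120], mat[iu])


@given(st.integers(0, 2**32 - 1), st.floats(0.1, 3.0))
def test_pli_bounds_and_symmetry_property(seed, lag):
    """0 <= PLI <= 1 and channel-swap symmetry for arbitrary signals."""
    rng = np.random.default_rng(seed)
    sa = rng.standard_normal(64)
    sb = np.roll(sa, 3) + lag * rng.standard_normal(64)
    v = pli(sa, sb)
    assert 0.0 <= v <= 1.0
    assert v == pli(sb, sa)
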