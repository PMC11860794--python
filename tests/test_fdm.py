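"""Unit and property tests for the Fourier band decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdmcma.fdm import (
    DegenerateSignalError,
    Signal,
    analytic_signal,
    build_tf_map,
    decompose,
    instantaneous_tracks,
    normalize_signal,
    phase_positivity,
    scan_band,
    top_bin,
)

FS = 360.0


# ---------------------------------------------------------------- oracles

def brute_force_analytic(x):
    """Direct O(N^2) evaluation of the positive-half synthesis."""
    n = len(x)
    s = np.array([sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)) / n
                  for k in range(n)])
    top = (n - 1) // 2 if n % 2 else n // 2
    z = np.zeros(n, dtype=complex)
    for t in range(n):
        for l in range(1, top + 1):
            w = 1.0 if (n % 2 == 0 and l == top) else 2.0
            z[t] += w * s[l] * np.exp(2j * np.pi * l * t / n)
    return z, s[0].real


def unwrapped_phase_oracle(v, tol=1e-12):
    """Monotone-phase check via per-sample angles: every circular phase
    increment must have a nonnegative sine (weighted by the magnitudes)."""
    import math

    n = len(v)
    scale = max(1.0, max(abs(z) for z in v) ** 2) if n else 1.0
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        if abs(a) == 0.0 or abs(b) == 0.0:
            continue
        dphi = math.atan2(b.imag, b.real) - math.atan2(a.imag, a.real)
        if math.sin(dphi) * abs(a) * abs(b) < -tol * scale:
            return False
    return True


def exhaustive_scan_oracle(x, n_prev):
    """Literal band scan: one inverse DFT per candidate width."""
    n = len(x)
    spec = np.fft.fft(x) / n
    top = top_bin(n)
    best = 0
    for p in range(1, n_prev):
        u = np.zeros(n, dtype=complex)
        for k in range(n_prev - p, n_prev):
            w = 1.0 if (n % 2 == 0 and k == top) else 2.0
            u[k] = w * spec[k]
        v = np.fft.ifft(u) * n
        if unwrapped_phase_oracle(list(v)):
            best = p
    return n_prev - best


# ---------------------------------------------------------- normalization

def test_normalize_matches_hand_arithmetic():
    raw = Signal([1.0, -1.0, 1.0, -1.0, 1.0], FS)
    out = normalize_signal(raw)
    np.testing.assert_allclose(out.samples, [0.8, -1.2, 0.8, -1.2, 0.8])
    assert out.fs == FS


@given(c=st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_normalize_is_scale_invariant(c):
    base = np.array([0.5, -1.0, 0.75, -0.25, 0.0])  # mean-zero
    a = normalize_signal(Signal(base, FS)).samples
    b = normalize_signal(Signal(c * base, FS)).samples
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_normalize_rejects_all_zero_signal():
    with pytest.raises(DegenerateSignalError):
        normalize_signal(Signal(np.zeros(10), FS))


# -------------------------------------------------------- analytic signal

@pytest.mark.parametrize("n,k", [(16, 3), (17, 5), (32, 1)])
def test_analytic_signal_of_cosine_is_complex_exponential(n, k):
    t = np.arange(n)
    z = analytic_signal(Signal(np.cos(2 * np.pi * k * t / n), FS))
    np.testing.assert_allclose(z.values, np.exp(2j * np.pi * k * t / n), atol=1e-12)
    assert abs(z.dc) < 1e-12


def test_analytic_signal_real_part_inverts_noise(rng):
    x = rng.normal(size=31)
    x -= x.mean()
    z = analytic_signal(Signal(x, FS))
    np.testing.assert_allclose(z.values.real, x, atol=1e-10)
    assert abs(z.dc) < 1e-12


@pytest.mark.parametrize("n", [9, 10])
def test_analytic_signal_against_brute_force_oracle(n, rng):
    x = rng.normal(size=n)
    z = analytic_signal(Signal(x, FS))
    z_ref, dc_ref = brute_force_analytic(x)
    np.testing.assert_allclose(z.values, z_ref, atol=1e-10)
    assert abs(z.dc - dc_ref) < 1e-12
    np.testing.assert_allclose(z.dc + z.values.real, x, atol=1e-10)


# ------------------------------------------------------- phase positivity

def test_positive_frequency_exponential_passes():
    n = 16
    for k in (0, 1, 5):
        v = np.exp(2j * np.pi * k * np.arange(n) / n)
        assert phase_positivity(v)


def test_negative_frequency_exponential_fails():
    n = 8
    v = np.exp(-2j * np.pi * np.arange(n) / n)
    assert not phase_positivity(v)


def test_all_zero_vector_passes():
    assert phase_positivity(np.zeros(8, dtype=complex))


def test_positivity_matches_unwrap_oracle_on_two_tone_mixtures():
    rng = np.random.default_rng(99)
    agree = 0
    trials = 300
    for _ in range(trials):
        n = int(rng.integers(8, 65))
        k1, k2 = rng.integers(0, n // 2, size=2)
        a, b = rng.normal(size=2) + 1j * rng.normal(size=2)
        t = np.arange(n)
        v = a * np.exp(2j * np.pi * k1 * t / n) + b * np.exp(2j * np.pi * k2 * t / n)
        agree += phase_positivity(v) == unwrapped_phase_oracle(list(v))
    assert agree == trials


# --------------------------------------------------------------- scanning

def test_single_tone_spectrum_forms_one_band(rng):
    for n in (21, 22):
        k = 4
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = np.fft.fft(x) / n
        assert scan_band(spec, top_bin(n) + 1) == 1


def test_scan_band_matches_exhaustive_oracle(rng):
    for n in (17, 24, 33):
        for _ in range(5):
            x = rng.normal(size=n)
            n_prev = top_bin(n) + 1
            assert scan_band(np.fft.fft(x) / n, n_prev) == exhaustive_scan_oracle(x, n_prev)


def test_first_band_contains_its_dominant_tone(rng):
    n = 101
    t = np.arange(n)
    k1, k2 = 7, 35
    x = np.cos(2 * np.pi * k1 * t / n) + 0.8 * np.cos(2 * np.pi * k2 * t / n)
    n1 = scan_band(np.fft.fft(x) / n, top_bin(n) + 1)
    assert n1 <= k2


def test_scan_exhausted_raises():
    spec = np.fft.fft(np.ones(9)) / 9
    with pytest.raises(ValueError):
        scan_band(spec, 1)


# ------------------------------------------------------------ decompose

def test_single_tone_decomposes_to_one_band_with_constant_if():
    n, k = 101, 10
    x = np.cos(2 * np.pi * k * np.arange(n) / n)
    dec = decompose(normalize_signal(Signal(x, FS)))
    assert dec.m == 1
    band = dec.afibfs[0]
    assert (band.band_lo, band.band_hi) == (1, top_bin(n))
    np.testing.assert_allclose(band.ifreq, k * FS / n, atol=1e-6)


def test_two_tone_partition_and_reconstruction():
    n = 201
    t = np.arange(n)
    x = np.cos(2 * np.pi * 5 * t / n) + np.cos(2 * np.pi * 40 * t / n)
    s = normalize_signal(Signal(x, FS))
    dec = decompose(s)
    covered = sorted(b for a in dec.afibfs for b in range(a.band_lo, a.band_hi + 1))
    assert covered == list(range(1, top_bin(n) + 1))
    err = np.max(np.abs(dec.reconstruct() - s.samples))
    assert err < 1e-9 * np.max(np.abs(s.samples))


def test_afibfs_are_mutually_orthogonal(rng):
    x = rng.normal(size=63)
    x -= x.mean()
    dec = decompose(normalize_signal(Signal(x, FS)))
    for i in range(dec.m):
        for j in range(i + 1, dec.m):
            wi, wj = dec.afibfs[i].values, dec.afibfs[j].values
            ip = abs(np.vdot(wi, wj))
            assert ip < 1e-9 * np.linalg.norm(wi) * np.linalg.norm(wj)


def test_completeness_on_random_signals_both_parities(rng):
    for n in (9, 10, 33, 64, 115):
        x = rng.normal(size=n)
        s = normalize_signal(Signal(x, FS))
        dec = decompose(s)
        err = np.max(np.abs(dec.reconstruct() - s.samples))
        assert err < 1e-9 * np.max(np.abs(s.samples))
        widths = sum(b.band_hi - b.band_lo + 1 for b in dec.afibfs)
        assert widths == top_bin(n)


def test_each_band_lowers_the_edge_monotonically(rng):
    x = rng.normal(size=63)
    dec = decompose(normalize_signal(Signal(x, FS)))
    los = [b.band_lo for b in dec.afibfs]
    assert all(a > b for a, b in zip(los, los[1:]))
    assert los[-1] == 1


# --------------------------------------------------------------- tracks

def test_linear_phase_band_has_constant_tracks():
    n, k, amp = 64, 6, 2.5
    w = amp * np.exp(2j * np.pi * k * np.arange(n) / n)
    ia, ifreq = instantaneous_tracks(w, FS)
    np.testing.assert_allclose(ia, amp)
    np.testing.assert_allclose(ifreq, k * FS / n, atol=1e-9)


def test_zero_band_reports_zero_tracks():
    ia, ifreq = instantaneous_tracks(np.zeros(16, dtype=complex), FS)
    assert not ia.any() and not ifreq.any()


def test_chirp_tracks_match_unwrap_oracle():
    n = 64
    t = np.arange(n)
    phase = 2 * np.pi * (2 * t + 10 * t**2 / (2 * n)) / n
    w = np.exp(1j * phase)
    _, ifreq = instantaneous_tracks(w, FS)
    dphi = np.diff(np.unwrap(phase))
    expected = np.where(dphi >= 0, dphi, 0) / (2 * np.pi) * FS
    np.testing.assert_allclose(ifreq[:-1], expected, atol=1e-9 * FS)


# ---------------------------------------------------------------- TF map

def _tone_signal(freq_hz, n=360, fs=FS, amp=1.0):
    return Signal(amp * np.cos(2 * np.pi * freq_hz * np.arange(n) / fs), fs)


def test_pure_tone_lights_exactly_its_row():
    tf = build_tf_map(decompose(normalize_signal(_tone_signal(10.0))))
    assert np.allclose(tf.grid[10], 1.0)
    other = np.delete(tf.grid, 10, axis=0)
    assert not other.any()


def test_tone_above_60hz_is_clipped_out():
    tf = build_tf_map(decompose(normalize_signal(_tone_signal(75.0))))
    assert not tf.grid.any()


def test_two_tone_rows_keep_amplitude_ratio():
    n, fs = 360, FS
    t = np.arange(n)
    x = np.cos(2 * np.pi * 5 * t / fs) + 0.5 * np.cos(2 * np.pi * 20 * t / fs)
    dec = decompose(normalize_signal(Signal(x, fs)))
    tf = build_tf_map(dec)
    mid = slice(n // 4, 3 * n // 4)
    assert np.allclose(tf.grid[5, mid], 1.0, atol=0.05)
    assert np.allclose(tf.grid[20, mid], 0.5, atol=0.05)


def test_low_sampling_rate_is_rejected():
    sig = normalize_signal(Signal(np.sin(np.arange(100)), 100.0))
    with pytest.raises(ValueError):
        build_tf_map(decompose(sig))
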