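"""Fourier decomposition method (FDM) for single-lead ECG.

The FDM partitions the positive-frequency half of a signal's DFT spectrum
into contiguous bands, each giving one *analytic Fourier intrinsic band
function* (AFIBF): a complex band-limited component whose instantaneous
phase is monotonically non-decreasing.  Bands are grown downward from the
top frequency bin (high-to-low scan): at each step the band is extended as
far as the phase-monotonicity criterion permits.  The real parts of the
AFIBFs, plus the DC term, reconstruct the signal exactly.

From the AFIBFs we derive instantaneous amplitude (IA) and instantaneous
frequency (IF) tracks and accumulate them into a sparse time-frequency map
clipped to 0-60 Hz, the band that carries essentially all ECG information.

DFT convention used throughout: the forward transform carries the ``1/N``
factor, ``S(k) = (1/N) sum_n s(n) exp(-2j*pi*k*n/N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateSignalError",
    "Signal",
    "AnalyticSignal",
    "AFIBF",
    "Decomposition",
    "TFMap",
    "normalize_signal",
    "analytic_signal",
    "phase_positivity",
    "scan_band",
    "decompose",
    "instantaneous_tracks",
    "build_tf_map",
    "TF_MAX_HZ",
]

#: Upper edge (exclusive) of the time-frequency map, in Hz.  ECG content
#: above this band is negligible, so the map is clipped there.
TF_MAX_HZ = 60

# Slack for the phase-monotonicity criterion: exact-zero increments occur
# for zero-coefficient bins, so the test is eps >= -PHASE_TOL * max(1, |v|_inf^2).
PHASE_TOL = 1e-12


class DegenerateSignalError(ValueError):
    """Raised for inputs the method cannot process (e.g. an all-zero signal)."""


@dataclass
class Signal:
    """A 1-D sampled signal with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        Real-valued samples (mV before normalization, dimensionless after).
    fs : float
        Sampling rate in Hz, > 0.
    label : str, optional
        Class tag carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 3:
            raise ValueError("signal must be 1-D with at least 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class AnalyticSignal:
    """Positive-frequency analytic signal ``z(n)`` plus the DC term ``S(0)``."""

    values: np.ndarray
    dc: float


@dataclass
class AFIBF:
    """One analytic Fourier intrinsic band function.

    ``band_lo``/``band_hi`` are inclusive DFT bin indices (1-based over the
    positive-frequency half).  ``ia`` is the per-sample instantaneous
    amplitude ``|w(n)|``; ``ifreq`` the instantaneous frequency in Hz,
    within [0, fs/2].
    """

    band_lo: int
    band_hi: int
    values: np.ndarray
    ia: np.ndarray = field(repr=False, default=None)
    ifreq: np.ndarray = field(repr=False, default=None)


@dataclass
class Decomposition:
    """Ordered AFIBF list (highest band first), DC term, length and rate."""

    afibfs: list[AFIBF]
    dc: float
    n: int
    fs: float

    @property
    def m(self) -> int:
        """Number of AFIBFs (emerges from the signal, not user-set)."""
        return len(self.afibfs)

    def reconstruct(self) -> np.ndarray:
        """Return ``dc + Re(sum_m w_m)``, which equals the analysed signal."""
        total = np.zeros(self.n, dtype=complex)
        for b in self.afibfs:
            total += b.values
        return self.dc + total.real


@dataclass
class TFMap:
    """60 x N time-frequency map; row r covers [r, r+1) Hz."""

    grid: np.ndarray
    fs: float


def top_bin(n: int) -> int:
    """Highest positive-frequency DFT bin: (N-1)/2 for odd N, N/2 for even."""
    return (n - 1) // 2 if n % 2 else n // 2


def normalize_signal(raw: Signal) -> Signal:
    """Center a raw signal on its mean and scale by its peak magnitude.

    ``s(n) = (raw(n) - mean(raw)) / max_n |raw(n)|``.  Removing the mean and
    the scale lets recordings from different databases (different gains and
    offsets) be compared on one footing while preserving the waveform shape.

    Raises
    ------
    DegenerateSignalError
        If the raw signal is identically zero (zero denominator).
    """
    peak = np.max(np.abs(raw.samples))
    if peak == 0.0:
        raise DegenerateSignalError("all-zero signal cannot be normalized")
    out = (raw.samples - raw.samples.mean()) / peak
    return Signal(out, raw.fs, raw.label)


def _half_spectrum(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (S, dc): the 1/N-scaled DFT over all N bins, and S(0).real."""
    s = np.fft.fft(samples) / samples.size
    return s, s[0].real


def _band_weights(n: int) -> np.ndarray:
    """Per-bin weight for synthesising the analytic signal from bins 1..top.

    Positive-frequency bins are doubled (they stand in for their negative
    conjugates); for even N the Nyquist bin is its own conjugate and is
    counted once.
    """
    top = top_bin(n)
    w = np.full(top + 1, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[top] = 1.0
    return w


def analytic_signal(s: Signal) -> AnalyticSignal:
    """Build the analytic signal ``z(n)`` from the positive DFT bins.

    For odd N, ``z(n) = 2 sum_{l=1}^{(N-1)/2} S(l) exp(2j*pi*l*n/N)``; for
    even N the Nyquist coefficient enters once with weight 1.  The identity
    ``s(n) = S(0) + Re z(n)`` holds to round-off.
    """
    x = s.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    n = x.size
    spec, dc = _half_spectrum(x)
    top = top_bin(n)
    u = np.zeros(n, dtype=complex)
    u[1 : top + 1] = _band_weights(n)[1:] * spec[1 : top + 1]
    values = np.fft.ifft(u) * n
    return AnalyticSignal(values, dc)


def phase_positivity(v: np.ndarray, tol: float = PHASE_TOL) -> bool:
    """Test monotone instantaneous phase without unwrapping any angle.

    With ``t`` the circular one-sample advance of ``v``, the per-sample
    criterion is ``eps(n) = Im(t(n) * conj(v(n))) >= 0``: the sine of each
    circular phase increment, scaled by the adjacent magnitudes, must be
    non-negative.  A relative slack absorbs floating-point noise; an
    all-zero ``v`` passes (eps is identically zero).
    """
    v = np.asarray(v, dtype=complex)
    t = np.roll(v, -1)
    eps = t.imag * v.real - t.real * v.imag
    scale = max(1.0, float(np.max(np.abs(v)) ** 2)) if v.size else 1.0
    return bool(np.all(eps >= -tol * scale))


def _weighted_coeffs(spectrum: np.ndarray) -> np.ndarray:
    """Weighted positive-half coefficients: 2*S(k), Nyquist once for even N."""
    n = spectrum.size
    top = top_bin(n)
    return _band_weights(n) * spectrum[: top + 1]


def scan_band(
    spectrum: np.ndarray,
    n_prev: int,
    tol: float = PHASE_TOL,
    block: int = 256,
) -> int:
    """One high-to-low scan step: find the lower edge of the next band.

    For each candidate width ``p = 1 .. n_prev-1`` the candidate band covers
    bins ``[n_prev-p, n_prev-1]``; its time-domain synthesis is tested for
    phase monotonicity, and the widest passing band wins:
    ``N_m = n_prev - max(passing p)``.  ``p = 1`` (a single complex
    exponential) always passes, so the scan cannot come up empty.

    Parameters
    ----------
    spectrum : ndarray
        Full N-bin DFT of the signal under the 1/N forward convention.
    n_prev : int
        Exclusive upper bin edge (the previous band's lower edge, or
        ``top_bin + 1`` on the first call).

    Returns
    -------
    int
        The new lower band edge ``N_m`` (>= 1).

    Notes
    -----
    All candidate syntheses share their partial sums, so the scan runs as a
    blocked cumulative sum over bins rather than one inverse FFT per
    candidate; the two are algebraically identical.
    """
    n = spectrum.size
    top = top_bin(n)
    if not (1 < n_prev <= top + 1):
        raise ValueError("scan exhausted: n_prev must be in (1, top_bin + 1]")
    coeffs = _weighted_coeffs(spectrum)
    idx = np.arange(n)
    step_down = np.exp(-2j * np.pi * idx / n)  # k -> k-1 phasor step
    v = np.zeros(n, dtype=complex)
    best = 0
    p = 1
    while p <= n_prev - 1:
        pb = min(block, n_prev - p)
        ks = n_prev - np.arange(p, p + pb)  # bins added, descending
        # phasor rows e^{2j pi k n / N} for k = ks, built by accumulation
        phasors = np.broadcast_to(step_down, (pb, n)).copy()
        phasors[0] = np.exp(2j * np.pi * ks[0] * idx / n)
        phasors = np.multiply.accumulate(phasors, axis=0)
        cum = v + np.cumsum(phasors * coeffs[ks, None], axis=0)
        adv = np.roll(cum, -1, axis=1)
        eps = adv.imag * cum.real - adv.real * cum.imag
        mag2 = cum.real**2 + cum.imag**2
        scale = np.maximum(1.0, mag2.max(axis=1))
        ok = np.nonzero(eps.min(axis=1) >= -tol * scale)[0]
        if ok.size:
            best = p + int(ok.max())
        v = cum[-1]
        p += pb
    assert best >= 1
    return n_prev - best


def decompose(s: Signal) -> Decomposition:
    """Decompose a normalized signal into its full set of AFIBFs.

    Repeats :func:`scan_band` from the top positive-frequency bin down until
    the lower edge reaches bin 1.  The resulting bands are disjoint, tile
    the positive spectrum, are mutually orthogonal (disjoint DFT support),
    and together with the DC term reconstruct the signal to round-off.
    """
    x = s.samples
    n = x.size
    spectrum, dc = _half_spectrum(x)
    coeffs = _weighted_coeffs(spectrum)
    top = top_bin(n)

    afibfs: list[AFIBF] = []
    n_prev = top + 1
    while n_prev > 1:
        n_m = scan_band(spectrum, n_prev)
        u = np.zeros(n, dtype=complex)
        u[n_m:n_prev] = coeffs[n_m:n_prev]
        values = np.fft.ifft(u) * n
        ia, ifreq = instantaneous_tracks(values, s.fs)
        afibfs.append(AFIBF(band_lo=n_m, band_hi=n_prev - 1, values=values,
                            ia=ia, ifreq=ifreq))
        n_prev = n_m
    return Decomposition(afibfs=afibfs, dc=dc, n=n, fs=s.fs)


def instantaneous_tracks(values: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and frequency of one band signal.

    IA is ``|w(n)|``.  The phase increment at sample ``n`` is the angle of
    ``w(n+1) * conj(w(n))`` (circular wrap at the last sample), clipped to
    [0, pi] as monotone-phase bands guarantee; IF is that increment divided
    by ``2*pi`` and expressed in Hz.  Samples where the band vanishes report
    IF = 0 (phase undefined at zeros).
    """
    values = np.asarray(values, dtype=complex)
    ia = np.abs(values)
    prod = np.roll(values, -1) * np.conj(values)
    phi = np.angle(prod)
    phi = np.clip(phi, 0.0, np.pi)  # tiny negatives are round-off
    phi[prod == 0] = 0.0
    ifreq = phi / (2.0 * np.pi) * fs
    return ia, ifreq


def build_tf_map(dec: Decomposition) -> TFMap:
    """Accumulate IA along each AFIBF's IF track into a 60 x N map.

    Cell ``(floor(ifreq), n)`` receives ``ia(n)`` for every band whose IF at
    sample ``n`` lies below 60 Hz; collisions sum.  Cells no IF track visits
    stay exactly zero — the map is sparse by construction.  Finally the map
    is scaled by its maximum entry (a no-op when identically zero).
    """
    if dec.fs <= 2 * TF_MAX_HZ:
        raise ValueError(
            f"unsupported sampling rate {dec.fs} Hz: need fs > {2 * TF_MAX_HZ}"
        )
    grid = np.zeros((TF_MAX_HZ, dec.n))
    for b in dec.afibfs:
        # snap IF values that are integral up to round-off before flooring
        rows = np.floor(b.ifreq + 1e-9).astype(int)
        mask = (b.ia > 0) & (rows < TF_MAX_HZ)
        np.add.at(grid, (rows[mask], np.nonzero(mask)[0]), b.ia[mask])
    peak = grid.max()
    if peak > 0:
        grid /= peak
    return TFMap(grid=grid, fs=dec.fs)
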