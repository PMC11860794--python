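"""Synthetic single-lead ECG with class-distinct morphology.

Beats are modelled as sums of Gaussian bumps standing in for the P, Q, R, S
and T waves; classes differ in wave amplitudes, widths, timings and heart
rate/regularity.  This deliberately simple closed-form model is enough to
exercise every pipeline stage (decomposition, T-F maps, 2DPCA, CMA) with
fully reproducible, label-true data and no external downloads.  It is a
test fixture, not a physiological simulation: real ECG has baseline wander,
correlated noise, and within-patient morphology drift that this generator
does not attempt.

Two default class libraries ship: six beat-level classes loosely analogous
to the MIT-BIH/AAMI N, L, R, V, S and F groups (360 Hz, 301-sample
segments) and four record-level rhythm classes analogous to sinus rhythm,
sinus bradycardia, supraventricular tachycardia and atrial fibrillation
(500 Hz, 10-second records).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fdm import Signal

__all__ = [
    "WaveComponent",
    "ClassSpec",
    "generate_beat",
    "generate_record",
    "generate_dataset",
    "beat_class_library",
    "record_class_library",
]


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian wave: center (ms relative to the R peak), amplitude (mV),
    width (Gaussian sigma, ms)."""

    center: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class ClassSpec:
    """Morphology and rhythm parameters of one synthetic class."""

    name: str
    waves: tuple[WaveComponent, ...]
    rr_mean: float = 800.0  # ms
    rr_sd: float = 40.0  # ms
    noise_sd: float = 0.02  # additive white noise, dimensionless
    fs: float = 360.0  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "waves", tuple(self.waves))
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _waveform(spec: ClassSpec, t_ms: np.ndarray, amp_factors: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t_ms, dtype=float)
    for w, a in zip(spec.waves, amp_factors):
        out += w.amplitude * a * np.exp(-0.5 * ((t_ms - w.center) / w.width) ** 2)
    return out


def generate_beat(spec: ClassSpec, seed: int, pre: int = 150, post: int = 150,
                  amp_jitter: float = 0.1) -> Signal:
    """One fixed-length beat segment centered on the R peak.

    Defaults give ``pre + post + 1 = 301`` samples.  Wave amplitudes are
    jittered uniformly by up to ``amp_jitter`` (fractional, +/-10% by
    default) and white noise of standard deviation ``spec.noise_sd`` is
    added.  Output is a pure function of ``(spec, seed)``.
    """
    if spec.fs <= 120:
        raise ValueError("sampling rate must exceed 120 Hz")
    rng = np.random.default_rng(seed)
    n = pre + post + 1
    t_ms = (np.arange(-pre, post + 1) / spec.fs) * 1000.0
    factors = 1.0 + amp_jitter * rng.uniform(-1.0, 1.0, size=len(spec.waves))
    x = _waveform(spec, t_ms, factors)
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=n)
    return Signal(x, spec.fs, label=spec.name)


def generate_record(spec: ClassSpec, duration_s: float = 10.0, seed: int = 0,
                    amp_jitter: float = 0.1) -> Signal:
    """A whole record of beats at stochastic RR intervals.

    R peaks are laid down starting half an RR interval into the record,
    stepping by draws from ``Normal(rr_mean, rr_sd)`` truncated positive;
    each beat's waveform is accumulated over its full support, then white
    noise is added.  The default 10 s at ``spec.fs`` = 500 Hz gives 5000
    samples.  Output is a pure function of ``(spec, duration_s, seed)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if spec.fs <= 120:
        raise ValueError("sampling rate must exceed 120 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * spec.fs))
    t_ms = (np.arange(n) / spec.fs) * 1000.0
    x = np.zeros(n)
    t_r = spec.rr_mean / 2.0
    end_ms = duration_s * 1000.0
    while t_r < end_ms:
        factors = 1.0 + amp_jitter * rng.uniform(-1.0, 1.0, size=len(spec.waves))
        x += _waveform(spec, t_ms - t_r, factors)
        rr = rng.normal(spec.rr_mean, spec.rr_sd) if spec.rr_sd > 0 else spec.rr_mean
        t_r += max(rr, 1.0)
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=n)
    return Signal(x, spec.fs, label=spec.name)


@dataclass
class LabeledDataset:
    """Seeded train/test splits plus a manifest describing how they were made."""

    train: list[Signal]
    test: list[Signal]
    manifest: dict = field(default_factory=dict)


def generate_dataset(specs: list[ClassSpec], n_train: int, n_test: int,
                     seed: int, kind: str = "beat",
                     duration_s: float = 10.0) -> LabeledDataset:
    """Disjoint, seeded train/test sets across classes.

    ``kind`` selects beat segments or whole records.  Per-sample seeds are
    drawn once from a master generator so the whole dataset is a pure
    function of ``(specs, n_train, n_test, seed)``.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if n_train < 2:
        raise ValueError("need n_train >= 2 (the classifier needs 2+ per class)")
    if kind not in ("beat", "record"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    train: list[Signal] = []
    test: list[Signal] = []
    manifest: dict = {"seed": seed, "kind": kind, "n_train": n_train,
                      "n_test": n_test, "classes": {}}
    for spec in specs:
        seeds = rng.integers(0, 2**31 - 1, size=n_train + n_test)
        for i, s in enumerate(seeds):
            if kind == "beat":
                sig = generate_beat(spec, int(s))
            else:
                sig = generate_record(spec, duration_s=duration_s, seed=int(s))
            (train if i < n_train else test).append(sig)
        manifest["classes"][spec.name] = {
            "fs": spec.fs,
            "seeds": [int(s) for s in seeds],
        }
    return LabeledDataset(train=train, test=test, manifest=manifest)


def beat_class_library(noise_sd: float = 0.02, fs: float = 360.0) -> list[ClassSpec]:
    """Six beat-morphology classes analogous to the AAMI-style N/L/R/V/S/F
    groups: narrow-QRS normal, broadened/notched bundle-branch-block shapes,
    a wide high-amplitude ectopic with discordant T and no P, a P-absent
    supraventricular beat, and an intermediate fusion shape."""
    mk = WaveComponent
    base_t = mk(250.0, 0.30, 40.0)
    return [
        ClassSpec("N", (mk(-170, 0.15, 22), mk(-25, -0.10, 9), mk(0, 1.00, 11),
                        mk(28, -0.22, 9), base_t),
                  rr_mean=800, rr_sd=40, noise_sd=noise_sd, fs=fs),
        ClassSpec("L", (mk(-170, 0.12, 22), mk(-12, 0.55, 26), mk(22, 0.70, 26),
                        mk(70, -0.15, 16), mk(280, -0.25, 45)),
                  rr_mean=820, rr_sd=40, noise_sd=noise_sd, fs=fs),
        ClassSpec("R", (mk(-170, 0.12, 22), mk(-18, 0.85, 13), mk(30, 0.45, 20),
                        mk(75, -0.30, 14), mk(260, 0.20, 42)),
                  rr_mean=810, rr_sd=40, noise_sd=noise_sd, fs=fs),
        ClassSpec("V", (mk(-8, 1.40, 38), mk(60, -0.45, 26), mk(240, -0.40, 55)),
                  rr_mean=700, rr_sd=80, noise_sd=noise_sd, fs=fs),
        ClassSpec("S", (mk(-30, -0.12, 10), mk(0, 0.95, 10), mk(25, -0.20, 9),
                        mk(230, 0.28, 38)),
                  rr_mean=600, rr_sd=60, noise_sd=noise_sd, fs=fs),
        ClassSpec("F", (mk(-120, 0.08, 20), mk(-5, 1.15, 22), mk(45, -0.30, 16),
                        mk(250, 0.10, 45)),
                  rr_mean=750, rr_sd=50, noise_sd=noise_sd, fs=fs),
    ]


def record_class_library(noise_sd: float = 0.02, fs: float = 500.0) -> list[ClassSpec]:
    """Four record-level rhythm classes analogous to sinus rhythm (SR), sinus
    bradycardia (SB), supraventricular tachycardia (GSVT) and atrial
    fibrillation (AFIB): same template beat, but heart rate, RR regularity
    and P-wave presence differ."""
    mk = WaveComponent
    qrs = (mk(-25, -0.10, 9), mk(0, 1.00, 11), mk(28, -0.22, 9), mk(250, 0.30, 40))
    with_p = (mk(-170, 0.15, 22),) + qrs
    return [
        ClassSpec("SR", with_p, rr_mean=800, rr_sd=30, noise_sd=noise_sd, fs=fs),
        ClassSpec("SB", with_p, rr_mean=1250, rr_sd=40, noise_sd=noise_sd, fs=fs),
        ClassSpec("GSVT", with_p, rr_mean=400, rr_sd=15, noise_sd=noise_sd, fs=fs),
        ClassSpec("AFIB", qrs, rr_mean=700, rr_sd=180, noise_sd=noise_sd, fs=fs),
    ]


def separated(spec: ClassSpec, factor: float) -> ClassSpec:
    """Scale a spec's wave amplitudes by ``factor`` (used to study how class
    separation affects end-to-end accuracy)."""
    waves = tuple(replace(w, amplitude=w.amplitude * factor) for w in spec.waves)
    return replace(spec, waves=waves)
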