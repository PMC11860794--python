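"""Reading ECG records, R-peak beat segmentation, and CSV/JSON persistence.

Signals travel as plain CSV (one sample per line, optional non-numeric
header); WFDB records are supported when the optional ``wfdb`` package is
importable.  Matrices, decompositions and trained models persist as CSV
files with JSON sidecars so every artifact is diffable text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cma import ClassModel, TrainedClassifier
from .features import ProjectionMatrix
from .fdm import Decomposition, Signal, TFMap

__all__ = [
    "AnnotatedRecord",
    "read_record",
    "segment_beats",
    "write_signal_csv",
    "read_signal_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "export_decomposition",
    "export_tf_map",
    "save_model",
    "load_model",
]

log = logging.getLogger("fdmcma")


@dataclass
class AnnotatedRecord:
    """A signal plus optional R-peak sample indices (0-based) and beat labels."""

    signal: Signal
    rpeaks: np.ndarray | None = None
    beat_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.rpeaks is not None:
            self.rpeaks = np.asarray(self.rpeaks, dtype=int)
            if np.any(np.diff(self.rpeaks) <= 0):
                raise ValueError("R-peak indices must be strictly increasing")
            if self.rpeaks.size and (
                self.rpeaks[0] < 0 or self.rpeaks[-1] >= self.signal.n
            ):
                raise ValueError("R-peak indices out of signal range")


def read_signal_csv(path: str | Path, fs: float, label: str | None = None) -> Signal:
    """One sample per line; a single non-numeric first line is skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such signal file: {path}")
    lines = path.read_text().strip().splitlines()
    start = 0
    if lines:
        try:
            float(lines[0].split(",")[0])
        except ValueError:
            start = 1
    samples = np.array([float(ln.split(",")[0]) for ln in lines[start:]])
    return Signal(samples, fs, label=label)


def read_record(path: str | Path, format: str = "csv", fs: float | None = None,
                channel: str | None = None) -> AnnotatedRecord:
    """Load a record from CSV (requires ``fs``) or a WFDB record + channel.

    CSV carries no annotations, so ``rpeaks`` is None.  WFDB support needs
    the optional ``wfdb`` package; beat annotations, when present, become
    R-peak indices and labels.
    """
    if format == "csv":
        if fs is None:
            raise ValueError("CSV input requires an explicit sampling rate (fs)")
        return AnnotatedRecord(signal=read_signal_csv(path, fs))
    if format == "wfdb":
        try:
            import wfdb  # noqa: PLC0415
        except ImportError as exc:
            raise ImportError(
                "WFDB input requires the optional 'wfdb' package; "
                "install it or convert the record to CSV"
            ) from exc
        rec = wfdb.rdrecord(str(path))
        names = list(rec.sig_name)
        if channel not in names:
            raise ValueError(f"channel {channel!r} not in record channels {names}")
        sig = Signal(rec.p_signal[:, names.index(channel)], rec.fs)
        rpeaks, labels = None, None
        try:
            ann = wfdb.rdann(str(path), "atr")
            beat_mask = [s not in "+~|\"" for s in ann.symbol]
            rpeaks = np.asarray(ann.sample)[beat_mask]
            labels = [s for s in ann.symbol if s not in "+~|\""]
        except FileNotFoundError:
            pass
        return AnnotatedRecord(signal=sig, rpeaks=rpeaks, beat_labels=labels)
    raise ValueError(f"unknown format {format!r}")


def segment_beats(rec: AnnotatedRecord, pre: int = 150, post: int = 150) -> list[Signal]:
    """Fixed-length beat windows ``[r - pre, r + post]`` around each R peak.

    Defaults give 301-sample segments.  Peaks whose window would run off
    either edge of the record are skipped (and logged), never zero-padded:
    padding would distort the spectrum row downstream.
    """
    if rec.rpeaks is None or rec.rpeaks.size == 0:
        raise ValueError("record has no R-peak annotations to segment on")
    sig = rec.signal
    out: list[Signal] = []
    for i, r in enumerate(rec.rpeaks):
        if r - pre < 0 or r + post >= sig.n:
            log.info("skipping R peak at %d: window [%d, %d] leaves the record",
                     r, r - pre, r + post)
            continue
        label = rec.beat_labels[i] if rec.beat_labels else None
        out.append(Signal(sig.samples[r - pre: r + post + 1], sig.fs, label=label))
    return out


def write_signal_csv(sig: Signal, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(repr(float(x)) for x in sig.samples) + "\n")


def write_matrix_csv(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.atleast_2d(mat), delimiter=",", fmt="%.17g")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def export_decomposition(dec: Decomposition, out_dir: str | Path) -> None:
    """One CSV per AFIBF (band edges header; rows of Re, Im, IA, IF) plus a
    JSON manifest with the DC term, length and sampling rate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, b in enumerate(dec.afibfs, start=1):
        rows = np.column_stack([b.values.real, b.values.imag, b.ia, b.ifreq])
        header = f"band_lo={b.band_lo},band_hi={b.band_hi}\nre,im,ia,if_hz"
        np.savetxt(out / f"afibf_{i:03d}.csv", rows, delimiter=",",
                   fmt="%.17g", header=header)
    (out / "decomposition.json").write_text(json.dumps(
        {"m": dec.m, "dc": dec.dc, "n": dec.n, "fs": dec.fs,
         "bands": [[b.band_lo, b.band_hi] for b in dec.afibfs]}, indent=2))


def export_tf_map(tf: TFMap, path: str | Path) -> None:
    write_matrix_csv(tf.grid, path)


def save_model(clf: TrainedClassifier, out_dir: str | Path) -> None:
    """Persist a trained classifier: per-class CSV matrices + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"variant": clf.variant, "d": clf.d, "classes": []}
    for m in clf.models:
        safe = m.class_id.replace("/", "_")
        write_matrix_csv(m.proj.columns, out / f"{safe}_projection.csv")
        write_matrix_csv(m.common, out / f"{safe}_common.csv")
        for r, q in enumerate(m.basis):
            write_matrix_csv(q, out / f"{safe}_basis_{r:03d}.csv")
        manifest["classes"].append({
            "class_id": m.class_id, "file_stem": safe, "l_count": m.l_count,
            "basis_size": len(m.basis),
            "eigenvalues": [float(v) for v in m.proj.eigenvalues],
            "h": int(m.common.shape[0]),
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(model_dir: str | Path) -> TrainedClassifier:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    models = []
    for entry in manifest["classes"]:
        stem = entry["file_stem"]
        proj = ProjectionMatrix(
            columns=read_matrix_csv(model_dir / f"{stem}_projection.csv"),
            eigenvalues=np.array(entry["eigenvalues"]))
        basis = [read_matrix_csv(model_dir / f"{stem}_basis_{r:03d}.csv")
                 for r in range(entry["basis_size"])]
        common = read_matrix_csv(model_dir / f"{stem}_common.csv")
        models.append(ClassModel(class_id=entry["class_id"], proj=proj,
                                 basis=basis, common=common,
                                 l_count=entry["l_count"]))
    return TrainedClassifier(models=models, variant=manifest["variant"],
                             d=manifest["d"])
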