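"""Data matrices and 2DPCA feature images.

A signal's *data matrix* stacks three views of the same beat or record: the
clipped, normalized time-frequency map (60 rows), the normalized
DFT-magnitude spectrum (1 row), and the normalized signal itself (1 row) —
62 x N in the full variant.  Ablation variants drop one or both 1-row
blocks.

Two-dimensional PCA then learns, per class, a projection matrix from the
matrix-valued scatter ``Phi = (1/R) sum_k (D_k - D_a)^T (D_k - D_a)``:
data matrices are projected by right-multiplication, without vectorization,
giving compact 62 x d *feature images*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdm import Decomposition, Signal, build_tf_map

__all__ = [
    "VARIANT_ROWS",
    "DataMatrix",
    "CovarianceMatrix",
    "ProjectionMatrix",
    "FeatureMatrix",
    "build_data_matrix",
    "class_covariance",
    "projection_matrix",
    "extract_features",
]

#: Row counts of the data-matrix variants: D = T-F + spectrum + signal,
#: D1 = T-F only, D2 = T-F + signal, D3 = T-F + spectrum.
VARIANT_ROWS = {"D": 62, "D1": 60, "D2": 61, "D3": 61}


@dataclass
class DataMatrix:
    """Stacked representation of one signal; ``grid`` is rows x N."""

    grid: np.ndarray
    variant: str
    label: str | None = None


@dataclass
class CovarianceMatrix:
    """In-class N x N scatter of data matrices, and how many contributed."""

    values: np.ndarray
    r_count: int


@dataclass
class ProjectionMatrix:
    """Leading-eigenvector projection: ``columns`` is N x d, orthonormal."""

    columns: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class FeatureMatrix:
    """Feature image ``D @ P`` (rows x d); remembers which class's P made it."""

    values: np.ndarray
    class_hint: str | None = None


def spectrum_row(samples: np.ndarray) -> np.ndarray:
    """Normalized DFT-magnitude row over all N bins (both symmetric halves)."""
    mag = np.abs(np.fft.fft(samples) / samples.size)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def build_data_matrix(s: Signal, dec: Decomposition, variant: str = "D") -> DataMatrix:
    """Assemble the data matrix for a normalized signal.

    ``variant`` selects the row blocks: ``"D"`` (62 rows) stacks the 60-row
    T-F map, the spectrum row and the signal row; ``"D1"`` keeps only the
    T-F map; ``"D2"`` adds the signal row; ``"D3"`` adds the spectrum row.
    """
    if variant not in VARIANT_ROWS:
        raise ValueError(f"unknown variant {variant!r}")
    if dec.n != s.n:
        raise ValueError("decomposition length does not match signal length")
    tf = build_tf_map(dec).grid
    blocks = [tf]
    if variant in ("D", "D3"):
        blocks.append(spectrum_row(s.samples)[None, :])
    if variant in ("D", "D2"):
        blocks.append(s.samples[None, :])
    return DataMatrix(grid=np.vstack(blocks), variant=variant, label=s.label)


def class_covariance(mats: list[DataMatrix]) -> CovarianceMatrix:
    """In-class scatter ``Phi = (1/R) sum_k (D_k - D_a)^T (D_k - D_a)``.

    ``D_a`` is the elementwise mean data matrix; the divisor is exactly
    ``1/R``.  Requires at least two same-shape matrices.
    """
    if len(mats) < 2:
        raise ValueError("need at least 2 data matrices")
    grids = np.stack([m.grid for m in mats])
    centered = grids - grids.mean(axis=0)
    phi = np.einsum("khn,khm->nm", centered, centered) / len(mats)
    return CovarianceMatrix(values=phi, r_count=len(mats))


def projection_matrix(cov: CovarianceMatrix, d: int) -> ProjectionMatrix:
    """Eigenvectors of the scatter matrix for the ``d`` largest eigenvalues.

    Columns are orthonormal and ordered by descending eigenvalue.  Each
    column's sign is fixed so its largest-magnitude entry is positive; the
    classifier is invariant to the convention as long as training and test
    share it, and fixing it makes features bitwise reproducible.
    """
    phi = cov.values
    n = phi.shape[0]
    if d > n:
        raise ValueError(f"d={d} exceeds matrix size {n}")
    if not np.allclose(phi, phi.T, atol=1e-8 * max(1.0, np.abs(phi).max())):
        raise ValueError("covariance matrix is not symmetric")
    evals, evecs = np.linalg.eigh(phi)
    order = np.argsort(evals, kind="stable")[::-1]
    evals, evecs = evals[order[:d]], evecs[:, order[:d]]
    anchor = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[anchor, np.arange(d)])
    signs[signs == 0] = 1.0
    return ProjectionMatrix(columns=evecs * signs, eigenvalues=evals)


def extract_features(mat: DataMatrix, proj: ProjectionMatrix,
                     class_hint: str | None = None) -> FeatureMatrix:
    """Feature image ``F = D @ P`` (rows x d)."""
    if mat.grid.shape[1] != proj.columns.shape[0]:
        raise ValueError("data matrix columns do not match projection rows")
    return FeatureMatrix(values=mat.grid @ proj.columns, class_hint=class_hint)
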