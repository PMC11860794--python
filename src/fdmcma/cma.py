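"""Common-matrix-approach (CMA) subspace classifier.

Each class's feature images are modelled as a shared *common matrix* plus a
member-specific component living in the class's *difference subspace* — the
span of within-class differences ``X_{r+1} - X_1``, orthonormalized by
Gram-Schmidt under the trace inner product ``<A, B> = tr(A^T B)``.
Removing the difference-subspace projection from any member yields the same
common matrix (an exact algebraic identity), so one member suffices.

A test signal is projected with every class's own 2DPCA matrix, reduced to
its common part against that class's subspace, and assigned to the class
whose common matrix it matches with minimal squared Frobenius distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    DataMatrix,
    FeatureMatrix,
    ProjectionMatrix,
    class_covariance,
    extract_features,
    projection_matrix,
)

__all__ = [
    "ClassModel",
    "TrainedClassifier",
    "Prediction",
    "within_class_differences",
    "gram_schmidt",
    "common_matrix",
    "train",
    "classify",
]

# Residual-norm threshold (relative to the largest input Frobenius norm)
# below which a difference matrix is treated as linearly dependent.
GSO_TOL = 1e-10


@dataclass
class ClassModel:
    class_id: str
    proj: ProjectionMatrix
    basis: list[np.ndarray]
    common: np.ndarray
    l_count: int


@dataclass
class TrainedClassifier:
    models: list[ClassModel]
    variant: str
    d: int

    @property
    def class_ids(self) -> list[str]:
        return [m.class_id for m in self.models]


@dataclass
class Prediction:
    label: str
    scores: dict[str, float]


def within_class_differences(feats: list[FeatureMatrix | np.ndarray]) -> list[np.ndarray]:
    """Difference matrices ``Y_r = X_{r+1} - X_1`` against the first member.

    The first supplied matrix is the reference; predictions are invariant to
    which member plays that role.
    """
    if len(feats) < 2:
        raise ValueError("need at least 2 feature matrices per class")
    arrs = [f.values if isinstance(f, FeatureMatrix) else np.asarray(f) for f in feats]
    ref = arrs[0]
    return [a - ref for a in arrs[1:]]


def _inner(a: np.ndarray, b: np.ndarray) -> float:
    # trace inner product tr(A^T B) = elementwise sum
    return float(np.sum(a * b))


def gram_schmidt(diffs: list[np.ndarray], tol: float = GSO_TOL) -> list[np.ndarray]:
    """Orthonormalize matrices under the trace inner product.

    Modified Gram-Schmidt with one re-orthogonalization pass per vector,
    which keeps the basis orthogonal even for many near-parallel inputs.
    Matrices whose residual Frobenius norm falls below ``tol`` times the
    largest input norm are dropped as linearly dependent; the surviving
    matrices are normalized to unit Frobenius norm.
    """
    if not diffs:
        raise ValueError("empty difference list")
    scale = max(float(np.linalg.norm(y)) for y in diffs)
    basis: list[np.ndarray] = []
    if scale == 0.0:
        return basis
    for y in diffs:
        z = np.array(y, dtype=float)
        for _ in range(2):
            for q in basis:
                z -= _inner(z, q) * q
        nrm = float(np.linalg.norm(z))
        if nrm > tol * scale:
            basis.append(z / nrm)
    return basis


def common_matrix(feat: FeatureMatrix | np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Remove the difference-subspace component: ``X - sum_r <X,Q_r> Q_r``."""
    x = feat.values if isinstance(feat, FeatureMatrix) else np.asarray(feat, dtype=float)
    out = np.array(x, dtype=float)
    for q in basis:
        if q.shape != x.shape:
            raise ValueError("basis matrix shape does not match feature shape")
        out -= _inner(x, q) * q
    return out


def train(per_class_data: dict[str, list[DataMatrix]], d: int) -> TrainedClassifier:
    """Fit one :class:`ClassModel` per class from its data matrices.

    Per class: 2DPCA scatter and projection (d leading eigenvectors),
    feature images, within-class differences, Gram-Schmidt basis, and the
    common matrix computed from the first member (any member gives the
    same result).  A class whose members are all identical is legal: its
    basis is empty and its common matrix is the shared feature image.
    """
    if len(per_class_data) < 2:
        raise ValueError("need at least 2 classes")
    variants = {m.variant for mats in per_class_data.values() for m in mats}
    if len(variants) != 1:
        raise ValueError(f"mixed data-matrix variants: {sorted(variants)}")
    models = []
    for class_id, mats in per_class_data.items():
        if len(mats) < 2:
            raise ValueError(f"class {class_id!r} has fewer than 2 samples")
        proj = projection_matrix(class_covariance(mats), d)
        feats = [extract_features(m, proj, class_hint=class_id) for m in mats]
        basis = gram_schmidt(within_class_differences(feats))
        common = common_matrix(feats[0], basis)
        models.append(ClassModel(class_id=class_id, proj=proj, basis=basis,
                                 common=common, l_count=len(mats)))
    return TrainedClassifier(models=models, variant=variants.pop(), d=d)


def classify(test: DataMatrix, clf: TrainedClassifier) -> Prediction:
    """Assign a test data matrix to the class with minimal common distance.

    For each class ``i`` the test matrix is projected with that class's own
    2DPCA matrix, its difference-subspace component is removed, and the
    score is ``W(i) = ||T_com - X_com^(i)||_F^2``.  The label is the
    argmin; ties break toward the earlier class in training order.
    """
    if test.variant != clf.variant:
        raise ValueError(
            f"test variant {test.variant!r} does not match training {clf.variant!r}"
        )
    scores: dict[str, float] = {}
    for model in clf.models:
        t = extract_features(test, model.proj).values
        t_com = common_matrix(t, model.basis)
        scores[model.class_id] = float(np.linalg.norm(t_com - model.common) ** 2)
    labels = list(scores)
    label = labels[int(np.argmin([scores[c] for c in labels]))]
    return Prediction(label=label, scores=scores)
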