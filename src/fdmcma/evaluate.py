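"""Confusion-matrix metrics and Monte-Carlo cross-validation.

Per class (one-vs-rest): sensitivity ``TP/(TP+FN)``, specificity
``TN/(TN+FP)``, positive predictive rate ``TP/(TP+FP)``, and F1 score, all
in percent; overall accuracy is the confusion-matrix trace over the total.
A zero denominator yields NaN (e.g. Ppr when a class is never predicted),
and NaN propagates into F1 and into averages rather than being skipped.

MCCV repeats random train/test splits: per run a training subset is drawn
per class without replacement (a class smaller than its quota contributes
all of its samples), the classifier is retrained, and metrics are
aggregated as mean +/- sd across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cma import classify, train
from .features import DataMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "MccvReport",
    "confusion_matrix",
    "compute_metrics",
    "run_mccv",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    labels: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class and overall metrics, all in percent (NaN when undefined)."""

    labels: list[str]
    sen: np.ndarray
    spe: np.ndarray
    ppr: np.ndarray
    f1: np.ndarray
    oa: float

    def macro(self) -> dict[str, float]:
        """Unweighted class averages; NaN propagates (not skipped)."""
        return {
            "Sen": float(np.mean(self.sen)),
            "Spe": float(np.mean(self.spe)),
            "Ppr": float(np.mean(self.ppr)),
            "F1": float(np.mean(self.f1)),
            "OA": self.oa,
        }


def confusion_matrix(y_true: list[str], y_pred: list[str],
                     labels: list[str] | None = None) -> ConfusionMatrix:
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("need equal-length, nonempty label sequences")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(labels))


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest Sen/Spe/Ppr/F1 per class plus overall accuracy, in %."""
    c = cm.counts.astype(float)
    if c.size == 0 or c.shape[0] < 2:
        raise ValueError("confusion matrix needs at least 2 classes")
    total = c.sum()
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = total - tp - fn - fp
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    ppr = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * ppr * sen, ppr + sen)
    return MetricsReport(labels=cm.labels, sen=sen * 100, spe=spe * 100,
                         ppr=ppr * 100, f1=f1 * 100,
                         oa=float(tp.sum() / total * 100))


@dataclass
class MccvReport:
    """Per-run metrics plus mean and sd of every metric across runs."""

    runs: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)

    def _finalize(self) -> None:
        self.labels = self.runs[0].labels
        stacks = {
            name: np.array([getattr(r, name) for r in self.runs])
            for name in ("sen", "spe", "ppr", "f1")
        }
        oa = np.array([r.oa for r in self.runs])
        self.mean = {"OA": float(oa.mean())}
        self.sd = {"OA": float(oa.std())}
        for name, arr in stacks.items():
            for j, lab in enumerate(self.labels):
                self.mean[f"{name.capitalize()}[{lab}]"] = float(arr[:, j].mean())
                self.sd[f"{name.capitalize()}[{lab}]"] = float(arr[:, j].std())


def run_mccv(
    pool: dict[str, list[DataMatrix]],
    n_runs: int,
    n_train_per_class: int | dict[str, int],
    d: int,
    seed: int,
    test_pool: dict[str, list[DataMatrix]] | None = None,
) -> MccvReport:
    """Monte-Carlo cross-validation over precomputed data matrices.

    Per run, ``n_train_per_class`` samples are drawn per class from ``pool``
    without replacement (all of them if the class is smaller than its
    quota).  Evaluation uses ``test_pool`` when given (a fixed held-out
    set), otherwise the run's own remainder.  Run ``r`` is seeded from
    ``(seed, r)``, so runs are independent and the whole procedure is
    reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    labels = sorted(pool)
    runs: list[MetricsReport] = []
    for r in range(n_runs):
        rng = np.random.default_rng([seed, r])
        train_data: dict[str, list[DataMatrix]] = {}
        held_out: dict[str, list[DataMatrix]] = {}
        for lab in labels:
            mats = pool[lab]
            quota = (n_train_per_class.get(lab) if isinstance(n_train_per_class, dict)
                     else n_train_per_class)
            if quota >= len(mats):
                train_data[lab] = list(mats)
                held_out[lab] = []
            else:
                picks = rng.choice(len(mats), size=quota, replace=False)
                mask = np.zeros(len(mats), dtype=bool)
                mask[picks] = True
                train_data[lab] = [mats[i] for i in np.nonzero(mask)[0]]
                held_out[lab] = [mats[i] for i in np.nonzero(~mask)[0]]
        eval_pool = test_pool if test_pool is not None else held_out
        if all(len(v) == 0 for v in eval_pool.values()):
            raise ValueError("no test data: every class fully consumed by training")
        clf = train(train_data, d)
        y_true, y_pred = [], []
        for lab in sorted(eval_pool):
            for mat in eval_pool[lab]:
                y_true.append(lab)
                y_pred.append(classify(mat, clf).label)
        runs.append(compute_metrics(confusion_matrix(y_true, y_pred, labels=labels)))
    report = MccvReport(runs=runs)
    report._finalize()
    return report
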