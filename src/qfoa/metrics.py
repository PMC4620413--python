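"""Confusion-matrix diagnostics and the cost-sensitive cross-validation fitness.

Computer-aided diagnosis cares asymmetrically about the two error rates of a
binary classifier: a missed diagnosis (false negative) delays treatment, while
a false alarm (false positive) only triggers further examination.  The fitness
used throughout this package is therefore the k-fold mean of a weighted sum of
the false negative rate (FNR, missed-diagnosis rate) and the false positive
rate (FPR, misdiagnosis rate),

    fitness = (1/K) * sum_k [ w * FNR_k + (1 - w) * FPR_k ],

minimized over classifier hyperparameters.  ``w`` is the weight of FNR; with
``w >= 0.5`` missed diagnoses dominate the cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "FitnessConfig",
    "RunSummary",
    "InvalidEvaluationError",
    "rates_from_confusion",
    "weighted_cv_fitness",
    "summarize_runs",
    "write_run_report",
]


class InvalidEvaluationError(ValueError):
    """A classifier evaluation was degenerate (one class absent)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts from one evaluation of a binary classifier.

    Positive class is the disease class (+1); ``tp + fn`` is the number of
    actual positives P, ``fp + tn`` the number of actual negatives N.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a non-negative integer")
        if self.tp + self.fn + self.fp + self.tn < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Derived rates, all in [0, 1].

    ``precision`` is NaN when no sample was predicted positive (undefined);
    ``f1`` is defined as 0 when ``tp == 0`` so downstream comparisons of
    degenerate classifiers never crash.
    """

    fpr: float
    fnr: float
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class FitnessConfig:
    """K-fold / FNR-weight configuration of the fitness function."""

    k_folds: int = 5
    fnr_weight: float = 0.9

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 <= self.fnr_weight <= 1.0:
            raise ValueError("fnr_weight must lie in [0, 1]")


@dataclass(frozen=True)
class RunSummary:
    """Mean and sample standard deviation (n-1 denominator) of repeated runs."""

    mean: float
    sample_std: float


def rates_from_confusion(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Compute FPR, FNR, accuracy, precision, recall and F1 from counts.

    Requires both classes present (P >= 1 and N >= 1); raises
    :class:`InvalidEvaluationError` naming the empty class otherwise.
    """
    if cm.p == 0:
        raise InvalidEvaluationError("no actual positives in evaluation")
    if cm.n == 0:
        raise InvalidEvaluationError("no actual negatives in evaluation")
    fpr = cm.fp / cm.n
    fnr = cm.fn / cm.p
    accuracy = (cm.tp + cm.tn) / (cm.p + cm.n)
    recall = cm.tp / cm.p
    if cm.tp + cm.fp == 0:
        precision = math.nan
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp == 0:
        f1 = 0.0
    else:
        f1 = 2.0 / (1.0 / precision + 1.0 / recall)
    return ClassificationMetrics(
        fpr=fpr, fnr=fnr, accuracy=accuracy, precision=precision, recall=recall, f1=f1
    )


def weighted_cv_fitness(
    fold_rates: Sequence[tuple[float, float]], w: float
) -> float:
    """Mean over folds of ``w*FNR + (1-w)*FPR``; smaller is better.

    ``fold_rates`` is a sequence of per-fold ``(fnr, fpr)`` pairs, each rate
    in [0, 1].
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    rates = list(fold_rates)
    if len(rates) == 0:
        raise ValueError("fold_rates must be non-empty")
    total = 0.0
    for fnr, fpr in rates:
        if not (0.0 <= fnr <= 1.0 and 0.0 <= fpr <= 1.0):
            raise ValueError(f"fold rates ({fnr}, {fpr}) outside [0, 1]")
        total += w * fnr + (1.0 - w) * fpr
    return total / len(rates)


def summarize_runs(values: Iterable[float]) -> RunSummary:
    """Mean and sample standard deviation (ddof=1) of repeated-run values.

    A single value yields sample_std 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    mean = float(arr.mean())
    # identical inputs have zero spread exactly, not up to summation rounding
    if arr.size == 1 or np.all(arr == arr[0]):
        std = 0.0
    else:
        std = float(arr.std(ddof=1))
    return RunSummary(mean=mean, sample_std=std)


# ---------------------------------------------------------------------------
# report writing

_RATE_COLS = ("FPR", "FNR", "Accuracy", "Precision", "F1")


def write_run_report(path, rows: Sequence[dict]) -> None:
    """Write a per-run CSV report with trailing ``mu`` and ``s`` summary rows.

    Each row dict carries keys ``run, C, gamma, FPR, FNR, Accuracy, Precision,
    F1``; rates are raw fractions and are formatted as percentages with two
    decimals, C and gamma with four decimals.  The mu/s rows are computed on
    the raw (unrounded) values.
    """
    header = ["run", "C", "gamma", *_RATE_COLS]
    lines = [",".join(header)]

    def fmt_row(label, c, g, rates):
        cells = [str(label), f"{c:.4f}", f"{g:.4f}"]
        cells += [f"{100.0 * r:.2f}%" for r in rates]
        return ",".join(cells)

    for row in rows:
        lines.append(
            fmt_row(row["run"], row["C"], row["gamma"], [row[k] for k in _RATE_COLS])
        )
    by_col = {k: [row[k] for row in rows] for k in ("C", "gamma", *_RATE_COLS)}
    mu = {k: summarize_runs(v).mean for k, v in by_col.items()}
    s = {k: summarize_runs(v).sample_std for k, v in by_col.items()}
    lines.append(fmt_row("mu", mu["C"], mu["gamma"], [mu[k] for k in _RATE_COLS]))
    # the spread row keeps raw (non-percent) formatting: it is a dispersion,
    # not a rate
    s_cells = ["s", f"{s['C']:.4f}", f"{s['gamma']:.4f}"]
    s_cells += [f"{s[k]:.4f}" for k in _RATE_COLS]
    lines.append(",".join(s_cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
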