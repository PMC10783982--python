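"""Confusion-matrix metrics, batch evaluation, BMD categorisation, reports.

The four classifier metrics are the standard binary diagnostics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   =  TP / (TP + FP)
    sensitivity =  TP / (TP + FN)        (recall, true-positive rate)
    specificity =  TN / (TN + FP)        (true-negative rate)

Evaluation follows a batch protocol: the dataset is split into
consecutive batches (20 images by default), the metrics are computed per
batch, and their across-batch average is appended.  A zero-denominator
metric is reported as missing (NaN), never silently coerced to 0 or 1, so
averages are not quietly inflated.

Bone-mineral-density categorisation uses the clinical thresholds in
mg/cm^2: above 833 is normal, 648-833 (inclusive) osteopenia, below 648
osteoporotic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "batch_evaluate",
    "batch_evaluate_predictions",
    "bmd_categorize",
    "emit_report",
    "BMD_LOWER",
    "BMD_UPPER",
    "BMD_CATEGORIES",
]

# clinical BMD category bounds, mg/cm^2
BMD_LOWER = 648.0
BMD_UPPER = 833.0
BMD_CATEGORIES = ("normal", "osteopenia", "osteoporotic")

METRIC_COLUMNS = ("accuracy", "precision", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The four metrics as fractions in [0, 1]; NaN marks an undefined ratio."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    batch_id: Optional[int] = None

    def as_percent_dict(self) -> dict[str, float]:
        return {
            m: round(getattr(self, m) * 100.0, 2) if math.isfinite(getattr(self, m)) else float("nan")
            for m in METRIC_COLUMNS
        }


def confusion(
    predictions: Sequence[str],
    labels: Sequence[str],
    positive_class: str,
    known_classes: Sequence[str] | None = None,
) -> ConfusionCounts:
    """Binarised confusion counts with the stated positive class.

    In a multi-class setting this is the one-vs-rest binarisation for
    ``positive_class``.  ``known_classes`` widens the class universe the
    positive class is validated against (useful when a slice of data does
    not contain every class).
    """
    if len(predictions) != len(labels):
        raise ValueError(f"length mismatch: {len(predictions)} predictions, {len(labels)} labels")
    known = set(labels) | set(predictions) | set(known_classes or ())
    if positive_class not in known:
        raise ValueError(f"positive_class {positive_class!r} not among {sorted(known)}")
    tp = tn = fp = fn = 0
    for p, l in zip(predictions, labels):
        pred_pos = p == positive_class
        true_pos = l == positive_class
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos and not true_pos:
            fp += 1
        elif not pred_pos and true_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts, batch_id: Optional[int] = None) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity from the counts."""
    if c.total == 0:
        raise ValueError("no evaluated images (all counts zero)")
    return MetricsReport(
        accuracy=(c.TP + c.TN) / c.total,
        precision=_ratio(c.TP, c.TP + c.FP, "precision"),
        sensitivity=_ratio(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=_ratio(c.TN, c.TN + c.FP, "specificity"),
        batch_id=batch_id,
    )


def batch_evaluate_predictions(
    predictions: Sequence[str],
    labels: Sequence[str],
    positive_class: str,
    batch_size: int = 20,
) -> pd.DataFrame:
    """Per-batch metric rows plus an ``average`` row.

    Batches are consecutive slices of the given order; a trailing partial
    batch is kept and flagged in the ``n_images`` column.  The average row
    is the arithmetic mean of the per-batch values, skipping undefined
    (NaN) entries.  Percentages, two decimals.
    """
    if len(predictions) != len(labels):
        raise ValueError("length mismatch")
    if len(labels) == 0:
        raise ValueError("empty dataset")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    universe = set(labels) | set(predictions)
    if positive_class not in universe:
        raise ValueError(f"positive_class {positive_class!r} not among {sorted(universe)}")
    rows = []
    for bi, start in enumerate(range(0, len(labels), batch_size)):
        pred_b = predictions[start : start + batch_size]
        lab_b = labels[start : start + batch_size]
        rep = metrics(
            confusion(pred_b, lab_b, positive_class, known_classes=universe), batch_id=bi
        )
        rows.append({"batch": bi + 1, "n_images": len(lab_b), **rep.as_percent_dict()})
    df = pd.DataFrame(rows)
    avg = {"batch": "average", "n_images": int(df["n_images"].sum())}
    for m in METRIC_COLUMNS:
        avg[m] = round(float(df[m].mean(skipna=True)), 2)
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def batch_evaluate(
    model,
    dataset,
    learners: Sequence = (),
    positive_class: str | None = None,
    batch_size: int = 20,
) -> pd.DataFrame:
    """Run the model over a labelled dataset and tabulate per-batch metrics."""
    from .network import predict_labels, prepare_inputs

    X, _, _ = prepare_inputs(dataset, learners, classes=model.classes)
    preds = predict_labels(model, X)
    if positive_class is None:
        positive_class = model.classes[-1]
    return batch_evaluate_predictions(preds, list(dataset.labels), positive_class, batch_size)


def bmd_categorize(bmd: float) -> str:
    """Clinical BMD category for a value in mg/cm^2.

    Above 833 -> normal; 648 to 833 inclusive -> osteopenia; below 648 ->
    osteoporotic.  Both boundary values belong to osteopenia, matching the
    closed "between" wording of the clinical rule against the strict
    "more than"/"less than" wording of its neighbours.
    """
    if not math.isfinite(bmd) or bmd <= 0:
        raise ValueError(f"BMD must be a positive finite value in mg/cm^2, got {bmd}")
    if bmd > BMD_UPPER:
        return "normal"
    if bmd >= BMD_LOWER:
        return "osteopenia"
    return "osteoporotic"


def emit_report(
    prediction: str,
    probabilities: dict[str, float],
    bmd: float | None = None,
    metadata: dict | None = None,
    path: str | Path | None = None,
) -> dict:
    """Build (and optionally write) a machine-readable diagnostic report.

    The JSON document carries the predicted class, the per-class
    probabilities, the BMD category when a BMD value is supplied, and any
    provenance metadata (model hash, boosted-channel order).  A plain-text
    rendering is written alongside the JSON when ``path`` is given.
    """
    if prediction not in probabilities:
        raise ValueError(f"prediction {prediction!r} missing from probabilities")
    report = {
        "prediction": prediction,
        "probabilities": {k: float(v) for k, v in probabilities.items()},
        "bmd_mg_cm2": float(bmd) if bmd is not None else None,
        "bmd_category": bmd_categorize(bmd) if bmd is not None else None,
        "metadata": dict(metadata or {}),
    }
    if path is not None:
        path = Path(path)
        path.write_text(json.dumps(report, indent=2))
        lines = [
            "Osteoporosis diagnostic report",
            f"  predicted class : {prediction}",
        ]
        for cls, p in report["probabilities"].items():
            lines.append(f"  P({cls:<14s}) = {p:.4f}")
        if bmd is not None:
            lines.append(f"  BMD             : {bmd:.1f} mg/cm^2 -> {report['bmd_category']}")
        for k, v in report["metadata"].items():
            lines.append(f"  {k}: {v}")
        path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return report
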