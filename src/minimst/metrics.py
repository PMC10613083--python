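"""Precision, recall and F-measure for outlier detection against ground truth.

With ``m`` the correctly returned outliers, the detector returning
``returned`` outliers in total and ``truth`` ground-truth outliers:

    precision = m / returned      recall = m / truth
    F = 2 P R / (P + R)

Precision is defined as 0 when the detector returns nothing (some
detectors legitimately return no outliers), and F is 0 when P + R = 0.
Report tables round to 2 decimal places; full precision is kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DetectionResult

__all__ = ["EvaluationReport", "precision", "recall", "f_measure", "evaluate", "metrics_table"]


@dataclass(frozen=True)
class EvaluationReport:
    correct_returned: int
    returned_count: int
    truth_count: int
    precision: float
    recall: float
    f_measure: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(P, R, F) rounded the way benchmark tables print them."""
        return (
            round(self.precision, ndigits),
            round(self.recall, ndigits),
            round(self.f_measure, ndigits),
        )


def precision(m: int, returned: int) -> float:
    """Fraction of returned outliers that are correct; 0 if none returned."""
    if m < 0 or returned < 0 or m > returned:
        raise ValueError(f"need 0 <= m <= returned, got m={m}, returned={returned}")
    return m / returned if returned else 0.0


def recall(m: int, truth: int) -> float:
    """Fraction of ground-truth outliers that were returned."""
    if truth < 1:
        raise ValueError("no ground-truth outliers: recall undefined")
    if m < 0 or m > truth:
        raise ValueError(f"need 0 <= m <= truth, got m={m}, truth={truth}")
    return m / truth


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    return 2 * p * r / (p + r) if p + r else 0.0


def evaluate(result, truth) -> EvaluationReport:
    """Score a detection against binary ground truth (1 = outlier).

    ``result`` may be a :class:`DetectionResult` or any binary per-point
    flag array.
    """
    if isinstance(result, DetectionResult):
        predicted = np.asarray(result.outlier_mask, dtype=bool)
    else:
        predicted = np.asarray(result).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")

    m = int((predicted & truth).sum())
    returned = int(predicted.sum())
    o = int(truth.sum())
    p = precision(m, returned)
    r = recall(m, o) if o else 0.0
    return EvaluationReport(m, returned, o, p, r, f_measure(p, r))


def metrics_table(rows: dict[str, EvaluationReport], method: str = "MMOD") -> pd.DataFrame:
    """Benchmark-style table: one row per dataset with P/R/F columns."""
    records = [
        {
            "dataset": name,
            "method": method,
            "precision": round(rep.precision, 2),
            "recall": round(rep.recall, 2),
            "f_measure": round(rep.f_measure, 2),
        }
        for name, rep in rows.items()
    ]
    return pd.DataFrame.from_records(records)
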