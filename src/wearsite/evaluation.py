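"""Scoring and report rendering.

Accuracy is the fraction of predictions matching ground truth; confusion
matrices use rows for truth and columns for predictions.  For the ordered
intensity classes, a confusion matrix collapses to the study's
under/correct/over format: per true class, the percentage of predictions
below, on, and above the diagonal (the sedentary row has no "under", the
vigorous row no "over").  Rendering mirrors the study's two table layouts:
integer percentages for the count-baseline table, one decimal for the
network-performance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .groundtruth import INTENSITIES


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correct classifications."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return float((pred == truth).mean())


def confusion(pred: np.ndarray, truth: np.ndarray,
              classes: tuple[str, ...]) -> np.ndarray:
    """K x K counts, entry (i, j) = #(truth = classes[i], pred = classes[j])."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    unknown = (set(np.unique(pred)) | set(np.unique(truth))) - set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in classes {classes}")
    return _sk_confusion(truth, pred, labels=list(classes))


def per_class_rates(conf: np.ndarray) -> pd.DataFrame:
    """Sensitivity (recall) and specificity per class from a confusion matrix."""
    conf = np.asarray(conf, dtype=float)
    total = conf.sum()
    tp = np.diag(conf)
    support = conf.sum(axis=1)
    predicted = conf.sum(axis=0)
    tn = total - support - predicted + tp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(support > 0, tp / support, np.nan)
        spec = np.where(total - support > 0, tn / (total - support), np.nan)
    return pd.DataFrame({"sensitivity": sens, "specificity": spec,
                         "support": support.astype(int)})


def collapse_under_over(conf: np.ndarray,
                        classes: tuple[str, ...] = INTENSITIES) -> pd.DataFrame:
    """Collapse an ordered-class confusion matrix to under/correct/over %.

    Structurally absent cells (no class below sedentary, none above
    vigorous) are NaN; empty rows are all-NaN.  Percentages of a populated
    row sum to 100 before rounding.
    """
    conf = np.asarray(conf, dtype=float)
    k = conf.shape[0]
    if conf.shape != (k, k) or k != len(classes):
        raise ValueError("confusion matrix does not match the class list")
    rows = []
    for i, lab in enumerate(classes):
        n = conf[i].sum()
        if n == 0:
            rows.append((lab, np.nan, np.nan, np.nan, 0))
            continue
        under = 100.0 * conf[i, :i].sum() / n
        correct = 100.0 * conf[i, i] / n
        over = 100.0 * conf[i, i + 1:].sum() / n
        rows.append((lab,
                     under if i > 0 else np.nan,
                     correct,
                     over if i < k - 1 else np.nan,
                     int(n)))
    return pd.DataFrame(rows, columns=["intensity", "under", "correct",
                                       "over", "n"]).set_index("intensity")


@dataclass
class EvaluationReport:
    """Everything scored for one task cell, with raw fractions retained."""

    task: str
    classes: tuple[str, ...]
    confusion: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def overall_accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else np.nan

    @property
    def per_class(self) -> pd.DataFrame:
        return per_class_rates(self.confusion)

    def under_correct_over(self) -> pd.DataFrame:
        if tuple(self.classes) != tuple(INTENSITIES):
            raise ValueError("under/correct/over requires the intensity order")
        return collapse_under_over(self.confusion, self.classes)


def evaluate(pred: np.ndarray, truth: np.ndarray, classes: tuple[str, ...],
             task: str = "", **metadata) -> EvaluationReport:
    return EvaluationReport(task=task, classes=tuple(classes),
                            confusion=confusion(pred, truth, classes),
                            metadata=metadata)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _fmt_pct(x: float, decimals: int) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    return f"{x:.0f}%" if decimals == 0 else f"{x:.{decimals}f}%"


def render_misspecification_table(report: pd.DataFrame) -> str:
    """Human-readable under/correct/over table (integer percentages)."""
    lines = [f"{'group':<10}{'intensity':<12}{'under':>8}{'correct':>9}{'over':>7}"]
    for _, r in report.iterrows():
        lines.append(f"{r['group']:<10}{r['intensity']:<12}"
                     f"{_fmt_pct(r['under'], 0):>8}"
                     f"{_fmt_pct(r['correct'], 0):>9}"
                     f"{_fmt_pct(r['over'], 0):>7}")
    return "\n".join(lines)


def render_grid_table(grid: pd.DataFrame) -> str:
    """Network-performance table: purpose x group rows, scope x arch columns
    (accuracies to one decimal, missing cells as a dash)."""
    piv = grid.pivot_table(index=["purpose", "group"],
                           columns=["scope", "architecture"],
                           values="val_accuracy", aggfunc="first",
                           sort=False)
    lines = []
    header = f"{'purpose':<22}{'group':<10}"
    cols = list(piv.columns)
    for scope, arch in cols:
        header += f"{scope + '/' + arch:>22}"
    lines.append(header)
    for (purpose, group), row in piv.iterrows():
        line = f"{purpose:<22}{group:<10}"
        for c in cols:
            v = row[c]
            line += f"{_fmt_pct(100 * v if np.isfinite(v) else np.nan, 1):>22}"
        lines.append(line)
    return "\n".join(lines)


def write_reports(grid: pd.DataFrame | None, misspec: pd.DataFrame | None,
                  out_dir) -> list[str]:
    """Write CSV + text renderings; returns the file paths written."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if misspec is not None:
        p = out_dir / "misspecification.csv"
        misspec.to_csv(p, index=False)
        written.append(str(p))
        p = out_dir / "misspecification.txt"
        p.write_text(render_misspecification_table(misspec) + "\n")
        written.append(str(p))
    if grid is not None:
        p = out_dir / "model_grid.csv"
        grid.to_csv(p, index=False)
        written.append(str(p))
        p = out_dir / "model_grid.txt"
        p.write_text(render_grid_table(grid) + "\n")
        written.append(str(p))
    return written
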