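"""Performance metrics: confusion matrices (row percent), one-vs-rest
sensitivity / specificity / F1, accuracy, and per-subject aggregation.

Definitions follow the standard epidemiological usage: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic
mean of precision and sensitivity, accuracy the proportion of correctly
classified windows.  Undefined ratios (zero denominators) are reported as
``None``, never silently substituted with 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLASSES


@dataclass
class ConfusionMatrix:
    """Counts with rows = labelled class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def zero_rows(self) -> list[str]:
        """Labelled classes with no instances (flagged, not divided)."""
        return [c for c, t in zip(self.classes, self.row_totals) if t == 0]

    @property
    def row_percent(self) -> np.ndarray:
        """Rows normalized to percentages; all-NaN for empty rows."""
        totals = self.row_totals.astype(float)
        out = np.full(self.counts.shape, np.nan)
        nz = totals > 0
        out[nz] = 100.0 * self.counts[nz] / totals[nz, None]
        return out

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(data, index=list(self.classes),
                            columns=list(self.classes))


def build_confusion(true_labels, predicted_labels,
                    classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Count (labelled, predicted) pairs into a confusion matrix."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(t) | set(p)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def compute_metrics(conf: ConfusionMatrix) -> dict:
    """One-vs-rest per-class metrics, overall accuracy and macro averages.

    Returns ``{"per_class": {cls: {sensitivity, specificity, precision,
    f1}}, "accuracy": float|None, "macro": {...}}``.  Macro averages skip
    undefined per-class values.
    """
    if len(conf.classes) < 2:
        raise ValueError("need at least 2 classes")
    c = conf.counts
    total = int(c.sum())
    per_class: dict[str, dict] = {}
    for i, cls in enumerate(conf.classes):
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else None
        spec = tn / (tn + fp) if tn + fp > 0 else None
        prec = tp / (tp + fp) if tp + fp > 0 else None
        if sens is not None and prec is not None and sens + prec > 0:
            f1 = 2 * prec * sens / (prec + sens)
        elif sens is not None and prec is not None:
            f1 = 0.0
        else:
            f1 = None
        per_class[cls] = {"sensitivity": sens, "specificity": spec,
                          "precision": prec, "f1": f1}
    accuracy = float(np.trace(c)) / total if total > 0 else None
    macro = {}
    for m in ("sensitivity", "specificity", "precision", "f1"):
        vals = [v[m] for v in per_class.values() if v[m] is not None]
        macro[m] = float(np.mean(vals)) if vals else None
    return {"per_class": per_class, "accuracy": accuracy, "macro": macro}


def aggregate_subjects(values) -> dict:
    """Mean, sample SD (n-1), min and max across subjects.

    With a single subject the SD is reported as ``None`` (not available),
    never 0.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("need at least one subject")
    arr = np.array(vals)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": len(arr),
    }


@dataclass
class MetricsReport:
    """Pooled and per-subject performance for one (setup, window) cell."""

    configuration: tuple[str, float]
    confusion: ConfusionMatrix
    pooled: dict
    per_subject: dict[str, dict]
    aggregate: dict[str, dict]


def evaluate_predictions(
    predictions: pd.DataFrame,
    classes: tuple[str, ...] = CLASSES,
    configuration: tuple[str, float] = ("", 0.0),
) -> MetricsReport:
    """Turn a LOSO prediction table into a full metrics report.

    ``predictions`` needs columns ``participant_id``, ``true``,
    ``predicted``.  Per-subject metrics are computed on each held-out
    participant's windows and aggregated (mean / SD / min / max) — the
    headline per-subject-mean accuracy — alongside pooled all-window
    metrics and the pooled row-percent confusion matrix.
    """
    conf = build_confusion(predictions["true"], predictions["predicted"], classes)
    pooled = compute_metrics(conf)
    per_subject: dict[str, dict] = {}
    for pid, grp in predictions.groupby("participant_id", sort=True):
        sconf = build_confusion(grp["true"], grp["predicted"], classes)
        m = compute_metrics(sconf)
        per_subject[pid] = m
    aggregate: dict[str, dict] = {
        "accuracy": aggregate_subjects(
            [m["accuracy"] for m in per_subject.values() if m["accuracy"] is not None]
        )
    }
    for metric in ("sensitivity", "specificity", "f1"):
        vals = [m["macro"][metric] for m in per_subject.values()
                if m["macro"][metric] is not None]
        if vals:
            aggregate[f"macro_{metric}"] = aggregate_subjects(vals)
    return MetricsReport(configuration=configuration, confusion=conf,
                         pooled=pooled, per_subject=per_subject,
                         aggregate=aggregate)


def compare_configurations(results: dict[tuple[str, float], MetricsReport]) -> pd.DataFrame:
    """Long-format comparison table across (setup, window-length) cells.

    One row per (setup, window_length, metric, class) with subject-level
    mean / SD / min / max; per-class rows use each subject's one-vs-rest
    value, ``class == "macro"`` rows the macro average, and
    ``(accuracy, all)`` the subject accuracies.
    """
    if not results:
        raise ValueError("no configurations to compare")
    rows = []
    for (setup, wl), report in sorted(results.items()):
        subjects = report.per_subject

        def agg_row(metric, cls, values):
            vals = [v for v in values if v is not None]
            if not vals:
                return
            a = aggregate_subjects(vals)
            rows.append({"setup": setup, "window_length": wl, "metric": metric,
                         "class": cls, **a})

        agg_row("accuracy", "all", [m["accuracy"] for m in subjects.values()])
        for metric in ("sensitivity", "specificity", "f1"):
            for cls in report.confusion.classes:
                agg_row(metric, cls,
                        [m["per_class"][cls][metric] for m in subjects.values()])
            agg_row(metric, "macro",
                    [m["macro"][metric] for m in subjects.values()])
    return pd.DataFrame(rows)
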