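"""Repeated imbalanced-split evaluation protocol.

Performance is measured per class by Precision = TP/(TP+FP),
Recall = TP/(TP+FN) and their harmonic mean

    F-score = 2 * Precision * Recall / (Precision + Recall),

macro-averaged (unweighted across classes — weighting by support would be
dominated by the majority class, defeating the point of studying
imbalance).  Each (imbalance design, augmentation method) cell is repeated
``n_repetitions`` times with freshly drawn imbalanced splits and network
initializations, all seeds derived deterministically from one base seed;
the same split is shared across methods within a repetition, so methods can
be compared with a paired one-sided t-test.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import gan
from .augment import augment_to_balance
from .spectra import ImbalanceSpec, SpectralDataset, make_imbalanced_split, normalize_minmax

__all__ = ["ConfusionCounts", "MetricsReport", "AggregateReport", "compute_metrics",
           "run_experiment", "paired_one_sided_t", "export_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Per-class and macro Precision/Recall/F-score for one evaluation.

    Zero-denominator convention: a precision or recall whose denominator is
    0 is reported as 0, and F = 0 when P + R = 0.
    """

    classes: list[str]
    confusion: dict[str, ConfusionCounts]
    precision: dict[str, float]
    recall: dict[str, float]
    f_score: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f: float

    def as_dict(self) -> dict:
        return {
            "per_class": {c: {"precision": self.precision[c], "recall": self.recall[c],
                              "f_score": self.f_score[c]} for c in self.classes},
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f_score": self.macro_f},
        }


def compute_metrics(true_labels, predicted_labels, classes) -> MetricsReport:
    """Per-class and macro metrics from raw label sequences."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    known = set(classes)
    stray = (set(true_labels) | set(predicted_labels)) - known
    if stray:
        raise ValueError(f"labels outside the class inventory: {sorted(stray)}")

    confusion, precision, recall, f_score = {}, {}, {}, {}
    n = len(true_labels)
    for c in classes:
        tp = sum(1 for t, p in zip(true_labels, predicted_labels) if t == c and p == c)
        fp = sum(1 for t, p in zip(true_labels, predicted_labels) if t != c and p == c)
        fn = sum(1 for t, p in zip(true_labels, predicted_labels) if t == c and p != c)
        confusion[c] = ConfusionCounts(tp, fp, fn, n - tp - fp - fn)
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        pr = precision[c] + recall[c]
        f_score[c] = 2.0 * precision[c] * recall[c] / pr if pr else 0.0
    k = len(list(classes))
    return MetricsReport(list(classes), confusion, precision, recall, f_score,
                         macro_precision=sum(precision.values()) / k,
                         macro_recall=sum(recall.values()) / k,
                         macro_f=sum(f_score.values()) / k)


def paired_one_sided_t(a, b):
    """Paired t-test of H1: mean(a) >= mean(b); returns (t, upper-tail p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D sequences with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate paired test: all differences equal")
    t = d.mean() / (sd / math.sqrt(d.size))
    p = float(stats.t.sf(t, df=d.size - 1))
    return float(t), p


@dataclass
class AggregateReport:
    """Repetition statistics for one (imbalance design, method) cell."""

    method: str
    spec: ImbalanceSpec
    repetitions: list[MetricsReport] = field(default_factory=list)

    @property
    def n_repetitions(self) -> int:
        return len(self.repetitions)

    def series(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, f"macro_{metric}") for r in self.repetitions])

    def mean(self, metric: str) -> float:
        return float(self.series(metric).mean())

    def sd(self, metric: str) -> float:
        s = self.series(metric)
        return float(s.std(ddof=1)) if s.size > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "balanced_ratio": self.spec.ratio_display,
            "majority_n": self.spec.majority_n,
            "minority_n": self.spec.minority_n,
            "n_repetitions": self.n_repetitions,
            "per_repetition": [r.as_dict() for r in self.repetitions],
            "summary": {m: {"mean": self.mean(m.replace("f_score", "f")),
                            "sd": self.sd(m.replace("f_score", "f"))}
                        for m in ("precision", "recall", "f_score")},
        }


def _derive_seed(base_seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(base_seed)] + [int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_method(train: SpectralDataset, test: SpectralDataset, method: str,
                    seed: int, gan_config: gan.ThreePlayerConfig,
                    k_neighbors: int = 5) -> MetricsReport:
    """Train one method on one split and score it on the held-out test set.

    Normalization constants come from the training split only.
    """
    train_n, norm = normalize_minmax(train)
    test_n = norm.transform(test)
    cfg_seed = dataclasses.replace(gan_config, seed=seed)
    if method == "threeplayer-gan":
        players, _log = gan.train(train_n, cfg_seed)
    else:
        if method == "none":
            fit_data = train_n
        elif method in ("smote", "b-smote"):
            # interpolation needs k < smallest class size
            k_eff = max(1, min(k_neighbors, min(train.class_counts().values()) - 1))
            fit_data = augment_to_balance(train_n, method, seed, k_eff)
        else:
            raise ValueError(f"unknown method {method!r}")
        players, _losses = gan.train_classifier(fit_data, cfg_seed)
    preds = gan.predict_labels(players, test_n.values)
    return compute_metrics(test.labels, preds, train.classes)


def run_experiment(dataset: SpectralDataset, specs, methods, n_repetitions: int,
                   base_seed: int, train_protocol: gan.ThreePlayerConfig | None = None,
                   k_neighbors: int = 5) -> list[AggregateReport]:
    """The repeated-split comparison protocol.

    For every (imbalance design, method, repetition): draw the imbalanced
    training split (shared across methods within the repetition), train the
    method, evaluate on all held-out spectra.  Returns one aggregate per
    (design, method) in the given order.
    """
    if train_protocol is None:
        train_protocol = gan.ThreePlayerConfig.scaled_down()
    reports = [AggregateReport(m, spec) for spec in specs for m in methods]
    by_key = {(id_spec, m): r for r, (id_spec, m) in
              zip(reports, ((i, m) for i in range(len(specs)) for m in methods))}
    for i, spec in enumerate(specs):
        for rep in range(n_repetitions):
            split_seed = _derive_seed(base_seed, i, rep)
            train, test, _realized = make_imbalanced_split(dataset, spec, split_seed)
            for j, method in enumerate(methods):
                method_seed = _derive_seed(base_seed, i, rep, j)
                report = evaluate_method(train, test, method, method_seed,
                                         train_protocol, k_neighbors)
                by_key[(i, method)].repetitions.append(report)
    return reports


def export_report(reports: list[AggregateReport], path,
                  feature_matrices: dict | None = None) -> None:
    """Write mean±sd tables (CSV + JSON) and optional feature matrices.

    The CSV has one row per (method, ratio, metric); the JSON additionally
    carries every per-repetition value so the table is re-derivable.
    """
    if not reports:
        raise ValueError("empty report collection")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in reports:
        for metric in ("precision", "recall", "f_score"):
            short = metric.replace("f_score", "f")
            rows.append({"method": r.method, "ratio": r.spec.ratio_display,
                         "metric": metric, "mean": r.mean(short), "sd": r.sd(short),
                         "n_reps": r.n_repetitions})
    frame = pd.DataFrame(rows, columns=["method", "ratio", "metric", "mean", "sd",
                                        "n_reps"])
    frame.to_csv(path / "metrics.csv", index=False, float_format="%.17g")
    payload = [r.as_dict() for r in reports]
    (path / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    if feature_matrices:
        for name, matrix in feature_matrices.items():
            np.savetxt(path / f"features_{name}.tsv", np.asarray(matrix),
                       delimiter="\t")
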