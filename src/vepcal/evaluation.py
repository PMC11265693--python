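"""Scoring of recovered epileptogenicity maps and optimizer runs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "LABELS",
    "ConfusionMatrix",
    "classify_regions",
    "confusion_and_accuracy",
    "convergence_report",
]

#: canonical label order for all 3x3 tabulations
LABELS = ("EZ", "PZ", "HZ")


def classify_regions(eta_est, eta_c: float = -2.05, delta_eta: float = 1.0):
    """Classify regions by excitability into EZ / PZ / HZ.

    EZ:  eta > eta_c               (autonomous seizure onset)
    PZ:  eta_c - d_eta < eta <= eta_c  (recruitable, near-critical)
    HZ:  eta <= eta_c - d_eta      (healthy)

    Boundary values go to the less pathological class (eta == eta_c -> PZ,
    eta == eta_c - d_eta -> HZ).
    """
    if delta_eta <= 0:
        raise ValueError("delta_eta must be positive")
    eta = np.asarray(eta_est, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("excitability values must be finite")
    labels = np.full(eta.shape, "HZ", dtype="<U2")
    labels[eta > eta_c] = "EZ"
    labels[(eta > eta_c - delta_eta) & (eta <= eta_c)] = "PZ"
    return labels


@dataclass
class ConfusionMatrix:
    """3x3 cross-tabulation (rows true, columns predicted, order EZ/PZ/HZ)."""

    counts: np.ndarray
    accuracy: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be a 3x3 matrix")

    def to_dict(self) -> dict:
        return {
            "labels": list(LABELS),
            "counts": self.counts.tolist(),
            "accuracy": float(self.accuracy),
        }


def confusion_and_accuracy(truth_labels, predicted_labels) -> ConfusionMatrix:
    """Cross-tabulate true vs predicted EZ/PZ/HZ labels; trace accuracy."""
    t = np.asarray(truth_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((t, "truth"), (p, "prediction")):
        bad = set(arr.tolist()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    counts = _sk_confusion(t, p, labels=list(LABELS))
    acc = float(np.trace(counts)) / float(counts.sum())
    return ConfusionMatrix(counts=counts, accuracy=acc)


@dataclass
class ConvergenceSummary:
    best_cost: float
    mean_cost: float
    std_cost: float
    single_run: bool
    per_run_best: list[float] = field(default_factory=list)
    traces: list[list[tuple[int, float]]] = field(default_factory=list)


def convergence_report(results) -> ConvergenceSummary:
    """Best / mean / std of final costs over repeated optimization runs.

    The standard deviation is the sample std (ddof=1); a single run reports
    0 with ``single_run`` flagged.
    """
    results = list(results)
    if not results:
        raise ValueError("convergence_report requires at least one result")
    bests = [float(r.best_cost) for r in results]
    single = len(bests) == 1
    std = 0.0 if single else float(np.std(bests, ddof=1))
    return ConvergenceSummary(
        best_cost=float(min(bests)),
        mean_cost=float(np.mean(bests)),
        std_cost=std,
        single_run=single,
        per_run_best=bests,
        traces=[list(r.trace) for r in results],
    )
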