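"""Evaluation: feature contributions, cluster separation, eyes-scoring accuracy.

Feature contributions are Spearman rank correlations between each feature
column and the estimated consciousness trace (per clustering method and for
the ensemble).  Cluster separation is the Euclidean (centroid-linkage)
distance between the two centroids, over all features or any subset.
Agreement with the behavioural eyes scoring binarises the trace at each
threshold in {0.3, 0.4, 0.5, 0.6, 0.7} (values at or above the threshold
map to 1), assigns 1 to eyes-open (O) and 0 to eyes-closed (C) epochs,
aggregates trace samples within each 5-min epoch by majority, and reports

    accuracy = (TP + TN) / (TP + TN + FP + FN)

over the evaluable epochs (O/C and NA epochs are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import ConsciousnessTrace
from .features import FeatureMatrix

__all__ = [
    "EyesScoring",
    "spearman_contributions",
    "intercluster_distance",
    "accuracy_vs_eyes",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.3, 0.4, 0.5, 0.6, 0.7)
VALID_LABELS = {"O", "C", "O/C", "NA"}


@dataclass
class EyesScoring:
    """Ordered, non-overlapping eyes-state epochs (start_s, end_s, label)."""

    epochs: list[tuple[float, float, str]]
    epoch_length_s: float = 300.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, label in self.epochs:
            if end <= start:
                raise ValueError(f"empty epoch [{start}, {end})")
            if start < prev_end:
                raise ValueError("epochs must be time-ordered and non-overlapping")
            if label not in VALID_LABELS:
                raise ValueError(f"unknown eyes label {label!r}")
            prev_end = end

    def __len__(self) -> int:
        return len(self.epochs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs,
                            columns=["epoch_start_s", "epoch_end_s", "label"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EyesScoring":
        df = pd.read_csv(path, keep_default_na=False)
        epochs = [
            (float(r.epoch_start_s), float(r.epoch_end_s), str(r.label))
            for r in df.itertuples()
        ]
        length = epochs[0][1] - epochs[0][0] if epochs else 300.0
        return cls(epochs=epochs, epoch_length_s=length)


def spearman_contributions(
    fm: FeatureMatrix,
    traces: dict[str, ConsciousnessTrace],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman ρ between each feature and each estimated trace.

    Returns one row per (feature, method) with the correlation, its p-value
    and a significance flag (p <= alpha).  Non-finite pairs are dropped;
    constant inputs yield NaN.
    """
    rows = []
    for method, trace in traces.items():
        if len(trace) != fm.n_windows:
            raise ValueError(f"trace {method!r} not aligned with features")
        for j, name in enumerate(fm.feature_names):
            x = fm.values[:, j]
            y = trace.p_conscious
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append({
                "feature": name,
                "method": method,
                "rho": float(rho),
                "p_value": float(p),
                "significant": bool(p <= alpha) if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows)


def intercluster_distance(
    c1: np.ndarray,
    c2: np.ndarray,
    dims: list[int] | None = None,
) -> float:
    """Euclidean (centroid-linkage) distance between two centroids.

    ``dims`` restricts the distance to a subset of feature coordinates,
    e.g. a feature pair.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("centroids must have equal dimension")
    if dims is not None:
        c1, c2 = c1[list(dims)], c2[list(dims)]
    return float(np.linalg.norm(c1 - c2))


def accuracy_vs_eyes(
    trace: ConsciousnessTrace,
    eyes: EyesScoring,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Thresholded accuracy of the trace against the eyes scoring.

    For each threshold the trace is binarised (>= threshold -> 1), each
    evaluable epoch's prediction is the majority binarised value of the
    trace samples starting inside it, and Accuracy = (TP+TN)/(TP+TN+FP+FN)
    with O as the positive class.
    """
    evaluable = [(s, e, lab) for s, e, lab in eyes.epochs if lab in ("O", "C")]
    if not evaluable:
        raise ValueError("no evaluable (O or C) epochs in the eyes scoring")
    t = trace.timestamps
    p = trace.p_conscious
    rows = []
    for thr in thresholds:
        binary = np.where(np.isnan(p), np.nan, (p >= thr).astype(float))
        tp = tn = fp = fn = 0
        for start, end, lab in evaluable:
            in_epoch = (t >= start) & (t < end) & ~np.isnan(binary)
            if not in_epoch.any():
                continue
            pred = 1 if binary[in_epoch].mean() >= 0.5 else 0
            truth = 1 if lab == "O" else 0
            if pred == 1 and truth == 1:
                tp += 1
            elif pred == 0 and truth == 0:
                tn += 1
            elif pred == 1 and truth == 0:
                fp += 1
            else:
                fn += 1
        total = tp + tn + fp + fn
        if total == 0:
            raise ValueError("no trace samples fall inside evaluable epochs")
        rows.append({
            "threshold": thr,
            "accuracy": (tp + tn) / total,
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        })
    return pd.DataFrame(rows)
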