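"""Overlap metrics for binary segmentation masks.

All four metrics are defined on the predicted tumor pixel set ``Vs`` and
the ground-truth tumor pixel set ``Vg`` of a common image grid:

    Dice      = 2|Vs ∩ Vg| / (|Vs| + |Vg|)
    Jaccard   =  |Vs ∩ Vg| / |Vs ∪ Vg|        (= IoU)
    Precision =  |Vs ∩ Vg| / |Vs|
    Recall    =  |Vs ∩ Vg| / |Vg|

Each metric is undefined when its denominator is empty; that case raises
:class:`UndefinedMetricError` rather than silently returning 0 or 1,
because silent conventions bias averages over many samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UndefinedMetricError", "PixelSets", "MetricsReport",
    "dice", "jaccard", "precision", "recall", "evaluate",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator pixel set is empty."""


@dataclass(frozen=True)
class PixelSets:
    """Predicted and ground-truth binary masks of one common shape."""

    vs: np.ndarray
    vg: np.ndarray

    def __post_init__(self):
        vs = np.asarray(self.vs).astype(bool)
        vg = np.asarray(self.vg).astype(bool)
        if vs.shape != vg.shape:
            raise ValueError(f"mask shapes differ: {vs.shape} vs {vg.shape}")
        object.__setattr__(self, "vs", vs)
        object.__setattr__(self, "vg", vg)

    @property
    def intersection(self) -> int:
        return int(np.count_nonzero(self.vs & self.vg))

    @property
    def n_pred(self) -> int:
        return int(np.count_nonzero(self.vs))

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.vg))


def _as_sets(vs, vg=None) -> PixelSets:
    if isinstance(vs, PixelSets) and vg is None:
        return vs
    return PixelSets(vs, vg)


def dice(vs, vg=None) -> float:
    """Dice coefficient 2|Vs ∩ Vg| / (|Vs| + |Vg|)."""
    s = _as_sets(vs, vg)
    denom = s.n_pred + s.n_true
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return 2.0 * s.intersection / denom


def jaccard(vs, vg=None) -> float:
    """Jaccard coefficient (IoU) |Vs ∩ Vg| / |Vs ∪ Vg|."""
    s = _as_sets(vs, vg)
    union = s.n_pred + s.n_true - s.intersection
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: empty union")
    return s.intersection / union


def precision(vs, vg=None) -> float:
    """|Vs ∩ Vg| / |Vs|; undefined when nothing was predicted."""
    s = _as_sets(vs, vg)
    if s.n_pred == 0:
        raise UndefinedMetricError("Precision undefined: empty prediction")
    return s.intersection / s.n_pred


def recall(vs, vg=None) -> float:
    """|Vs ∩ Vg| / |Vg|; undefined when the ground truth is empty."""
    s = _as_sets(vs, vg)
    if s.n_true == 0:
        raise UndefinedMetricError("Recall undefined: empty ground truth")
    return s.intersection / s.n_true


@dataclass
class MetricsReport:
    """Per-sample and mean overlap metrics, with the inclusion policy recorded.

    ``per_sample`` rows are (sample_id, dice, jaccard, precision, recall);
    precision is NaN where the prediction is empty (recall and the overlap
    numerator are still defined because included samples have nonempty
    ground truth). ``false_positive_slices`` counts samples excluded for
    empty ground truth that nonetheless carry predicted pixels.
    """

    per_sample: list[tuple] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    policy: str = ""
    false_positive_slices: int = 0

    def to_dict(self) -> dict:
        return {
            "per_sample": [
                {"id": r[0], "dice": r[1], "jaccard": r[2],
                 "precision": r[3], "recall": r[4]}
                for r in self.per_sample
            ],
            "aggregate": self.aggregate,
            "policy": self.policy,
            "false_positive_slices": self.false_positive_slices,
        }


def evaluate(predictions, truths, sample_ids=None,
             policy: str = "per-slice mean over samples with nonempty ground truth",
             per_volume: bool = False) -> MetricsReport:
    """Compute all four metrics per sample and their means.

    Samples with empty ground truth are excluded from the averages (their
    recall is undefined); those of them with nonempty predictions are
    tallied separately as false-positive slices. With ``per_volume`` the
    caller passes whole-volume masks and pixel counts pool across slices
    implicitly.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if sample_ids is None:
        sample_ids = list(range(len(predictions)))
    report = MetricsReport(policy=policy + (" (per-volume pooling)" if per_volume else ""))
    for sid, pred, true in zip(sample_ids, predictions, truths):
        s = PixelSets(pred, true)
        if s.n_true == 0:
            if s.n_pred > 0:
                report.false_positive_slices += 1
            continue
        d = dice(s)
        j = jaccard(s)
        p = precision(s) if s.n_pred > 0 else float("nan")
        r = recall(s)
        report.per_sample.append((sid, d, j, p, r))
    if report.per_sample:
        arr = np.array([row[1:] for row in report.per_sample], dtype=float)
        prec = arr[:, 2][~np.isnan(arr[:, 2])]
        report.aggregate = {
            "dice": float(np.mean(arr[:, 0])),
            "jaccard": float(np.mean(arr[:, 1])),
            "precision": float(np.mean(prec)) if prec.size else float("nan"),
            "recall": float(np.mean(arr[:, 3])),
            "n_samples": len(report.per_sample),
        }
    else:
        report.aggregate = {"dice": float("nan"), "jaccard": float("nan"),
                            "precision": float("nan"), "recall": float("nan"),
                            "n_samples": 0}
    return report
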