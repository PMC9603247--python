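"""Threshold classification metrics on the 2x2 confusion table.

ACC, PRE (precision), SEN (sensitivity/recall), SPE (specificity) and
MCC (Matthews correlation, equal to the Pearson correlation of the two
binary vectors). Ratios with a zero denominator are reported as 0 and
flagged in ``undefined`` so fold averaging never crashes on degenerate
folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    acc: float
    pre: float
    sen: float
    spe: float
    mcc: float
    undefined: tuple[str, ...] = ()

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        nd = 2 if percent else 6
        d = {k: round(getattr(self, k) * scale, nd)
             for k in ("acc", "pre", "sen", "spe", "mcc")}
        d["undefined"] = list(self.undefined)
        return d

    def to_json(self, percent: bool = False) -> str:
        return json.dumps(self.to_dict(percent=percent), indent=2)


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate true labels against predictions (1 = positive class)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be equal-length 1-D")
    if y.size == 0:
        raise ValueError("need at least one sample")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Compute ACC, PRE, SEN, SPE, MCC from confusion counts.

    MCC uses the standard form (TP*TN - FP*FN) over the square root of
    the four marginal products; any zero marginal makes it undefined
    (flagged, reported as 0).
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = (float(counts.tp), float(counts.tn),
                      float(counts.fp), float(counts.fn))
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / counts.total
    pre = ratio(tp, tp + fp, "pre")
    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricReport(acc, pre, sen, spe, mcc, tuple(undefined))


def evaluate(labels: Sequence[int], predictions: Sequence[int]) -> MetricReport:
    """Convenience: confusion + metrics in one call."""
    return compute_metrics(confusion(labels, predictions))


__all__ = ["ConfusionCounts", "MetricReport", "confusion",
           "compute_metrics", "evaluate"]
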