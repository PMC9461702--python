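"""Validation arithmetic: pixelwise segmentation scores and feature errors.

Automatic segmentations are scored against reference (manual or ground-truth)
masks with the usual pixel counts: sensitivity (true positive rate,
TP/(TP+FN)) and precision (positive predictive value, TP/(TP+FP)).  Feature
values are compared between manual (MS) and automatic (AS) measurement as a
relative error |(MS-AS)/MS|*100 in percent, or an absolute error |MS-AS| for
dimensionless/angular quantities (roundness, averaged intersphere angle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ValidationCounts", "pixel_counts", "segmentation_scores",
           "feature_errors", "batch_feature_errors"]


@dataclass(frozen=True)
class ValidationCounts:
    """Pixel counts of an automatic mask against a reference mask."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("pixel counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        """TPR = TP / (TP + FN); NaN when the reference is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        """PPV = TP / (TP + FP); NaN when the automatic mask is empty."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")


def pixel_counts(auto_mask: np.ndarray, reference_mask: np.ndarray
                 ) -> ValidationCounts:
    auto = np.asarray(auto_mask, dtype=bool)
    ref = np.asarray(reference_mask, dtype=bool)
    if auto.shape != ref.shape:
        raise ValueError("masks must have the same shape")
    tp = int(np.count_nonzero(auto & ref))
    fp = int(np.count_nonzero(auto & ~ref))
    fn = int(np.count_nonzero(~auto & ref))
    return ValidationCounts(tp=tp, fp=fp, fn=fn)


def segmentation_scores(auto_mask: np.ndarray, reference_mask: np.ndarray
                        ) -> tuple[float, float]:
    """Pixelwise (sensitivity, precision) of ``auto_mask`` vs the reference.

    An empty reference leaves sensitivity undefined (NaN); an empty automatic
    mask leaves precision undefined (NaN).
    """
    c = pixel_counts(auto_mask, reference_mask)
    return c.sensitivity, c.precision


def feature_errors(ms: float, as_: float, mode: str = "relative") -> float:
    """Error of an automatic feature value against the manual one.

    ``relative`` returns |(MS - AS)/MS| * 100 in percent and requires
    MS != 0; ``absolute`` returns |MS - AS|.
    """
    if mode == "relative":
        if ms == 0:
            raise ZeroDivisionError("relative error undefined for MS = 0")
        return abs((ms - as_) / ms) * 100.0
    if mode == "absolute":
        return abs(ms - as_)
    raise ValueError(f"unknown mode {mode!r}")


def batch_feature_errors(ms: np.ndarray, as_: np.ndarray,
                         mode: str = "relative") -> pd.Series:
    """Mean +/- SD of per-sample feature errors, as a small summary Series."""
    ms = np.asarray(ms, dtype=float)
    as_ = np.asarray(as_, dtype=float)
    if ms.shape != as_.shape:
        raise ValueError("MS and AS arrays must align")
    errs = np.array([feature_errors(m, a, mode) for m, a in zip(ms, as_)])
    return pd.Series({"mean": errs.mean(), "sd": errs.std(ddof=1) if errs.size > 1 else 0.0,
                      "n": errs.size})
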