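"""Pixel-level template-matching evaluation of binary masks.

Predicted and ground-truth masks are compared pixel to pixel into
TP/TN/FP/FN counts, from which sensitivity, specificity, accuracy, PPV
and NPV are derived; a global structural similarity index (SSIM) over the
whole template completes the six reported measures.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("fundustex")

# standard SSIM stability constants for dynamic range L
_K1, _K2 = 0.01, 0.03


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    ssim: float | None = None


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two same-shape binary masks."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str) -> float:
    """den == 0 means the condition is vacuous; the ratio is defined as 1."""
    if den == 0:
        logger.debug("zero denominator for %s: defined as 1", name)
        return 1.0
    return num / den


def report(c: ConfusionCounts, ssim_value: float | None = None) -> MetricReport:
    """The five ratio metrics (plus optional SSIM) from confusion counts."""
    return MetricReport(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        ppv=_ratio(c.tp, c.tp + c.fp, "PPV"),
        npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
        ssim=ssim_value,
    )


def ssim(x: np.ndarray, y: np.ndarray, dynamic_range: float = 255.0) -> float:
    """Global (whole-template) structural similarity index.

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
           ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    computed over the full images with population moments and the standard
    stability constants c1 = (0.01 L)^2, c2 = (0.03 L)^2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    c1 = (_K1 * dynamic_range) ** 2
    c2 = (_K2 * dynamic_range) ** 2
    mu_x, mu_y = x.mean(), y.mean()
    var_x = ((x - mu_x) ** 2).mean()
    var_y = ((y - mu_y) ** 2).mean()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return float((2 * mu_x * mu_y + c1) * (2 * cov + c2)
                 / ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)))


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Full six-measure report between a predicted and a ground-truth mask.

    SSIM is computed on the masks rescaled to {0, 255}."""
    c = confusion(pred, truth)
    s = ssim((np.asarray(pred) > 0).astype(np.float64) * 255.0,
             (np.asarray(truth) > 0).astype(np.float64) * 255.0)
    return report(c, ssim_value=s)


CSV_COLUMNS = ["Image", "Specificity (%)", "Sensitivity (%)", "SSI (%)",
               "PPV (%)", "NPV (%)", "Accuracy (%)"]


def metrics_row(name: str, r: MetricReport) -> list:
    def pct(v):
        return f"{100.0 * v:.2f}"

    return [name, pct(r.specificity), pct(r.sensitivity),
            pct(r.ssim if r.ssim is not None else 0.0),
            pct(r.ppv), pct(r.npv), pct(r.accuracy)]


def write_metrics_csv(path, rows: list[list]) -> None:
    """Per-image metric rows in the standard six-column percentage layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        writer.writerows(rows)
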