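"""Segmentation metrics and histology-reference computations.

Dice and predictive values are computed per label over in-mask voxels;
the multi-class Dice is the unweighted mean over labels present in either
segmentation.  The TUNEL-like histology reference is thresholded on the
blue channel: below 0.78 is tumour, at or above is necrosis/apoptosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import LABELS, TUNEL_BLUE_THRESHOLD

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "predictive_values",
    "segment_tunel",
    "necrosis_fraction",
    "pearson_r",
    "unpaired_ttest",
]


@dataclass
class ConfusionCounts:
    """Per-label one-vs-rest confusion counts over in-mask voxels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def dice(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")


def confusion_counts(pred, ref, label: int, mask=None) -> ConfusionCounts:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("label maps must share a shape")
    if mask is None:
        mask = (pred > 0) | (ref > 0)
    p = pred[mask] == label
    r = ref[mask] == label
    return ConfusionCounts(
        tp=int(np.sum(p & r)), fp=int(np.sum(p & ~r)),
        tn=int(np.sum(~p & ~r)), fn=int(np.sum(~p & r)),
    )


def dice(pred, ref, labels=None, mask=None):
    """Per-label Dice coefficients and their multi-class mean.

    Labels absent from both maps are skipped.  Returns
    ``(per_label: dict, mean: float)``.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if labels is None:
        labels = sorted(set(np.unique(pred)) | set(np.unique(ref)) - {0})
        labels = [l for l in labels if l != 0]
    per_label = {}
    for l in labels:
        a = pred == l
        b = ref == l
        if mask is not None:
            a = a & mask
            b = b & mask
        na, nb = int(a.sum()), int(b.sum())
        if na + nb == 0:
            continue
        per_label[int(l)] = 2.0 * int((a & b).sum()) / (na + nb)
    mean = float(np.mean(list(per_label.values()))) if per_label else float("nan")
    return per_label, mean


def predictive_values(pred, ref, label: int, mask=None):
    """(PPV, NPV) of ``pred`` for one label against the reference; NaN when
    a denominator is empty."""
    c = confusion_counts(pred, ref, label, mask)
    return c.ppv, c.npv


def segment_tunel(rgb: np.ndarray, crop_mask: np.ndarray) -> np.ndarray:
    """Threshold a TUNEL-like RGB image (values in [0, 1]) inside the crop.

    Blue channel < 0.78 -> tumour; >= 0.78 -> necrosis/apoptosis; outside
    the crop mask -> 0.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB values must be scaled to [0, 1]")
    crop_mask = np.asarray(crop_mask, bool)
    blue = rgb[..., 2]
    out = np.zeros(blue.shape, dtype=np.int32)
    out[crop_mask & (blue < TUNEL_BLUE_THRESHOLD)] = LABELS["active_tumour"]
    out[crop_mask & (blue >= TUNEL_BLUE_THRESHOLD)] = LABELS["necrosis_apoptosis"]
    return out


def necrosis_fraction(labels: np.ndarray) -> float:
    """Necrosis/apoptosis voxels over tumour + necrosis/apoptosis voxels.

    Other labels (blood/edema, muscle, background) are excluded from the
    denominator; NaN when no tumour or necrosis voxels exist.
    """
    labels = np.asarray(labels)
    n_nec = int((labels == LABELS["necrosis_apoptosis"]).sum())
    n_tum = int((labels == LABELS["active_tumour"]).sum())
    if n_nec + n_tum == 0:
        return float("nan")
    return n_nec / (n_nec + n_tum)


def pearson_r(x, y):
    """Sample Pearson correlation and two-sided p-value; NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def unpaired_ttest(group_a, group_b, equal_var: bool = True):
    """Two-sample t statistic and two-sided p (Student by default, Welch
    with ``equal_var=False``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t.statistic), float(t.pvalue)
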