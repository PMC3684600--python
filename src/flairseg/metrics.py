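"""Agreement statistics between automatic and gold-standard segmentations.

Voxel-overlap measures (similarity index / Dice, overlap fraction, extra
fraction, Jaccard), lesion volume, the intraclass correlation coefficient
for absolute agreement, and the paired t test on lesion volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "SimilarityMetrics",
    "VolumePair",
    "ICCResult",
    "confusion_counts",
    "similarity_metrics",
    "lesion_volume",
    "icc_absolute_agreement",
    "paired_t_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts of an automatic mask against a gold mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SimilarityMetrics:
    si: float
    of: float
    ef: float
    jaccard: float


@dataclass(frozen=True)
class VolumePair:
    """Manual (gold) and automatic lesion volume for one patient/slice set."""

    manual: float
    auto: float


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


def confusion_counts(auto: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN voxel counts of ``auto`` against ``gold``."""
    auto = np.asarray(auto).astype(bool)
    gold = np.asarray(gold).astype(bool)
    if auto.shape != gold.shape:
        raise ValueError("masks must share a shape")
    tp = int(np.sum(auto & gold))
    fp = int(np.sum(auto & ~gold))
    fn = int(np.sum(~auto & gold))
    tn = int(np.sum(~auto & ~gold))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def similarity_metrics(counts: ConfusionCounts) -> SimilarityMetrics:
    """Similarity index, overlap fraction, extra fraction and Jaccard.

    ``SI = 2 TP / (2 TP + FP + FN)`` (Dice), ``OF = TP / (TP + FN)``
    (sensitivity against gold), ``EF = FP / (TP + FN)`` (false positives
    relative to the gold lesion size) and ``Jaccard = TP / (TP + FP + FN)``.
    A good segmentation has SI and OF near 1 and EF near 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        raise ValueError("SI/Jaccard undefined: both masks are empty")
    si = 2.0 * tp / (2.0 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn)
    if tp + fn == 0:
        raise ValueError("OF/EF undefined: gold mask is empty")
    of = tp / (tp + fn)
    ef = fp / (tp + fn)
    return SimilarityMetrics(si=si, of=of, ef=ef, jaccard=jaccard)


def lesion_volume(mask: np.ndarray, voxel_dims) -> float:
    """Mask volume in cm^3 given voxel dimensions (dx, dy, dz) in mm."""
    dims = tuple(float(v) for v in voxel_dims)
    if len(dims) != 3 or any(v <= 0 for v in dims):
        raise ValueError("voxel_dims must be three positive lengths in mm")
    return float(np.count_nonzero(mask)) * dims[0] * dims[1] * dims[2] / 1000.0


def _as_pair_array(pairs) -> np.ndarray:
    rows = []
    for p in pairs:
        if isinstance(p, VolumePair):
            rows.append((p.manual, p.auto))
        else:
            m, a = p
            rows.append((float(m), float(a)))
    return np.asarray(rows, dtype=float)


def icc_absolute_agreement(pairs, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measure.

    Computed from the standard mean-square decomposition (rows = subjects,
    columns = the two segmentation methods), with the McGraw–Wong
    confidence interval.  Zero total variance (all volumes identical) is
    degenerate and returns ICC 1 with a warning.
    """
    data = _as_pair_array(pairs)
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subject pairs")
    grand = data.mean()
    if np.allclose(data, grand):
        warnings.warn("zero total variance: ICC degenerate, returning 1", stacklevel=2)
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0)
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - confidence
    if mse <= 0:
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return ICCResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper))


def paired_t_test(pairs) -> tuple[float, float]:
    """Classical paired t test on manual-vs-automatic volume differences.

    Returns the t statistic and two-sided p value with n - 1 degrees of
    freedom.  Differences with zero variance are degenerate and raise.
    """
    data = _as_pair_array(pairs)
    if data.shape[0] < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    diffs = data[:, 0] - data[:, 1]
    if np.allclose(diffs, diffs[0]):
        raise ValueError("zero-variance differences: t statistic degenerate")
    t, p = stats.ttest_rel(data[:, 0], data[:, 1])
    return float(t), float(p)
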