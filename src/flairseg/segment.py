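"""Lesion, CSF and NABT segmentation from membership and enhanced images.

MS lesions: a primary mask is obtained by adaptive (Wellner-style)
thresholding of the contrast-enhanced image; candidate lesions are the
connected components of the bright-membership image above the BM threshold;
a candidate component is accepted if it overlaps the primary mask.

CSF: a primary mask is obtained by a localized weighted filter on the
dark-membership image (neighbourhood mean and centre value combined with
weights 0.9 and 0.6 over a 3x3 neighbourhood, unit step at T = mean + SD of
the nonzero dark memberships); candidate CSF regions are dark memberships
above the DM threshold, again accepted by overlap.

Remaining in-brain pixels are labelled normal-appearing brain tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label

from . import fuzzy
from .ga import GAConfig, run_ga
from .ssim import contrast_enhanced_image

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_NABT = 2
LABEL_LESION = 3

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_NABT",
    "LABEL_LESION",
    "SegmentationConfig",
    "SegmentationResult",
    "wellner_adaptive_threshold",
    "candidate_lesion_mask",
    "overlap_select",
    "segment_lesions",
    "localized_weighted_filter",
    "segment_csf",
    "segment_tissues",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and filter weights of the segmentation stage.

    ``bm`` (0.05) and ``dm`` (0.5) are the bright/dark membership candidate
    thresholds; ``w_neigh``, ``w_self`` and ``n_neigh`` (0.9, 0.6, 3) are
    the localized-weighted-filter parameters; the adaptive threshold uses a
    moving-average window of ``wellner_window_frac`` of the image width and
    a slack of ``wellner_t`` percent.
    """

    bm: float = 0.05
    dm: float = 0.5
    w_neigh: float = 0.9
    w_self: float = 0.6
    n_neigh: int = 3
    wellner_window_frac: float = 1.0 / 8.0
    wellner_t: float = 15.0
    connectivity: int = 8
    ssim_window: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.bm < 1 and 0 < self.dm < 1):
            raise ValueError("bm and dm must lie in (0, 1)")
        if self.n_neigh < 3 or self.n_neigh % 2 == 0:
            raise ValueError("n_neigh must be odd and >= 3")
        if self.w_neigh < 0 or self.w_self < 0:
            raise ValueError("filter weights must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class SegmentationResult:
    """Full output of :func:`segment_tissues`."""

    labels: np.ndarray
    lesion_mask: np.ndarray
    csf_mask: np.ndarray
    params: fuzzy.FuzzyParams
    entropy: float
    thresholds: tuple
    memberships: fuzzy.MembershipImages = field(repr=False)
    enhanced: np.ndarray = field(repr=False)


def wellner_adaptive_threshold(
    image: np.ndarray, window_frac: float = 1.0 / 8.0, t_pct: float = 15.0
) -> np.ndarray:
    """Adaptive thresholding against a local moving average.

    A pixel is foreground iff its value strictly exceeds the box mean of
    the surrounding window (width ``round(window_frac * image width)``)
    by more than ``t_pct`` percent of the image's dynamic range.  The slack
    is additive: a purely multiplicative margin would accept every pixel
    marginally above its local mean, flooding the mask with noise, whereas
    this rule leaves constant images entirely background and keeps only
    pixels that stand out from their surroundings by an appreciable
    fraction of the intensity scale.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    w = int(round(window_frac * image.shape[1]))
    if w < 1:
        raise ValueError("adaptive-threshold window is smaller than 1 px")
    local_mean = uniform_filter(image, size=w, mode="reflect")
    slack = (t_pct / 100.0) * float(image.max() - image.min())
    return image > local_mean + slack


def candidate_lesion_mask(bright: np.ndarray, bm: float = 0.05) -> np.ndarray:
    """All candidate lesion pixels: bright membership above ``bm``."""
    return np.asarray(bright, dtype=float) > bm


def overlap_select(
    candidates: np.ndarray, primary: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Keep candidate connected components that touch the primary mask."""
    candidates = np.asarray(candidates).astype(bool)
    primary = np.asarray(primary).astype(bool)
    if candidates.shape != primary.shape:
        raise ValueError("masks must share a shape")
    conn = 2 if connectivity == 8 else 1
    comp = cc_label(candidates, connectivity=conn)
    hit = np.unique(comp[candidates & primary])
    hit = hit[hit > 0]
    return np.isin(comp, hit)


def segment_lesions(
    enhanced: np.ndarray, bright: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """MS-lesion mask: membership candidates gated by the adaptive mask."""
    if cfg is None:
        cfg = SegmentationConfig()
    primary = wellner_adaptive_threshold(enhanced, cfg.wellner_window_frac, cfg.wellner_t)
    candidates = candidate_lesion_mask(bright, cfg.bm)
    return overlap_select(candidates, primary, cfg.connectivity)


def localized_weighted_filter(
    dark: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Primary CSF mask from the dark-membership image.

    ``score = w_neigh * (centre-excluded n x n neighbourhood mean)
    + w_self * dark``; pixels with ``score >= T`` pass, where ``T`` is the
    mean plus standard deviation of the nonzero dark memberships.  Isolated
    bright pixels score below T and are suppressed.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    dark = np.asarray(dark, dtype=float)
    nz = dark[dark > 0]
    if nz.size == 0:
        warnings.warn("dark membership image is identically zero", stacklevel=2)
        return np.zeros(dark.shape, dtype=bool)
    T = float(nz.mean() + nz.std())
    n = cfg.n_neigh
    neigh = (uniform_filter(dark, size=n, mode="reflect") * n * n - dark) / (n * n - 1)
    score = cfg.w_neigh * neigh + cfg.w_self * dark
    return score >= T


def segment_csf(dark: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """CSF mask: dark-membership candidates gated by the weighted filter."""
    if cfg is None:
        cfg = SegmentationConfig()
    primary = localized_weighted_filter(dark, cfg)
    candidates = np.asarray(dark, dtype=float) > cfg.dm
    return overlap_select(candidates, primary, cfg.connectivity)


def segment_tissues(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: SegmentationConfig | None = None,
    ga_cfg: GAConfig | None = None,
) -> SegmentationResult:
    """Fully automatic lesion/CSF/NABT segmentation of an extracted brain.

    Runs the whole pipeline: in-mask histogram, genetic-algorithm fit of the
    fuzzy membership knots, membership images, SSIM contrast enhancement,
    lesion selection, CSF selection.  Lesion labels take precedence over
    CSF, which takes precedence over NABT; out-of-mask pixels are labelled
    background.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    if ga_cfg is None:
        ga_cfg = GAConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty brain mask")

    hist = fuzzy.normalized_histogram(image, mask)
    fit = run_ga(hist, ga_cfg)
    table = fuzzy.memberships(fit.params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thresholds = fuzzy.crossing_thresholds(fit.params)
    images = fuzzy.membership_images(image, mask, table)

    enhanced = contrast_enhanced_image(
        image, images.bright, mask=mask, window=cfg.ssim_window
    )
    lesions = segment_lesions(enhanced, images.bright, cfg) & mask
    csf = segment_csf(images.dark, cfg) & mask

    labels = np.zeros(image.shape, dtype=np.uint8)
    labels[mask] = LABEL_NABT
    labels[csf] = LABEL_CSF
    labels[lesions] = LABEL_LESION
    return SegmentationResult(
        labels=labels,
        lesion_mask=labels == LABEL_LESION,
        csf_mask=labels == LABEL_CSF,
        params=fit.params,
        entropy=fit.entropy,
        thresholds=thresholds,
        memberships=images,
        enhanced=enhanced,
    )
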