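"""Synthetic FLAIR-like brain-slice phantoms with gold-standard labels.

The phantom emulates an axial FLAIR slice after brain extraction: an
elliptical brain of normal-appearing tissue (medium intensity), paired
ventricle-shaped CSF regions near the centre plus a thin peripheral CSF rim
(dark), and randomly placed elliptical lesions (bright) with a
periventricular placement bias.  Class mean intensities, additive Gaussian
noise, the total lesion-area fraction (small / moderate / large load), an
optional skull ring and an optional smooth multiplicative bias field are
configurable.  Gold labels are exact by construction and every phantom is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import ellipse as draw_ellipse

from .metrics import confusion_counts, similarity_metrics
from .segment import (
    LABEL_CSF,
    LABEL_LESION,
    LABEL_NABT,
    SegmentationConfig,
    overlap_select,
    wellner_adaptive_threshold,
)

LOAD_FRACTIONS = {"small": 0.002, "moderate": 0.01, "large": 0.03}
LOAD_COUNTS = {"small": 3, "moderate": 8, "large": 15}

__all__ = ["PhantomConfig", "PhantomSlice", "generate_phantom", "bm_sweep",
           "LOAD_FRACTIONS", "LOAD_COUNTS"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensities and noise of the synthetic slice.

    Intensity means follow the FLAIR ordering dark CSF (40) < NABT (110) <
    lesion (200) on the 0-255 scale; ``noise_sigma`` is the additive
    Gaussian SD in gray levels.  ``lesion_load`` maps to a total lesion-area
    fraction of the brain (0.2% / 1% / 3%) and a lesion count (3 / 8 / 15);
    both can be overridden explicitly.
    """

    size: int = 256
    csf_mean: float = 40.0
    nabt_mean: float = 110.0
    lesion_mean: float = 200.0
    noise_sigma: float = 5.0
    lesion_load: str = "moderate"
    lesion_fraction: float | None = None
    n_lesions: int | None = None
    periventricular_bias: float = 0.7
    skull_ring: bool = False
    skull_mean: float = 220.0
    bias_field: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.csf_mean < self.nabt_mean < self.lesion_mean):
            raise ValueError("class means must satisfy CSF < NABT < lesion")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.lesion_load not in LOAD_FRACTIONS:
            raise ValueError(f"lesion_load must be one of {sorted(LOAD_FRACTIONS)}")
        frac = self.fraction
        if not (0 < frac < 0.1):
            raise ValueError("lesion fraction must lie in (0, 0.1)")

    @property
    def fraction(self) -> float:
        return (
            self.lesion_fraction
            if self.lesion_fraction is not None
            else LOAD_FRACTIONS[self.lesion_load]
        )

    @property
    def count(self) -> int:
        return self.n_lesions if self.n_lesions is not None else LOAD_COUNTS[self.lesion_load]


@dataclass(frozen=True)
class PhantomSlice:
    """A generated phantom: image, exact gold labels and brain mask."""

    image: np.ndarray
    labels: np.ndarray
    brain_mask: np.ndarray
    config: PhantomConfig

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels == LABEL_LESION

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels == LABEL_CSF


def _ellipse_mask(shape, center, radii, rotation=0.0):
    rr, cc = draw_ellipse(
        center[0], center[1], radii[0], radii[1], shape=shape, rotation=rotation
    )
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def generate_phantom(cfg: PhantomConfig | None = None) -> PhantomSlice:
    """Generate one synthetic slice; see the module docstring.

    Raises a placement error if the configured lesion area cannot be placed
    without overlapping CSF or other lesions after bounded retries.
    """
    if cfg is None:
        cfg = PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    size = cfg.size
    shape = (size, size)
    cy = cx = size / 2.0

    brain = _ellipse_mask(shape, (cy, cx), (0.42 * size, 0.34 * size))

    # ventricles: two elongated ellipses flanking the midline
    vent = np.zeros(shape, dtype=bool)
    for sign in (-1, 1):
        vent |= _ellipse_mask(
            shape,
            (cy - 0.02 * size, cx + sign * 0.07 * size),
            (0.13 * size, 0.035 * size),
            rotation=sign * 0.15,
        )
    vent &= binary_erosion(brain, iterations=3)

    # thin peripheral CSF rim just inside the brain boundary
    rim = brain & ~binary_erosion(brain, iterations=2)
    csf = vent | rim

    labels = np.zeros(shape, dtype=np.uint8)
    labels[brain] = LABEL_NABT
    labels[csf] = LABEL_CSF

    # lesion placement: inside the brain, clear of CSF, periventricular bias
    interior = binary_erosion(brain, iterations=4) & ~binary_dilation(csf, iterations=2)
    near_vent = binary_dilation(vent, iterations=max(3, size // 16)) & interior
    target_total = cfg.fraction * brain.sum()
    shares = rng.uniform(0.5, 1.5, size=cfg.count)
    shares = shares / shares.sum() * target_total
    lesions = np.zeros(shape, dtype=bool)
    for area in shares:
        placed = False
        for _ in range(500):
            pool = near_vent if rng.random() < cfg.periventricular_bias else interior
            cand = np.argwhere(pool & ~binary_dilation(lesions, iterations=1))
            if len(cand) == 0:
                continue
            r0, c0 = cand[rng.integers(len(cand))]
            aspect = rng.uniform(0.6, 1.0)
            r1 = np.sqrt(area / (np.pi * aspect))
            blob = _ellipse_mask(
                shape, (r0, c0), (r1, aspect * r1), rotation=rng.uniform(0, np.pi)
            )
            ok = (
                blob.any()
                and not (blob & ~interior).any()
                and not (blob & binary_dilation(lesions, iterations=1)).any()
            )
            if ok:
                lesions |= blob
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place the configured lesion load")
    labels[lesions] = LABEL_LESION

    image = np.zeros(shape, dtype=float)
    image[labels == LABEL_NABT] = cfg.nabt_mean
    image[labels == LABEL_CSF] = cfg.csf_mean
    image[labels == LABEL_LESION] = cfg.lesion_mean
    if cfg.skull_ring:
        ring = _ellipse_mask(shape, (cy, cx), (0.47 * size, 0.39 * size)) & ~_ellipse_mask(
            shape, (cy, cx), (0.445 * size, 0.365 * size)
        )
        image[ring & ~brain] = cfg.skull_mean
    if cfg.bias_field > 0:
        yy, xx = np.mgrid[0:size, 0:size] / size
        theta = rng.uniform(0, 2 * np.pi)
        ramp = np.cos(theta) * (xx - 0.5) + np.sin(theta) * (yy - 0.5)
        image *= 1.0 + cfg.bias_field * ramp
    if cfg.noise_sigma > 0:
        image += rng.normal(0.0, cfg.noise_sigma, size=shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return PhantomSlice(image=image, labels=labels, brain_mask=brain, config=cfg)


def bm_sweep(
    phantoms,
    bm_values,
    cfg: SegmentationConfig | None = None,
    ga_cfg=None,
) -> tuple[pd.DataFrame, float]:
    """Mean lesion Jaccard against gold for each candidate BM threshold.

    The membership fit and contrast enhancement are computed once per
    phantom; only the candidate threshold and overlap selection are redone
    per BM value.  Returns the per-BM table and the argmax BM.
    """
    from . import fuzzy
    from .ga import GAConfig, run_ga
    from .ssim import contrast_enhanced_image

    if cfg is None:
        cfg = SegmentationConfig()
    if ga_cfg is None:
        ga_cfg = GAConfig()
    bm_values = [float(v) for v in bm_values]
    if len(phantoms) == 0:
        raise ValueError("need at least one phantom")
    if any(not (0 < v < 1) for v in bm_values):
        raise ValueError("BM values must lie in (0, 1)")

    scores = np.zeros((len(phantoms), len(bm_values)))
    for i, ph in enumerate(phantoms):
        hist = fuzzy.normalized_histogram(ph.image, ph.brain_mask)
        fit = run_ga(hist, ga_cfg)
        images = fuzzy.membership_images(
            ph.image, ph.brain_mask, fuzzy.memberships(fit.params)
        )
        enhanced = contrast_enhanced_image(
            ph.image, images.bright, mask=ph.brain_mask, window=cfg.ssim_window
        )
        primary = wellner_adaptive_threshold(
            enhanced, cfg.wellner_window_frac, cfg.wellner_t
        )
        for j, bm in enumerate(bm_values):
            auto = overlap_select(images.bright > bm, primary, cfg.connectivity)
            auto &= ph.brain_mask
            m = similarity_metrics(confusion_counts(auto, ph.lesion_mask))
            scores[i, j] = m.jaccard
    table = pd.DataFrame({"bm": bm_values, "mean_jaccard": scores.mean(axis=0)})
    best_bm = float(table.loc[table["mean_jaccard"].idxmax(), "bm"])
    return table, best_bm
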