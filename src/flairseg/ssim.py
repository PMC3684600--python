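"""Structural-similarity (SSIM) machinery and contrast enhancement.

The lesion contrast of a FLAIR slice is increased by computing, at every
pixel, the local SSIM between the slice and its bright-membership image.
Where a window of the slice is structurally similar to the corresponding
window of the lesion membership (i.e. over lesions), the map approaches its
unique maximum of 1; over normal tissue and CSF the luminance term drives
it towards 0, so lesions stand out sharply in the enhanced image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "SSIMConstants",
    "ssim_components",
    "ssim_index",
    "ssim_map",
    "contrast_enhanced_image",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilising constants and exponents of the SSIM index.

    ``C1 = (k1 L)^2`` and ``C2 = (k2 L)^2`` guard the luminance and contrast
    ratios against near-zero denominators; ``C3 = C2 / 2`` makes the
    contrast-structure product collapse to the familiar two-term SSIM map.
    ``L`` is the dynamic range of the signals (1 for images scaled to
    [0, 1]).
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.dynamic_range <= 0:
            raise ValueError("k1, k2 and dynamic_range must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("exponents must be non-negative")

    @property
    def C1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


def _global_stats(x: np.ndarray, y: np.ndarray):
    mu_x, mu_y = x.mean(), y.mean()
    sd_x, sd_y = x.std(), y.std()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return mu_x, mu_y, sd_x, sd_y, cov


def ssim_components(x, y, consts: SSIMConstants | None = None):
    """Luminance, contrast and structure comparison terms for two signals.

    ``l = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)``,
    ``c = (2 sd_x sd_y + C2) / (sd_x^2 + sd_y^2 + C2)``,
    ``s = (cov + C3) / (sd_x sd_y + C3)``.
    """
    if consts is None:
        consts = SSIMConstants()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("signals must have equal nonzero lengths")
    mu_x, mu_y, sd_x, sd_y, cov = _global_stats(x, y)
    l = (2 * mu_x * mu_y + consts.C1) / (mu_x**2 + mu_y**2 + consts.C1)
    c = (2 * sd_x * sd_y + consts.C2) / (sd_x**2 + sd_y**2 + consts.C2)
    s = (cov + consts.C3) / (sd_x * sd_y + consts.C3)
    return l, c, s


def ssim_index(x, y, consts: SSIMConstants | None = None) -> float:
    """SSIM index ``l^alpha * c^beta * s^gamma``; 1 iff the signals match."""
    if consts is None:
        consts = SSIMConstants()
    l, c, s = ssim_components(x, y, consts)
    return float(l**consts.alpha * c**consts.beta * s**consts.gamma)


def ssim_map(
    X: np.ndarray, Y: np.ndarray, window: int = 11, consts: SSIMConstants | None = None
) -> np.ndarray:
    """Local SSIM map over sliding ``window x window`` mean windows.

    Uses the two-term form ``[(2 mu_x mu_y + C1)(2 cov + C2)] /
    [(mu_x^2 + mu_y^2 + C1)(sd_x^2 + sd_y^2 + C2)]``, i.e. the luminance,
    contrast and structure product with ``C3 = C2 / 2`` and unit exponents.
    Plain (unweighted) windows with symmetric edge padding.  Values lie in
    [-1, 1] and equal 1 exactly where the two windows are identical.
    """
    if consts is None:
        consts = SSIMConstants()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("images must share a shape")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")

    def box(im):
        return uniform_filter(im, size=window, mode="reflect")

    mu_x, mu_y = box(X), box(Y)
    var_x = np.clip(box(X * X) - mu_x**2, 0.0, None)
    var_y = np.clip(box(Y * Y) - mu_y**2, 0.0, None)
    cov = box(X * Y) - mu_x * mu_y
    num = (2 * mu_x * mu_y + consts.C1) * (2 * cov + consts.C2)
    den = (mu_x**2 + mu_y**2 + consts.C1) * (var_x + var_y + consts.C2)
    return num / den


def contrast_enhanced_image(
    image: np.ndarray,
    bright: np.ndarray,
    mask: np.ndarray | None = None,
    window: int = 11,
    consts: SSIMConstants | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Contrast-enhanced image from a FLAIR slice and its bright membership.

    The slice is scaled to [0, 1] so both signals share dynamic range 1,
    then the local SSIM map against the bright-membership image is computed.
    With ``rescale`` the map is min-max rescaled to [0, 1] over the brain
    mask (adaptive thresholding downstream expects a non-negative image);
    otherwise the raw [-1, 1] map is returned.
    """
    image = np.asarray(image, dtype=float)
    if np.issubdtype(np.asarray(image).dtype, np.floating) and image.max() <= 1.0:
        X = image
    else:
        X = image / 255.0
    N = ssim_map(X, np.asarray(bright, dtype=float), window=window, consts=consts)
    if not rescale:
        return N
    if mask is None:
        mask = np.ones(N.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != N.shape:
            raise ValueError("mask shape must match image shape")
    inside = N[mask]
    lo, hi = inside.min(), inside.max()
    if hi <= lo:
        out = np.zeros_like(N)
    else:
        out = np.clip((N - lo) / (hi - lo), 0.0, 1.0)
    out[~mask] = 0.0
    return out
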