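"""Fuzzy three-class partition of a gray-level histogram.

A FLAIR brain slice is modelled as a mixture of three fuzzy intensity
classes: *dark* (CSF), *medium* (normal-appearing brain tissue, NABT) and
*bright* (MS lesions).  The dark class is described by a quadratic-spline
Z-shaped membership function over the 256 gray levels, the bright class by
the complementary S-shaped spline, and the medium class by the complement of
the two, so the three memberships sum to one at every gray level.  The six
spline knots ``a1 <= a2 <= a3 <= a4 <= a5 <= a6`` are the free parameters;
they are chosen by maximising the total fuzzy entropy of the partition (see
:mod:`flairseg.ga`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

N_LEVELS = 256
_LEVELS = np.arange(N_LEVELS, dtype=float)

__all__ = [
    "N_LEVELS",
    "Histogram",
    "FuzzyParams",
    "MembershipTable",
    "MembershipImages",
    "ClassEntropy",
    "normalized_histogram",
    "z_membership",
    "s_membership",
    "memberships",
    "total_fuzzy_entropy",
    "crossing_thresholds",
    "membership_images",
]


@dataclass(frozen=True)
class Histogram:
    """Normalised 256-bin gray-level histogram.

    Attributes
    ----------
    p : ndarray, shape (256,)
        Bin probabilities, non-negative and summing to one.
    n_pixels : int
        Number of pixels counted.
    """

    p: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_LEVELS,):
            raise ValueError(f"histogram must have {N_LEVELS} bins, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("histogram probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class FuzzyParams:
    """The six ordered membership knots (a1, ..., a6), each in [0, 255]."""

    a: tuple

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.a)
        if len(a) != 6:
            raise ValueError("FuzzyParams needs exactly six values")
        if any(v < 0 or v > 255 for v in a):
            raise ValueError("parameters must lie in [0, 255]")
        if any(a[i] > a[i + 1] for i in range(5)):
            raise ValueError(f"parameters must be ordered ascending, got {a}")
        object.__setattr__(self, "a", a)

    def __iter__(self):
        return iter(self.a)

    def __getitem__(self, i):
        return self.a[i]


@dataclass(frozen=True)
class MembershipTable:
    """Per-gray-level memberships of the three classes (each length 256)."""

    mu_d: np.ndarray
    mu_m: np.ndarray
    mu_b: np.ndarray


@dataclass(frozen=True)
class MembershipImages:
    """Per-pixel membership images; zero outside the brain mask."""

    dark: np.ndarray
    medium: np.ndarray
    bright: np.ndarray


@dataclass(frozen=True)
class ClassEntropy:
    """Per-class fuzzy entropies (nats) and class probabilities."""

    H_d: float
    H_m: float
    H_b: float
    H_total: float
    P_d: float
    P_m: float
    P_b: float


def normalized_histogram(image: np.ndarray, mask: np.ndarray | None = None) -> Histogram:
    """Histogram of the in-mask pixels of an 8-bit image.

    Parameters
    ----------
    image : ndarray
        2-D integer image with values in [0, 255].
    mask : ndarray of bool, optional
        Pixels to count; defaults to the whole image.  Must be non-empty.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if mask is None:
        values = image.ravel()
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        values = image[mask]
    if values.size == 0:
        raise ValueError("empty mask: cannot build a histogram")
    values = values.astype(np.int64)
    if values.min() < 0 or values.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    counts = np.bincount(values, minlength=N_LEVELS)
    return Histogram(p=counts / values.size, n_pixels=int(values.size))


def _z_curve(k, a, b, c):
    """Vectorised quadratic Z-spline; broadcasts (a, b, c) against ``k``."""
    k = np.asarray(k, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ca, ba, cb = c - a, b - a, c - b
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = 1.0 - (k - a) ** 2 / (ca * ba)
        lower = (k - c) ** 2 / (ca * cb)
    out = np.where(k <= a, 1.0, 0.0)
    out = np.where((k > a) & (k <= b) & (ba > 0), upper, out)
    out = np.where((k > b) & (k <= c) & (cb > 0), lower, out)
    return out


def z_membership(k, a: float, b: float, c: float):
    """Z-shaped (non-increasing) quadratic-spline membership.

    ``1`` for ``k <= a``, ``1 - (k-a)^2 / ((c-a)(b-a))`` for ``a < k <= b``,
    ``(k-c)^2 / ((c-a)(c-b))`` for ``b < k <= c`` and ``0`` beyond ``c``.
    When ``a == b == c`` the curve degenerates to a step at ``a``.
    """
    if not (a <= b <= c):
        raise ValueError(f"parameters must satisfy a <= b <= c, got ({a}, {b}, {c})")
    out = _z_curve(k, a, b, c)
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return float(out)
    return out


def s_membership(k, a: float, b: float, c: float):
    """S-shaped (non-decreasing) complement of :func:`z_membership`."""
    if not (a <= b <= c):
        raise ValueError(f"parameters must satisfy a <= b <= c, got ({a}, {b}, {c})")
    out = 1.0 - _z_curve(k, a, b, c)
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return float(out)
    return out


def memberships(params: FuzzyParams) -> MembershipTable:
    """Evaluate the three membership functions at all 256 gray levels.

    ``mu_d = Z(k; a1, a2, a3)``, ``mu_b = S(k; a4, a5, a6)`` and
    ``mu_m = 1 - mu_d - mu_b``; the ordering ``a3 <= a4`` guarantees that
    the two outer splines have disjoint support so ``mu_m >= 0``.
    """
    if not isinstance(params, FuzzyParams):
        params = FuzzyParams(tuple(params))
    a1, a2, a3, a4, a5, a6 = params.a
    mu_d = _z_curve(_LEVELS, a1, a2, a3)
    mu_b = 1.0 - _z_curve(_LEVELS, a4, a5, a6)
    mu_m = 1.0 - mu_d - mu_b
    return MembershipTable(mu_d=mu_d, mu_m=mu_m, mu_b=mu_b)


def _class_entropy(q: np.ndarray) -> tuple[float, float]:
    """Entropy and probability of one fuzzy class from q_k = p_k * mu_k."""
    P = float(q.sum())
    if P <= 0.0:
        return 0.0, 0.0
    t = q[q > 0] / P
    return float(-(t * np.log(t)).sum()), P


def total_fuzzy_entropy(hist: Histogram, params: FuzzyParams) -> ClassEntropy:
    """Total fuzzy entropy ``H_d + H_m + H_b`` of the partition.

    For each class ``c``, ``P_c = sum_k p_k mu_c(k)`` and
    ``H_c = -sum_k (p_k mu_c(k) / P_c) ln(p_k mu_c(k) / P_c)`` over terms
    with positive argument; ``P_c = 0`` yields ``H_c = 0``.
    """
    table = memberships(params)
    p = hist.p
    H_d, P_d = _class_entropy(p * table.mu_d)
    H_m, P_m = _class_entropy(p * np.clip(table.mu_m, 0.0, 1.0))
    H_b, P_b = _class_entropy(p * table.mu_b)
    return ClassEntropy(
        H_d=H_d, H_m=H_m, H_b=H_b, H_total=H_d + H_m + H_b,
        P_d=P_d, P_m=P_m, P_b=P_b,
    )


def _entropy_batch(p: np.ndarray, abc: np.ndarray) -> np.ndarray:
    """Total fuzzy entropy for many parameter vectors at once.

    Parameters
    ----------
    p : ndarray, shape (256,)
    abc : ndarray, shape (m, 6), each row ordered ascending.
    """
    abc = np.asarray(abc, dtype=float)
    mu_d = _z_curve(_LEVELS, abc[:, 0:1], abc[:, 1:2], abc[:, 2:3])
    mu_b = 1.0 - _z_curve(_LEVELS, abc[:, 3:4], abc[:, 4:5], abc[:, 5:6])
    mu_m = np.clip(1.0 - mu_d - mu_b, 0.0, 1.0)
    total = np.zeros(abc.shape[0])
    for mu in (mu_d, mu_m, mu_b):
        q = p * mu
        P = q.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = q / P[:, None]
            term = np.where(q > 0, t * np.log(t), 0.0)
        H = -np.nansum(term, axis=1)
        H[P <= 0] = 0.0
        total += H
    return total


def crossing_thresholds(params: FuzzyParams) -> tuple[int, int]:
    """Gray-level thresholds at the membership-curve crossings.

    ``T1`` is the smallest level where the medium membership reaches the dark
    one, ``T2`` the smallest level at or above ``T1`` where the bright
    membership reaches the medium one.  A three-level label image assigns
    ``k < T1`` to dark, ``T1 <= k < T2`` to medium and ``k >= T2`` to bright.
    Degenerate parameter vectors where a class never dominates are flagged
    with a warning and clamped thresholds are returned.
    """
    table = memberships(params)
    cross1 = np.nonzero(table.mu_m >= table.mu_d)[0]
    if cross1.size == 0:
        warnings.warn("medium membership never reaches the dark one", stacklevel=2)
        T1 = N_LEVELS - 1
    else:
        T1 = int(cross1[0])
    cross2 = np.nonzero((table.mu_b >= table.mu_m) & (_LEVELS >= T1))[0]
    if cross2.size == 0:
        warnings.warn("bright membership never reaches the medium one", stacklevel=2)
        T2 = N_LEVELS - 1
    else:
        T2 = int(cross2[0])
    return T1, T2


def membership_images(
    image: np.ndarray, mask: np.ndarray | None, table: MembershipTable
) -> MembershipImages:
    """Per-pixel membership lookup; out-of-mask pixels are 0 in all three."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    idx = image.astype(np.int64)
    if idx.min() < 0 or idx.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    dark = table.mu_d[idx]
    medium = table.mu_m[idx]
    bright = table.mu_b[idx]
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        dark = np.where(mask, dark, 0.0)
        medium = np.where(mask, medium, 0.0)
        bright = np.where(mask, bright, 0.0)
    return MembershipImages(dark=dark, medium=medium, bright=bright)
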