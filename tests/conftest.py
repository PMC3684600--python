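"""Shared fixtures and independent (naive) oracle implementations.

The oracles deliberately use plain Python loops and textbook formulas so
they stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from flairseg.fuzzy import Histogram


def naive_z(k, a, b, c):
    """Scalar quadratic Z-spline, straight from the piecewise definition."""
    if c == a:
        return 1.0 if k <= a else 0.0
    if k <= a:
        return 1.0
    if k <= b and b > a:
        return 1.0 - (k - a) ** 2 / ((c - a) * (b - a))
    if k <= c and c > b:
        return (k - c) ** 2 / ((c - a) * (c - b))
    return 0.0


def naive_memberships(params):
    a1, a2, a3, a4, a5, a6 = params
    mu_d = [naive_z(k, a1, a2, a3) for k in range(256)]
    mu_b = [1.0 - naive_z(k, a4, a5, a6) for k in range(256)]
    mu_m = [1.0 - d - b for d, b in zip(mu_d, mu_b)]
    return mu_d, mu_m, mu_b


def naive_total_fuzzy_entropy(p, params):
    """Direct per-term summation of the three class entropies."""
    total = 0.0
    for mu in naive_memberships(params):
        P = sum(p[k] * mu[k] for k in range(256))
        if P <= 0:
            continue
        H = 0.0
        for k in range(256):
            q = p[k] * mu[k]
            if q > 0:
                t = q / P
                H -= t * np.log(t)
        total += H
    return total


def naive_ssim_map(X, Y, window, C1, C2):
    """Per-window double-loop computation of the two-term SSIM map."""
    pad = window // 2
    Xp = np.pad(X, pad, mode="symmetric")
    Yp = np.pad(Y, pad, mode="symmetric")
    out = np.empty(X.shape)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            wx = Xp[i:i + window, j:j + window].ravel()
            wy = Yp[i:i + window, j:j + window].ravel()
            mx, my = wx.mean(), wy.mean()
            vx, vy = wx.var(), wy.var()
            cov = ((wx - mx) * (wy - my)).mean()
            out[i, j] = ((2 * mx * my + C1) * (2 * cov + C2)) / (
                (mx**2 + my**2 + C1) * (vx + vy + C2)
            )
    return out


def random_trimodal_histogram(rng, n=30000):
    """A well-separated three-mode gray-level histogram."""
    m1 = rng.uniform(20, 70)
    m2 = rng.uniform(m1 + 40, 170)
    m3 = rng.uniform(m2 + 40, 245)
    sds = rng.uniform(5, 15, 3)
    w = rng.dirichlet((3, 5, 2))
    x = np.concatenate(
        [rng.normal(m, s, int(n * wi)) for m, s, wi in zip((m1, m2, m3), sds, w)]
    )
    x = np.clip(np.round(x), 0, 255).astype(int)
    return Histogram(p=np.bincount(x, minlength=256) / x.size, n_pixels=x.size)


def random_legal_params(rng):
    return tuple(float(v) for v in np.sort(rng.uniform(0, 255, 6)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def moderate_phantom():
    from flairseg.phantom import PhantomConfig, generate_phantom

    return generate_phantom(PhantomConfig(noise_sigma=5.0, seed=0))


@pytest.fixture(scope="session")
def fitted_phantom(moderate_phantom):
    """A phantom together with its full pipeline segmentation result."""
    from flairseg.ga import GAConfig
    from flairseg.segment import segment_tissues

    res = segment_tissues(
        moderate_phantom.image, moderate_phantom.brain_mask, ga_cfg=GAConfig(seed=100)
    )
    return moderate_phantom, res
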