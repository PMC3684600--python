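"""Membership splines, fuzzy entropy, and threshold extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flairseg.fuzzy import (
    FuzzyParams,
    Histogram,
    crossing_thresholds,
    membership_images,
    memberships,
    normalized_histogram,
    s_membership,
    total_fuzzy_entropy,
    z_membership,
)

from conftest import naive_total_fuzzy_entropy, random_legal_params


class TestHistogram:
    def test_counts_two_levels(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        h = normalized_histogram(img)
        assert h.p[0] == 0.5 and h.p[255] == 0.5 and h.p[1:255].sum() == 0

    def test_constant_image(self):
        h = normalized_histogram(np.full((4, 4), 7, dtype=np.uint8))
        assert h.p[7] == 1.0

    def test_mask_restricts_counts(self):
        img = np.array([[10, 20], [30, 40]], dtype=np.uint8)
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        h = normalized_histogram(img, mask)
        assert h.n_pixels == 2 and h.p[10] == 0.5 and h.p[40] == 0.5

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            normalized_histogram(np.zeros((2, 2), dtype=np.uint8), np.zeros((2, 2), bool))

    def test_sums_to_one(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert normalized_histogram(img).p.sum() == pytest.approx(1.0, abs=1e-12)


class TestSplines:
    def test_plateaus(self):
        assert z_membership(9, 10, 50, 100) == 1.0
        assert z_membership(101, 10, 50, 100) == 0.0
        assert s_membership(9, 10, 50, 100) == 0.0
        assert s_membership(101, 10, 50, 100) == 1.0

    def test_midpoint_value(self):
        # 1 - 50^2 / (100 * 50) = 0.5
        assert z_membership(50, 0, 50, 100) == pytest.approx(0.5)
        assert s_membership(50, 0, 50, 100) == pytest.approx(0.5)

    def test_degenerate_step(self):
        assert z_membership(100, 100, 100, 100) == 1.0
        assert z_membership(101, 100, 100, 100) == 0.0

    def test_complement_identity(self, rng):
        a, b, c = np.sort(rng.uniform(0, 255, 3))
        k = np.arange(256)
        np.testing.assert_allclose(
            s_membership(k, a, b, c), 1.0 - z_membership(k, a, b, c), atol=1e-14
        )

    def test_unordered_raises(self):
        with pytest.raises(ValueError):
            z_membership(0, 50, 10, 100)


class TestMemberships:
    def test_interior_all_medium(self):
        t = memberships(FuzzyParams((0, 0, 0, 255, 255, 255)))
        assert np.all(t.mu_m[1:255] == 1.0)

    def test_plateau_regions(self):
        t = memberships(FuzzyParams((10, 20, 30, 200, 220, 240)))
        assert t.mu_d[5] == 1.0 and t.mu_b[250] == 1.0 and t.mu_m[100] == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 255), min_size=6, max_size=6))
    def test_sum_to_one(self, raw):
        t = memberships(FuzzyParams(tuple(sorted(raw))))
        np.testing.assert_allclose(t.mu_d + t.mu_m + t.mu_b, 1.0, atol=1e-12)

    def test_monotone_shapes(self, rng):
        t = memberships(FuzzyParams(random_legal_params(rng)))
        assert np.all(np.diff(t.mu_d) <= 1e-12)
        assert np.all(np.diff(t.mu_b) >= -1e-12)


class TestEntropy:
    def test_single_level_zero_entropy(self):
        p = np.zeros(256)
        p[40] = 1.0
        h = Histogram(p=p, n_pixels=100)
        e = total_fuzzy_entropy(h, FuzzyParams((100, 150, 200, 210, 220, 230)))
        assert e.H_total == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 256, 500)
            p = np.bincount(x, minlength=256) / x.size
            h = Histogram(p=p, n_pixels=x.size)
            params = FuzzyParams(random_legal_params(rng))
            got = total_fuzzy_entropy(h, params).H_total
            want = naive_total_fuzzy_entropy(p, params.a)
            assert got == pytest.approx(want, abs=1e-10)

    def test_four_point_histogram_against_oracle(self):
        p = np.zeros(256)
        p[[0, 85, 170, 255]] = 0.25
        h = Histogram(p=p, n_pixels=4)
        params = FuzzyParams((10, 40, 90, 120, 200, 250))
        got = total_fuzzy_entropy(h, params)
        want = naive_total_fuzzy_entropy(p, params.a)
        assert got.H_total == pytest.approx(want, abs=1e-10)
        assert got.P_d + got.P_m + got.P_b == pytest.approx(1.0, abs=1e-12)

    def test_depends_only_on_histogram(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        perm = rng.permutation(img.ravel()).reshape(img.shape)
        params = FuzzyParams(random_legal_params(rng))
        e1 = total_fuzzy_entropy(normalized_histogram(img), params).H_total
        e2 = total_fuzzy_entropy(normalized_histogram(perm), params).H_total
        assert e1 == pytest.approx(e2, abs=1e-14)


class TestCrossingThresholds:
    def test_between_plateaus(self):
        T1, T2 = crossing_thresholds(FuzzyParams((10, 20, 30, 200, 220, 240)))
        assert 10 < T1 < 30 and 200 < T2 < 240 and T1 <= T2

    def test_symmetric_spline_crosses_at_midpoint(self):
        # c - b == b - a makes the Z spline cross 0.5 exactly at b
        T1, _ = crossing_thresholds(FuzzyParams((40, 80, 120, 200, 220, 240)))
        assert T1 == 80

    def test_all_medium_crosses_immediately(self):
        with pytest.warns(UserWarning):
            T1, _ = crossing_thresholds(FuzzyParams((0, 0, 0, 255, 255, 255)))
        assert T1 == 1

    def test_monotone_under_shift(self, rng):
        base = np.sort(rng.uniform(0, 200, 6))
        t_base = crossing_thresholds(FuzzyParams(tuple(base)))
        for shift in (10, 30, 55):
            t_shift = crossing_thresholds(FuzzyParams(tuple(base + shift)))
            assert t_shift[0] >= t_base[0] and t_shift[1] >= t_base[1]


class TestMembershipImages:
    def test_lookup_and_masking(self):
        params = FuzzyParams((10, 20, 30, 200, 220, 240))
        t = memberships(params)
        img = np.array([[5, 100], [250, 0]], dtype=np.uint8)
        mask = np.array([[1, 1], [1, 0]], dtype=bool)
        out = membership_images(img, mask, t)
        assert out.dark[0, 0] == 1.0 and out.medium[0, 0] == 0.0
        assert out.medium[0, 1] == 1.0
        assert out.bright[1, 0] == 1.0
        # out-of-mask pixel is zero in all three images
        assert out.dark[1, 1] == out.medium[1, 1] == out.bright[1, 1] == 0.0
        total = out.dark + out.medium + out.bright
        np.testing.assert_allclose(total[mask], 1.0, atol=1e-12)

    def test_shape_mismatch_raises(self):
        t = memberships(FuzzyParams((10, 20, 30, 200, 220, 240)))
        with pytest.raises(ValueError):
            membership_images(np.zeros((2, 2), np.uint8), np.ones((3, 3), bool), t)
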