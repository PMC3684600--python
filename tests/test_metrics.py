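"""Overlap statistics, volumes, ICC and the paired t test."""

import numpy as np
import pytest

from flairseg.metrics import (
    ConfusionCounts,
    VolumePair,
    confusion_counts,
    icc_absolute_agreement,
    lesion_volume,
    paired_t_test,
    similarity_metrics,
)


class TestConfusionCounts:
    def test_perfect_match(self):
        m = np.zeros((10, 10), bool)
        m[:1, :5] = True
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 95)

    def test_partial_overlap(self):
        gold = np.zeros((5, 5), bool)
        gold[0, :5] = True
        auto = np.zeros((5, 5), bool)
        auto[0, :4] = True
        auto[1, 0] = True
        c = confusion_counts(auto, gold)
        assert (c.tp, c.fp, c.fn) == (4, 1, 1)

    def test_empty_auto(self):
        gold = np.ones((3, 3), bool)
        c = confusion_counts(np.zeros((3, 3), bool), gold)
        assert (c.tp, c.fp, c.fn) == (0, 0, 9)

    def test_total_preserved(self, rng):
        a = rng.uniform(0, 1, (12, 12)) > 0.5
        g = rng.uniform(0, 1, (12, 12)) > 0.5
        assert confusion_counts(a, g).total == a.size


class TestSimilarityMetrics:
    def test_hand_computed_values(self):
        m = similarity_metrics(ConfusionCounts(tp=4, fp=1, fn=1, tn=94))
        assert m.si == pytest.approx(0.8)
        assert m.of == pytest.approx(0.8)
        assert m.ef == pytest.approx(0.2)
        assert m.jaccard == pytest.approx(4 / 6)

    def test_perfect_segmentation(self):
        m = similarity_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=0))
        assert m.si == m.of == m.jaccard == 1.0 and m.ef == 0.0

    def test_dice_jaccard_identity(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 100, 3)
            m = similarity_metrics(ConfusionCounts(int(tp), int(fp), int(fn), 0))
            assert m.si == pytest.approx(2 * m.jaccard / (1 + m.jaccard), abs=1e-12)

    def test_empty_gold_raises(self):
        with pytest.raises(ValueError):
            similarity_metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=5))

    def test_agrees_with_set_arithmetic(self, rng):
        a = rng.uniform(0, 1, (16, 16)) > 0.5
        g = rng.uniform(0, 1, (16, 16)) > 0.4
        m = similarity_metrics(confusion_counts(a, g))
        inter = (a & g).sum()
        union = (a | g).sum()
        assert m.jaccard == pytest.approx(inter / union)
        assert m.si == pytest.approx(2 * inter / (a.sum() + g.sum()))


class TestLesionVolume:
    def test_unit_voxels(self):
        mask = np.zeros((40, 40), bool)
        mask.ravel()[:1000] = True
        assert lesion_volume(mask, (1, 1, 1)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert lesion_volume(np.zeros((4, 4), bool), (1, 1, 1)) == 0.0

    def test_linearity_in_slice_thickness(self, rng):
        mask = rng.uniform(0, 1, (20, 20)) > 0.5
        assert lesion_volume(mask, (1, 1, 4)) == pytest.approx(
            2 * lesion_volume(mask, (1, 1, 2))
        )

    def test_bad_dims_raise(self):
        with pytest.raises(ValueError):
            lesion_volume(np.ones((2, 2), bool), (1.0, -1.0, 1.0))


class TestICC:
    def test_perfect_agreement(self, rng):
        vols = rng.uniform(1, 20, 10)
        res = icc_absolute_agreement([VolumePair(v, v) for v in vols])
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_noise_dominated_agreement_is_low(self):
        rng = np.random.default_rng(42)
        subj = rng.normal(10, 1.0, 50)
        pairs = [
            VolumePair(s + rng.normal(0, 2.0), s + rng.normal(0, 2.0)) for s in subj
        ]
        assert icc_absolute_agreement(pairs).icc < 0.5

    @pytest.mark.parametrize("var_s,var_e", [(1.0, 0.25), (1.0, 1.0), (4.0, 1.0)])
    def test_recovers_analytic_icc(self, var_s, var_e):
        # two-way model without rater bias: ICC = var_s / (var_s + var_e)
        rng = np.random.default_rng(int(var_s * 10 + var_e * 100))
        subj = rng.normal(0, np.sqrt(var_s), 200)
        pairs = [
            (s + rng.normal(0, np.sqrt(var_e)), s + rng.normal(0, np.sqrt(var_e)))
            for s in subj
        ]
        got = icc_absolute_agreement(pairs).icc
        want = var_s / (var_s + var_e)
        assert got == pytest.approx(want, abs=0.08)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        subj = rng.normal(5, 2, 30)
        manual = subj + rng.normal(0, 1, 30)
        auto = subj + 0.5 + rng.normal(0, 1, 30)
        got = icc_absolute_agreement(list(zip(manual, auto)))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["m", "a"], 30),
            "score": np.column_stack([manual, auto]).ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ci_col = next(c for c in ref.columns if c.startswith("CI95"))
        ref2 = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert got.icc == pytest.approx(ref2["ICC"], abs=1e-9)
        assert got.ci_low == pytest.approx(ref2[ci_col][0], abs=0.01)
        assert got.ci_high == pytest.approx(ref2[ci_col][1], abs=0.01)

    def test_rater_swap_invariance(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.uniform(1, 10, (12, 2))]
        swapped = [(b, a) for a, b in pairs]
        assert icc_absolute_agreement(pairs).icc == pytest.approx(
            icc_absolute_agreement(swapped).icc, abs=1e-12
        )

    def test_degenerate_and_small_samples(self):
        with pytest.warns(UserWarning):
            res = icc_absolute_agreement([(3.0, 3.0)] * 5)
        assert res.icc == 1.0
        with pytest.raises(ValueError):
            icc_absolute_agreement([(1.0, 2.0), (2.0, 3.0)])


class TestPairedT:
    def test_zero_mean_differences(self):
        pairs = [(2.0, 1.0), (1.0, 2.0), (2.0, 1.0), (1.0, 2.0)]
        t, p = paired_t_test(pairs)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_constant_nonzero_differences_raise(self):
        with pytest.raises(ValueError):
            paired_t_test([(3.0, 1.0), (4.0, 2.0), (5.0, 3.0)])

    def test_location_equivariance_of_mean_difference(self, rng):
        base = rng.uniform(1, 10, (8, 2))
        shifted = base.copy()
        shifted[:, 1] += 1.5
        d0 = np.mean(base[:, 0] - base[:, 1])
        d1 = np.mean(shifted[:, 0] - shifted[:, 1])
        assert d1 == pytest.approx(d0 - 1.5)
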