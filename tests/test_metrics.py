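"""Metric suite: worked examples, algebraic identities and library cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.metrics import structural_similarity as sk_ssim
from skimage.metrics import peak_signal_noise_ratio as sk_psnr

from mpfnet import metrics
from mpfnet.metrics import SsimParams


@pytest.fixture
def pair(rng):
    return rng.random((32, 32)), rng.random((32, 32))


# ---------------------------------------------------------------------------
# accuracy / IoU / Dice on label maps
# ---------------------------------------------------------------------------

class TestLabelMetrics:
    def test_identity_prediction_is_perfect(self, rng):
        truth = rng.integers(0, 3, (16, 16))
        ay, oa = metrics.class_accuracy(truth, truth)
        assert oa == 1.0 and np.nanmin(ay) == 1.0
        iou, miou = metrics.mean_iou(truth, truth)
        assert miou == 1.0
        assert metrics.dice(truth > 0, truth > 0) == 1.0

    def test_complement_of_binary_truth_scores_zero(self, rng):
        truth = rng.integers(0, 2, (8, 8))
        _, oa = metrics.class_accuracy(1 - truth, truth)
        assert oa == 0.0

    def test_hand_counted_overall_accuracy(self):
        truth = np.zeros((4, 4), dtype=int)
        pred = truth.copy()
        pred.flat[[0, 5, 10, 15]] = 1       # 12 of 16 pixels agree
        _, oa = metrics.class_accuracy(pred, truth, num_classes=2)
        assert oa == 0.75

    def test_miou_matches_set_intersection_oracle(self, rng):
        pred = rng.integers(0, 3, (8, 8))
        truth = rng.integers(0, 3, (8, 8))
        iou, miou = metrics.mean_iou(pred, truth, num_classes=3)
        # independent oracle: per-class pixel-set intersection / union
        expected = []
        for c in range(3):
            p, t = set(zip(*np.where(pred == c))), set(zip(*np.where(truth == c)))
            if p or t:
                expected.append(len(p & t) / len(p | t))
        assert np.allclose(np.array(expected), iou[~np.isnan(iou)])
        assert miou == pytest.approx(np.mean(expected))

    def test_absent_class_excluded_from_mean(self):
        pred = np.zeros((4, 4), dtype=int)
        truth = np.zeros((4, 4), dtype=int)
        iou, miou = metrics.mean_iou(pred, truth, num_classes=3)
        assert np.isnan(iou[1]) and np.isnan(iou[2]) and miou == 1.0

    def test_dice_counting_oracle(self):
        truth = np.zeros((20, 20), dtype=bool)
        pred = np.zeros((20, 20), dtype=bool)
        truth.flat[:100] = True
        pred.flat[40:120] = True            # |T|=100, |P|=80, |T∩P|=60
        assert metrics.dice(pred, truth) == pytest.approx(2 * 60 / 180)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool); a[0, 0] = True
        b = np.zeros((4, 4), dtype=bool); b[3, 3] = True
        assert metrics.dice(a, b) == 0.0
        iou, _ = metrics.mean_iou(a.astype(int), b.astype(int), num_classes=2)
        assert iou[1] == 0.0

    def test_empty_masks_agree_vacuously(self):
        z = np.zeros((4, 4), dtype=bool)
        assert metrics.dice(z, z) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_dice_iou_identity_on_random_masks(self, seed):
        """Dice = 2·IoU/(1+IoU), the exact algebraic relation for binary masks."""
        r = np.random.default_rng(seed)
        a, b = r.integers(0, 2, (12, 12)), r.integers(0, 2, (12, 12))
        if not (a.any() or b.any()):
            return
        iou, _ = metrics.mean_iou(a, b, num_classes=2)
        fg_iou = iou[1]
        if np.isnan(fg_iou):
            return
        assert metrics.dice(a, b) == pytest.approx(2 * fg_iou / (1 + fg_iou),
                                                   abs=1e-12)


# ---------------------------------------------------------------------------
# intensity metrics
# ---------------------------------------------------------------------------

class TestIntensityMetrics:
    def test_pearson_affine_invariance(self, pair):
        a, _ = pair
        assert metrics.pearson_cc(a, a) == pytest.approx(1.0)
        assert metrics.pearson_cc(2 * a + 5, a) == pytest.approx(1.0)
        assert metrics.pearson_cc(-a + 3, a) == pytest.approx(-1.0)

    def test_pearson_matches_direct_summation(self, rng):
        p, y = rng.random((16, 16)), rng.random((16, 16))
        pf, yf = p.ravel(), y.ravel()
        num = ((pf - pf.mean()) * (yf - yf.mean())).sum()
        den = np.sqrt(((pf - pf.mean()) ** 2).sum() * ((yf - yf.mean()) ** 2).sum())
        assert metrics.pearson_cc(p, y) == pytest.approx(num / den, abs=1e-12)

    def test_pearson_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            metrics.pearson_cc(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    def test_nrmse_closed_form_on_checkerboard(self):
        truth = np.indices((8, 8)).sum(axis=0) % 2  # 0/1 checkerboard
        pred = truth + 0.5
        mse, rmse, nr = metrics.nrmse(pred, truth)
        assert (mse, rmse, nr) == (0.25, 0.5, 0.5)

    def test_nrmse_scale_invariance(self, pair):
        a, b = pair
        _, _, n1 = metrics.nrmse(a, b)
        _, _, n2 = metrics.nrmse(7.3 * a, 7.3 * b)
        assert n1 == pytest.approx(n2)

    def test_nrmse_constant_reference_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            metrics.nrmse(rng.random((4, 4)), np.full((4, 4), 2.0))

    def test_psnr_values(self, rng):
        t = rng.random((8, 8))
        assert metrics.psnr(t, t, 1.0) == np.inf
        # MSE == v_max^2 -> 0 dB
        assert metrics.psnr(np.zeros((4, 4)), np.full((4, 4), 3.0), 3.0) == \
            pytest.approx(0.0)
        # arithmetic check: 255^2 / 65.025 = 1000 -> 30 dB
        pred = t.copy()
        pred.flat[0] += np.sqrt(65.025 * t.size)
        assert metrics.psnr(pred, t, 255.0) == pytest.approx(30.0)

    def test_psnr_matches_skimage(self, pair):
        a, b = pair
        assert metrics.psnr(a, b, 1.0) == pytest.approx(
            sk_psnr(b, a, data_range=1.0))

    def test_psnr_halving_mse_raises_3db(self, pair):
        a, b = pair
        d1 = metrics.psnr(b + (a - b), b, 1.0)
        d2 = metrics.psnr(b + (a - b) / np.sqrt(2), b, 1.0)
        assert d2 - d1 == pytest.approx(10 * np.log10(2))


class TestSsim:
    def test_identity(self, rng):
        a = rng.random((16, 16))
        assert metrics.ssim(a, a) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        a, b = 0.3, 0.7
        params = SsimParams(window=5, data_range=1.0)
        got = metrics.ssim(np.full((8, 8), a), np.full((8, 8), b), params)
        lum = (2 * a * b + params.c1) / (a * a + b * b + params.c1)
        assert got == pytest.approx(lum)   # contrast/structure = 1 in the limit
        assert got < 1.0

    def test_bounded(self, rng):
        for _ in range(10):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            assert -1.0 <= metrics.ssim(a, b, SsimParams(window=7)) <= 1.0

    def test_matches_skimage_reference(self, pair):
        a, b = pair
        mine = metrics.ssim(a, b, SsimParams(window=11, data_range=1.0))
        ref = sk_ssim(a, b, win_size=11, data_range=1.0, gaussian_weights=False)
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="window"):
            metrics.ssim(np.zeros((4, 4)), np.zeros((4, 4)), SsimParams(window=11))

    def test_exponents_reweight_components(self, pair):
        a, b = pair
        default = metrics.ssim(a, b)
        damped = metrics.ssim(a, b, SsimParams(p=0.0))  # drop structure term
        assert damped != pytest.approx(default)


class TestBinarize:
    def test_binary_image_unchanged(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        assert np.array_equal(metrics.binarize(img.astype(float)), img)

    def test_ramp_threshold_half(self):
        ramp = np.linspace(0, 1, 10)[None].repeat(4, axis=0)
        mask = metrics.binarize(ramp, threshold=0.5)
        assert np.array_equal(mask[0], (np.linspace(0, 1, 10) >= 0.5))

    def test_constant_image_warns_all_background(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = metrics.binarize(np.full((4, 4), 3.0))
        assert not mask.any()

    def test_otsu_matches_brute_force(self, rng):
        yy, xx = np.mgrid[0:32, 0:32]
        img = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 40.0) \
            + 0.05 * rng.random((32, 32))
        # 8-bit quantised blob so the exhaustive search and the histogram
        # method optimise over the same candidate set
        img = np.round((img - img.min()) / (img.max() - img.min()) * 255) / 255
        norm = img
        # exhaustive search over candidate thresholds for max between-class variance
        cands = np.unique(norm)[:-1]
        best_t, best_v = None, -1.0
        for t in cands:
            fg = norm > t
            w1, w0 = fg.mean(), 1 - fg.mean()
            if w1 in (0.0, 1.0):
                continue
            v = w0 * w1 * (norm[fg].mean() - norm[~fg].mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert np.array_equal(metrics.binarize(img, method="otsu"), norm > best_t)


# ---------------------------------------------------------------------------
# comparative statistics and report assembly
# ---------------------------------------------------------------------------

class TestRelativeChange:
    @pytest.mark.parametrize("a,b,direction,expected", [
        (0.879, 0.716, "higher_is_better", 22.77),
        (0.192, 0.201, "lower_is_better", 4.48),
        (0.5, 0.5, "higher_is_better", 0.0),
    ])
    def test_examples(self, a, b, direction, expected):
        assert metrics.relative_change(a, b, direction) == expected

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            metrics.relative_change(1.0, 0.0)


class TestReport:
    def test_perfect_prediction_row(self, rng):
        y = rng.random((1, 3, 32, 32))
        rep = metrics.build_report(y, y)
        assert np.allclose(rep["nrmse"], 0.0)
        for col in ("ssim", "pcc", "dice", "miou"):
            assert np.allclose(rep[col], 1.0)
        assert (rep["n_images"] == 1).all()

    def test_report_composes_single_pair_metrics(self, rng):
        preds = rng.random((3, 3, 32, 32))
        truths = rng.random((3, 3, 32, 32))
        rep = metrics.build_report(preds, truths)
        for k, organelle in enumerate(metrics.ORGANELLES):
            per = [metrics.evaluate_pair(preds[i, k], truths[i, k])
                   for i in range(3)]
            row = rep[rep.organelle == organelle].iloc[0]
            for key in ("nrmse", "ssim", "pcc", "dice", "miou"):
                assert row[key] == pytest.approx(np.mean([d[key] for d in per]))

    def test_replicated_image_has_zero_std(self, rng):
        one = rng.random((1, 3, 32, 32))
        preds = np.repeat(one, 4, axis=0)
        truths = np.repeat(rng.random((1, 3, 32, 32)), 4, axis=0)
        rep = metrics.build_report(preds, truths)
        assert np.allclose(rep[[c for c in rep.columns if c.endswith("_std")]], 0.0)

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            metrics.build_report(np.empty((0, 3, 8, 8)), np.empty((0, 3, 8, 8)))


class TestSymmetry:
    """Swapping prediction and truth leaves symmetric metrics unchanged."""

    def test_swap_invariance(self, pair):
        a, b = pair
        assert metrics.pearson_cc(a, b) == pytest.approx(metrics.pearson_cc(b, a))
        assert metrics.ssim(a, b) == pytest.approx(metrics.ssim(b, a))
        assert metrics.nrmse(a, b)[0] == pytest.approx(metrics.nrmse(b, a)[0])
        ma, mb = metrics.binarize(a), metrics.binarize(b)
        assert metrics.dice(ma, mb) == metrics.dice(mb, ma)
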