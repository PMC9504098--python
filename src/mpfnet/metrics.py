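"""Image-quality and segmentation metrics for label-free prediction.

Implements the evaluation suite used to score predicted organelle
fluorescence against ground truth: per-class/overall pixel accuracy,
mean intersection-over-union, Pearson correlation, MSE/RMSE/NRMSE, PSNR,
SSIM (with configurable exponents on the luminance/contrast/structure
components), and the Sørensen–Dice coefficient, plus the relative-change
statistic used to compare models and a report builder that mirrors the
per-organelle benchmark tables.

Continuous metrics (NRMSE, SSIM, PCC) operate on the raw intensity
images; overlap metrics (Dice, mIoU) operate on masks produced by
:func:`binarize`, since the regression outputs are continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu

ORGANELLES = ("nucleus", "endoplasmic_reticulum", "mitochondria")

__all__ = [
    "SsimParams", "class_accuracy", "mean_iou", "pearson_cc", "nrmse",
    "psnr", "ssim", "dice", "binarize", "relative_change", "build_report",
    "evaluate_pair", "ORGANELLES",
]


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# label-map metrics
# ---------------------------------------------------------------------------

def class_accuracy(pred: np.ndarray, truth: np.ndarray,
                   num_classes: int | None = None):
    """Per-class accuracy AY_i and overall accuracy OA.

    AY_i = correctly predicted pixels of class i / truth pixels of class i;
    OA = total correct / total pixels.  A class with no truth pixels has an
    undefined AY and is reported as NaN (excluded from any averaging).

    Returns ``(ay, oa)`` with ``ay`` an array of length ``num_classes``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_shape(pred, truth)
    if num_classes is None:
        num_classes = int(max(pred.max(initial=0), truth.max(initial=0))) + 1
    ay = np.full(num_classes, np.nan)
    correct = pred == truth
    for i in range(num_classes):
        support = truth == i
        n = support.sum()
        if n:
            ay[i] = correct[support].sum() / n
    oa = correct.mean()
    return ay, float(oa)


def _confusion(pred: np.ndarray, truth: np.ndarray, k: int) -> np.ndarray:
    idx = truth.astype(np.int64).ravel() * k + pred.astype(np.int64).ravel()
    return np.bincount(idx, minlength=k * k).reshape(k, k)


def mean_iou(pred: np.ndarray, truth: np.ndarray,
             num_classes: int | None = None):
    """Per-class IoU and its mean over classes.

    IoU_i = TP_i / (TP_i + FP_i + FN_i).  A class absent from both images
    has an undefined IoU (0/0); it is reported as NaN and excluded from
    the mean rather than scored zero.

    Returns ``(iou, miou)``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_shape(pred, truth)
    if num_classes is None:
        num_classes = int(max(pred.max(initial=0), truth.max(initial=0))) + 1
    cm = _confusion(pred, truth, num_classes)
    tp = np.diag(cm).astype(float)
    union = cm.sum(axis=0) + cm.sum(axis=1) - np.diag(cm)
    with np.errstate(invalid="ignore"):
        iou = np.where(union > 0, tp / np.maximum(union, 1), np.nan)
    return iou, float(np.nanmean(iou))


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2|T∩P| / (|T| + |P|) for binary masks.

    Two empty masks agree vacuously and score 1.
    """
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(truth_mask).astype(bool)
    _check_same_shape(p, t)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


# ---------------------------------------------------------------------------
# intensity metrics
# ---------------------------------------------------------------------------

def pearson_cc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between the flattened pixel values."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    t = np.asarray(truth, dtype=np.float64).ravel()
    _check_same_shape(np.asarray(pred), np.asarray(truth))
    if p.size < 2:
        raise ValueError("need at least 2 pixels for a correlation")
    pc = p - p.mean()
    tc = t - t.mean()
    denom = np.sqrt((pc * pc).sum() * (tc * tc).sum())
    if denom == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float((pc * tc).sum() / denom)


def nrmse(pred: np.ndarray, truth: np.ndarray):
    """(MSE, RMSE, NRMSE) with NRMSE = RMSE / (max(truth) − min(truth)).

    The error is normalised by the dynamic range of the reference image,
    which makes it invariant to a joint positive rescaling of both images.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    _check_same_shape(p, t)
    mse = float(np.mean((p - t) ** 2))
    rmse = float(np.sqrt(mse))
    rng = float(t.max() - t.min())
    if rng == 0:
        raise ValueError("constant reference image: NRMSE normalisation undefined")
    return mse, rmse, rmse / rng


def psnr(pred: np.ndarray, truth: np.ndarray, v_max: float) -> float:
    """Peak signal-to-noise ratio 10·log10(v_max² / MSE), in dB."""
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    _check_same_shape(p, t)
    mse = np.mean((p - t) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(v_max ** 2 / mse))


@dataclass
class SsimParams:
    """Window size, stabilisation constants and component exponents for SSIM.

    ``c1 = (k1·L)²``, ``c2 = (k2·L)²``, ``c3 = c2/2`` with the standard
    k1 = 0.01, k2 = 0.03 and L the declared dynamic range.  The exponents
    weight luminance^m · contrast^n · structure^p; the default (1, 1, 1)
    collapses to the familiar two-factor SSIM formula.
    """

    window: int = 11
    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    m: float = 1.0
    n: float = 1.0
    p: float = 1.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def ssim(pred: np.ndarray, truth: np.ndarray,
         params: SsimParams | None = None) -> float:
    """Mean structural similarity over local square windows.

    Local means/variances/covariance use a uniform window with sample
    (n−1) normalisation; the map of luminance^m · contrast^n · structure^p
    is averaged over the interior where the window fully fits.  With the
    default exponents this matches the conventional SSIM index.
    """
    if params is None:
        params = SsimParams()
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    _check_same_shape(x, y)
    win = params.window
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} window")

    filt = lambda a: uniform_filter(a, size=win)
    npix = win ** 2
    cov_norm = npix / (npix - 1.0)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)

    c1, c2, c3 = params.c1, params.c2, params.c3
    lum = (2 * ux * uy + c1) / (ux ** 2 + uy ** 2 + c1)
    sx = np.sqrt(np.maximum(vx, 0.0))
    sy = np.sqrt(np.maximum(vy, 0.0))
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    struct = (vxy + c3) / (sx * sy + c3)
    if params.m == params.n == params.p == 1.0:
        smap = lum * con * struct
    else:
        smap = (np.sign(lum) * np.abs(lum) ** params.m
                * np.sign(con) * np.abs(con) ** params.n
                * np.sign(struct) * np.abs(struct) ** params.p)
    pad = (win - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# plumbing: discretisation and comparative statistics
# ---------------------------------------------------------------------------

def binarize(image: np.ndarray, threshold: float = 0.5,
             method: str = "fixed") -> np.ndarray:
    """Foreground mask from a continuous image.

    ``fixed``: min-max normalise, then threshold (default 0.5).
    ``otsu``: Otsu's between-class-variance maximising threshold.
    A constant image yields an all-background mask with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: returning all-background mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    norm = (img - lo) / (hi - lo)
    if method == "fixed":
        return (norm >= threshold).astype(np.uint8)
    if method == "otsu":
        return (norm > threshold_otsu(norm)).astype(np.uint8)
    raise ValueError(f"unknown binarisation method {method!r}")


def relative_change(a: float, b: float, direction: str = "higher_is_better") -> float:
    """Percent improvement of score ``a`` over reference ``b``.

    ``higher_is_better``: 100·(a−b)/b.  ``lower_is_better`` (error-type
    metrics such as NRMSE): 100·(b−a)/b.  Rounded to 2 decimals, the
    convention used when quoting model-vs-model improvements.
    """
    if b == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    if direction == "higher_is_better":
        pct = 100.0 * (a - b) / b
    elif direction == "lower_is_better":
        pct = 100.0 * (b - a) / b
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return round(pct, 2)


METRIC_DIRECTIONS = {
    "nrmse": "lower_is_better",
    "ssim": "higher_is_better",
    "pcc": "higher_is_better",
    "dice": "higher_is_better",
    "miou": "higher_is_better",
}


def evaluate_pair(pred: np.ndarray, truth: np.ndarray,
                  ssim_params: SsimParams | None = None,
                  threshold: float = 0.5) -> dict[str, float]:
    """All five report metrics for one predicted/true channel pair."""
    _, _, nr = nrmse(pred, truth)
    pm = binarize(pred, threshold)
    tm = binarize(truth, threshold)
    _, miou = mean_iou(pm, tm, num_classes=2)
    return {
        "nrmse": nr,
        "ssim": ssim(pred, truth, ssim_params),
        "pcc": pearson_cc(pred, truth),
        "dice": dice(pm, tm),
        "miou": miou,
    }


def build_report(preds: np.ndarray, truths: np.ndarray,
                 model: str = "model",
                 organelles: tuple[str, ...] = ORGANELLES,
                 ssim_params: SsimParams | None = None,
                 threshold: float = 0.5) -> pd.DataFrame:
    """Per-organelle metric means ± std over a test set.

    ``preds`` and ``truths`` are (n_images, K, H, W) stacks with matching
    shapes; rows mirror the benchmark-table layout: one row per organelle
    with columns nrmse/ssim/pcc/dice/miou plus their stds and n_images.
    """
    preds = np.asarray(preds, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if preds.ndim == 3:
        preds, truths = preds[None], truths[None]
    _check_same_shape(preds, truths)
    if preds.shape[0] == 0:
        raise ValueError("empty test set")
    if preds.shape[1] != len(organelles):
        raise ValueError("channel count does not match organelle names")
    rows = []
    for k, organelle in enumerate(organelles):
        per_image = [evaluate_pair(preds[i, k], truths[i, k], ssim_params, threshold)
                     for i in range(preds.shape[0])]
        row = {"model": model, "organelle": organelle}
        for key in ("nrmse", "ssim", "pcc", "dice", "miou"):
            vals = np.array([d[key] for d in per_image])
            row[key] = float(vals.mean())
            row[key + "_std"] = float(vals.std())
        row["n_images"] = preds.shape[0]
        rows.append(row)
    return pd.DataFrame(rows)
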