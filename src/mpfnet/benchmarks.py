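"""Published per-organelle benchmark means for the A549 SRS evaluation.

Reported test-set metric means (NRMSE↓, SSIM↑, PCC↑, Dice↑, mIoU↑) for
the MPFnet, UwUnet and plain U-Net predictors on the original lung-cancer
(A549) stimulated-Raman-scattering dataset, which is available only on
request.  They serve as fixed inputs to the model-comparison statistics
(:func:`mpfnet.train_eval.compare`), not as anything this package
recomputes: the dataset needed to recompute them is not public.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # model, organelle, nrmse, ssim, pcc, dice, miou
    ("MPFnet", "nucleus", 0.192, 0.913, 0.908, 0.935, 0.879),
    ("MPFnet", "endoplasmic_reticulum", 0.187, 0.886, 0.911, 0.936, 0.881),
    ("MPFnet", "mitochondria", 0.206, 0.915, 0.903, 0.933, 0.876),
    ("UwUnet", "nucleus", 0.201, 0.892, 0.892, 0.919, 0.852),
    ("UwUnet", "endoplasmic_reticulum", 0.225, 0.857, 0.903, 0.925, 0.861),
    ("UwUnet", "mitochondria", 0.217, 0.886, 0.880, 0.921, 0.854),
    ("Unet", "nucleus", 0.442, 0.757, 0.843, 0.855, 0.716),
    ("Unet", "endoplasmic_reticulum", 0.454, 0.761, 0.856, 0.873, 0.771),
    ("Unet", "mitochondria", 0.511, 0.760, 0.835, 0.843, 0.731),
]


def published_benchmarks() -> pd.DataFrame:
    """The published benchmark means as a tidy report-style DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["model", "organelle", "nrmse", "ssim", "pcc", "dice", "miou"]
    )
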