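"""Synthetic paired hyperspectral / fluorescence data generator.

Emulates the statistical structure of paired SRS–fluorescence acquisitions:
each scene contains a few cells with three organelle compartments —
nucleus (filled ellipse), mitochondria (puncta and short rods outside the
nucleus), endoplasmic reticulum (a reticulated random-walk network seeded
at the nuclear envelope).  The three fluorescence channels are blurred,
[0,1]-normalised renderings of those supports.  The C-channel "vibrational"
input stack is a nonnegative linear mixture of the three organelle images
through a C×3 spectral-signature matrix (overlapping Gaussian profiles by
default, so no input channel is a clean copy of any one organelle), plus
background and Poisson/Gaussian noise.

The forward model is deliberately linear-mixing-plus-noise: SRS signal is
approximately linear in molecular concentration, and spectral overlap
between molecular species is exactly what makes the unmixing task hard.
Everything is driven by explicit seeds; a dataset is reproducible
bit-for-bit from (config, master seed).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter, binary_dilation
from skimage.draw import ellipse, disk
from skimage.io import imsave

__all__ = [
    "SceneConfig", "PairedSample", "default_mixing_matrix", "render_scene",
    "mix_to_input", "make_pair", "generate_pairs", "make_dataset",
    "load_dataset",
]


def default_mixing_matrix(n_channels: int = 10) -> np.ndarray:
    """Overlapping Gaussian spectral signatures, one column per organelle.

    Peaks sit at 30%, 55% and 80% of the channel axis with a width of
    18% of the axis, giving substantial cross-talk between neighbouring
    organelle signatures — the spectral-overlap regime the network is
    meant to disentangle.
    """
    c = np.arange(n_channels, dtype=np.float64)
    centers = np.array([0.30, 0.55, 0.80]) * (n_channels - 1)
    width = 0.18 * n_channels
    M = np.exp(-0.5 * ((c[:, None] - centers[None, :]) / width) ** 2)
    return M


@dataclass
class SceneConfig:
    """Geometry, spectra and noise of one synthetic acquisition setup.

    Image size defaults to 128 for desk-scale work; the acquisition-scale
    setting is 512.  ``n_channels`` defaults to the ten vibrational
    transitions of the emulated instrument.
    """

    image_size: int = 128
    n_channels: int = 10
    n_cells: int = 3
    nucleus_radius: tuple[float, float] = (0.08, 0.14)   # fractions of image size
    mito_puncta_per_cell: tuple[int, int] = (8, 16)
    mito_radius_px: tuple[int, int] = (1, 3)
    er_walks_per_cell: int = 6
    er_steps: int = 60
    er_width_px: int = 1
    blur_sigma: float = 1.0
    mixing_matrix: np.ndarray | None = None
    background: float = 0.02
    gaussian_sigma: float = 0.01
    poisson_gain: float = 200.0     # photons per unit intensity; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_channels < 3:
            raise ValueError("need at least 3 input channels")
        if self.mixing_matrix is None:
            self.mixing_matrix = default_mixing_matrix(self.n_channels)
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=np.float64)
        if self.mixing_matrix.shape != (self.n_channels, 3):
            raise ValueError("mixing_matrix must have shape (n_channels, 3)")
        if (self.mixing_matrix < 0).any():
            raise ValueError("mixing_matrix must be nonnegative")
        if not (self.mixing_matrix.sum(axis=0) > 0).all():
            raise ValueError("every organelle column must be nonzero")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixing_matrix"] = self.mixing_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if d.get("mixing_matrix") is not None:
            d["mixing_matrix"] = np.asarray(d["mixing_matrix"], dtype=np.float64)
        for key in ("nucleus_radius", "mito_puncta_per_cell", "mito_radius_px"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PairedSample:
    """One (hyperspectral input, fluorescence truth, masks) triple."""

    input: np.ndarray            # (C, H, W) float
    truth: np.ndarray            # (3, H, W) float in [0, 1]
    masks: np.ndarray            # (3, H, W) uint8 pre-blur supports
    seed: int
    config_hash: str


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator):
    """Random non-overlapping nucleus ellipses; gives up after bounded retries."""
    n = cfg.image_size
    rmin, rmax = (r * n for r in cfg.nucleus_radius)
    placed = []  # (cy, cx, a, b, theta)
    attempts = 0
    while len(placed) < cfg.n_cells and attempts < 50 * cfg.n_cells:
        attempts += 1
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        margin = max(a, b) + 2
        cy = rng.uniform(margin, n - margin)
        cx = rng.uniform(margin, n - margin)
        if all(np.hypot(cy - py, cx - px) > (max(a, b) + max(pa, pb) + 4)
               for py, px, pa, pb, _ in placed):
            placed.append((cy, cx, a, b, rng.uniform(0, np.pi)))
    if len(placed) < cfg.n_cells:
        warnings.warn(
            f"placed only {len(placed)} of {cfg.n_cells} cells without overlap",
            stacklevel=3)
    return placed


def _random_walk(start: np.ndarray, steps: int, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Integer pixel trace of a correlated random walk inside the image."""
    pos = start.astype(np.float64).copy()
    heading = rng.uniform(0, 2 * np.pi)
    pts = np.empty((steps, 2), dtype=np.int64)
    for i in range(steps):
        heading += rng.normal(0.0, 0.6)
        pos += np.array([np.sin(heading), np.cos(heading)])
        pos = np.clip(pos, 0, n - 1)
        pts[i] = pos.round()
    return pts


def render_scene(config: SceneConfig, seed: int):
    """Render fluorescence truth channels and their binary supports.

    Returns ``(truth, masks)``: truth is (3, H, W) in [0, 1] channel order
    (nucleus, mitochondria, ER); masks are the pre-blur supports.
    """
    rng = np.random.default_rng(seed)
    n = config.image_size
    masks = np.zeros((3, n, n), dtype=np.uint8)
    nuclei = _place_nuclei(config, rng)

    for cy, cx, a, b, theta in nuclei:
        rr, cc = ellipse(cy, cx, a, b, shape=(n, n), rotation=theta)
        masks[0, rr, cc] = 1

    nucleus_mask = masks[0].astype(bool)
    for cy, cx, a, b, _ in nuclei:
        r_cell = max(a, b)
        # mitochondria: puncta scattered in a perinuclear shell
        n_puncta = rng.integers(*config.mito_puncta_per_cell, endpoint=True)
        for _ in range(n_puncta):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(1.1 * r_cell, 2.2 * r_cell)
            py = cy + rad * np.sin(ang)
            px = cx + rad * np.cos(ang)
            if not (0 <= py < n and 0 <= px < n):
                continue
            rr, cc = disk((py, px), rng.integers(*config.mito_radius_px, endpoint=True),
                          shape=(n, n))
            masks[1, rr, cc] = 1
        # ER: random-walk filaments seeded at the nuclear envelope
        for _ in range(config.er_walks_per_cell):
            ang = rng.uniform(0, 2 * np.pi)
            start = np.array([cy + (r_cell + 1) * np.sin(ang),
                              cx + (r_cell + 1) * np.cos(ang)])
            start = np.clip(start, 0, n - 1)
            pts = _random_walk(start, config.er_steps, n, rng)
            masks[2, pts[:, 0], pts[:, 1]] = 1

    # organelles live outside the nucleus
    masks[1][nucleus_mask] = 0
    masks[2][nucleus_mask] = 0
    if config.er_width_px > 1:
        masks[2] = binary_dilation(
            masks[2], iterations=config.er_width_px - 1).astype(np.uint8)

    truth = np.empty_like(masks, dtype=np.float64)
    for k in range(3):
        ch = gaussian_filter(masks[k].astype(np.float64), config.blur_sigma)
        peak = ch.max()
        truth[k] = ch / peak if peak > 0 else ch
    return truth, masks


def mix_to_input(truth: np.ndarray, config: SceneConfig, seed: int) -> np.ndarray:
    """Mix organelle channels into the C-channel input stack, with noise.

    channel_c = Σ_o M[c,o]·truth_o + background, degraded by Poisson shot
    noise (at ``poisson_gain`` photons per unit intensity) and additive
    Gaussian read noise, clipped to be nonnegative.
    """
    M = config.mixing_matrix
    clean = np.einsum("co,ohw->chw", M, np.asarray(truth, dtype=np.float64))
    clean = clean + config.background
    rng = np.random.default_rng(seed)
    noisy = clean
    if config.poisson_gain > 0:
        noisy = rng.poisson(np.maximum(noisy, 0.0) * config.poisson_gain)
        noisy = noisy / config.poisson_gain
    if config.gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, config.gaussian_sigma, noisy.shape)
    return np.maximum(noisy, 0.0)


def make_pair(config: SceneConfig, seed: int) -> PairedSample:
    """Render one scene and its mixed, noisy input stack."""
    truth, masks = render_scene(config, seed)
    # independent noise stream, decorrelated from the geometry stream
    x = mix_to_input(truth, config, seed + 1_000_003)
    return PairedSample(input=x, truth=truth, masks=masks, seed=seed,
                        config_hash=config.content_hash())


def generate_pairs(config: SceneConfig, n_images: int,
                   master_seed: int | None = None) -> list[PairedSample]:
    """In-memory dataset: per-image seeds derived from the master seed."""
    if master_seed is None:
        master_seed = config.seed
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2 ** 31 - 1, size=n_images)
    return [make_pair(config, int(s)) for s in seeds]


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------

def make_dataset(config: SceneConfig, n_images: int, out_dir,
                 split: float = 0.8, master_seed: int | None = None) -> pd.DataFrame:
    """Write an on-disk dataset with a reproducible train/test split.

    Inputs go out as C-page TIFF, truths as 3-page TIFF, masks as RGB PNG;
    the returned (and saved) manifest lists per-image paths, seeds and
    split membership.  The split is a seeded shuffle: with ``split=0.8``
    and 10 images, exactly 8 land in train and 2 in test.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images to split")
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "truths").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    if master_seed is None:
        master_seed = config.seed
    pairs = generate_pairs(config, n_images, master_seed)
    order = np.random.default_rng(master_seed + 1).permutation(n_images)
    n_train = int(round(split * n_images))
    membership = np.empty(n_images, dtype=object)
    membership[order[:n_train]] = "train"
    membership[order[n_train:]] = "test"

    records = []
    for i, pair in enumerate(pairs):
        paths = {
            "input_path": f"inputs/{i:05d}.tif",
            "truth_path": f"truths/{i:05d}.tif",
            "mask_path": f"masks/{i:05d}.png",
        }
        tifffile.imwrite(out / paths["input_path"], pair.input.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(out / paths["truth_path"], pair.truth.astype(np.float32),
                         photometric="minisblack")
        imsave(out / paths["mask_path"],
               (pair.masks.transpose(1, 2, 0) * 255).astype(np.uint8),
               check_contrast=False)
        records.append({"index": i, "split": membership[i], "seed": pair.seed,
                        "config_hash": pair.config_hash, **paths})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    config.to_yaml(out / "scene_config.yaml")
    return manifest


def load_dataset(data_dir, split: str | None = None):
    """Load (inputs, truths) arrays for one split from an on-disk dataset."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    xs = np.stack([tifffile.imread(data_dir / p) for p in manifest["input_path"]])
    ys = np.stack([tifffile.imread(data_dir / p) for p in manifest["truth_path"]])
    return xs.astype(np.float64), ys.astype(np.float64)
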