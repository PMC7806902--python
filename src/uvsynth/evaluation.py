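"""Quantitative evaluation of synthetic UV images and spot masks.

Reports per-pixel L1 loss on the 0-255 scale (median by default, mean as a
variant), the Frechet distance between feature distributions of two image
sets (FID) with a pluggable embedder, pixel-level segmentation metrics
(IoU / recall / precision / F-measure), Pearson correlation, no-intercept
linear regression, and pixelwise-L1 heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import patch_ops


# ---------------------------------------------------------------------------
# per-pixel L1

def per_pixel_l1(img_a: np.ndarray, img_b: np.ndarray,
                 mask: np.ndarray | None = None,
                 aggregate: str = "median") -> float:
    """Aggregate absolute pixel difference, scaled to 0-255.

    The median (default) is robust to outlier pixels; the mean variant is
    provided for comparison.  Multichannel inputs contribute one distance
    per pixel per channel.
    """
    if img_a.shape != img_b.shape:
        raise ValueError("image shapes differ")
    d = np.abs(np.asarray(img_a, float) - np.asarray(img_b, float)) * 255.0
    if mask is not None:
        m = mask.astype(bool)
        if m.shape != d.shape[:m.ndim]:
            raise ValueError("mask shape does not match images")
        if not m.any():
            raise ValueError("mask is empty")
        d = d[m]
    if aggregate == "median":
        return float(np.median(d))
    if aggregate == "mean":
        return float(np.mean(d))
    raise ValueError("aggregate must be 'median' or 'mean'")


def l1_heatmap(img_a: np.ndarray, img_b: np.ndarray,
               mask: np.ndarray | None = None):
    """Pixelwise |a-b| on the 0-255 scale (0 outside the mask) and an RGBA
    overlay rendered with a fixed colormap."""
    if img_a.shape != img_b.shape:
        raise ValueError("image shapes differ")
    d = np.abs(np.asarray(img_a, float) - np.asarray(img_b, float)) * 255.0
    if d.ndim == 3:
        d = d.mean(axis=2)
    if mask is not None:
        d = np.where(mask.astype(bool), d, 0.0)
    import matplotlib
    overlay = matplotlib.colormaps["inferno"](np.clip(d / 255.0, 0, 1))
    return d, overlay


# ---------------------------------------------------------------------------
# FID

@dataclass
class FidInputs:
    mu1: np.ndarray
    mu2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    embedder_id: str = ""


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid_from_moments(inputs: FidInputs) -> float:
    """|mu1-mu2|^2 + tr(S1 + S2 - 2 (S1 S2)^{1/2}), clipped to >= 0.

    tr (S1 S2)^{1/2} is evaluated as tr sqrt(sqrt(S1) S2 sqrt(S1)), which is
    equal for PSD matrices and numerically stable; negative eigenvalues from
    round-off are clipped at zero.
    """
    s1 = (inputs.sigma1 + inputs.sigma1.T) / 2.0
    s2 = (inputs.sigma2 + inputs.sigma2.T) / 2.0
    diff = float(np.sum((inputs.mu1 - inputs.mu2) ** 2))
    r1 = _sqrtm_psd(s1)
    inner = r1 @ s2 @ r1
    vals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    tr_sqrt = float(np.sqrt(np.clip(vals, 0.0, None)).sum())
    val = diff + float(np.trace(s1) + np.trace(s2)) - 2.0 * tr_sqrt
    return max(val, 0.0)


def fid(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """FID between two sets of feature vectors (rows = samples)."""
    fa = np.atleast_2d(np.asarray(features_a, float))
    fb = np.atleast_2d(np.asarray(features_b, float))
    if fa.shape[1] != fb.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least two feature vectors per set")
    mu1, mu2 = fa.mean(axis=0), fb.mean(axis=0)
    s1 = np.cov(fa, rowvar=False)
    s2 = np.cov(fb, rowvar=False)
    s1 = np.atleast_2d(s1)
    s2 = np.atleast_2d(s2)
    return fid_from_moments(FidInputs(mu1, mu2, s1, s2))


class RandomProjectionEmbedder:
    """Fixed-seed linear projection of downsampled patch pixels.

    A lightweight, fully deterministic feature embedder for FID when a
    pretrained perceptual network is not available or not wanted.  Patches
    are block-averaged to ``grid_size`` x ``grid_size`` and projected with a
    Gaussian matrix drawn once at construction.
    """

    def __init__(self, dim: int = 64, grid_size: int = 16, seed: int = 0):
        self.dim, self.grid_size, self.seed = dim, grid_size, seed
        self._proj: np.ndarray | None = None
        self.embedder_id = f"randproj{dim}-g{grid_size}-s{seed}"

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        p = np.asarray(patch, float)
        if p.ndim == 3:
            p = p.mean(axis=2)
        g = self.grid_size
        h, w = p.shape
        by, bx = max(h // g, 1), max(w // g, 1)
        p = p[:by * (h // by), :bx * (w // bx)]
        small = p.reshape(h // by, by, w // bx, bx).mean(axis=(1, 3))
        flat = small.ravel()
        if self._proj is None or self._proj.shape[0] != flat.size:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((flat.size, self.dim)) / np.sqrt(flat.size)
        return flat @ self._proj


def embed_patches(images, region_masks, embedder, patch_size: int = 256,
                  stride: int | None = None,
                  min_mask_fraction: float = 0.5) -> np.ndarray:
    """One feature vector per face-covering patch across all images."""
    stride = stride or patch_size
    feats = []
    for img, mask in zip(images, region_masks):
        grid = patch_ops.plan_grid(img.shape[:2], patch_size, stride,
                                   region_mask=mask,
                                   min_mask_fraction=min_mask_fraction)
        for patch in patch_ops.extract(img, grid):
            feats.append(embedder(patch))
    if not feats:
        raise ValueError("no patches cover the region masks")
    return np.stack(feats)


# ---------------------------------------------------------------------------
# segmentation metrics

@dataclass
class ConfusionPixels:
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_pixels(pred: np.ndarray, truth: np.ndarray,
                     region: np.ndarray | None = None) -> ConfusionPixels:
    p = pred.astype(bool)
    t = truth.astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    if region is not None:
        r = region.astype(bool)
        p, t = p[r], t[r]
    return ConfusionPixels(tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
                           fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)))


def mask_metrics(pred: np.ndarray, truth: np.ndarray,
                 region: np.ndarray | None = None) -> dict:
    """IoU, recall, precision and F-measure of a predicted spot mask.

    Conventions for degenerate cases: an empty truth with an empty
    prediction scores 1 everywhere; an empty truth with a non-empty
    prediction gives recall NaN (undefined), IoU and precision 0.
    """
    c = confusion_pixels(pred, truth, region)
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fn == 0:  # no true spots
        if fp == 0:
            return {"iou": 1.0, "recall": 1.0, "precision": 1.0, "f": 1.0}
        return {"iou": 0.0, "recall": float("nan"), "precision": 0.0,
                "f": float("nan")}
    iou = tp / (tp + fp + fn)
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f = (2 * precision * recall / (precision + recall)
         if (precision + recall) else 0.0)
    return {"iou": iou, "recall": recall, "precision": precision, "f": f}


# ---------------------------------------------------------------------------
# correlation / regression

def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples, n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sum(dx * dx))
    sy = float(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance")
    return float(np.sum(dx * dy) / np.sqrt(sx * sy))


def regress_no_intercept(x, y) -> float:
    """Least-squares slope of y = b x (no intercept): sum(xy) / sum(x^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all-zero x")
    return float(np.sum(x * y) / sxx)


# ---------------------------------------------------------------------------
# ablation report

ABLATION_ROWS = [
    ("uv_net", "+", "+"),
    ("uv_net", "-", "+"),
    ("uv_net", "+", "-"),
    ("uv_net", "-", "-"),
    ("ica_blue", "-", "-"),
    ("ica_gray", "-", "-"),
    ("blue_channel", "-", "-"),
    ("grayscale", "-", "-"),
]


def ablation_report(metrics: dict) -> "pandas.DataFrame":
    """Assemble the ablation grid (4 generator variants x 2 learning
    techniques, plus the ICA / blue-channel / grayscale baselines) as a
    table of median L1 and FID.  ``metrics`` maps
    (method, disc_flag, align_flag) -> {"l1": ..., "fid": ...}; missing
    variants are reported as NA."""
    import pandas as pd

    rows = []
    for method, disc, align in ABLATION_ROWS:
        m = metrics.get((method, disc, align), {})
        rows.append({"method": method, "discriminator": disc,
                     "local_alignment": align,
                     "median_l1": m.get("l1", float("nan")),
                     "fid": m.get("fid", float("nan"))})
    return pd.DataFrame(rows)
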