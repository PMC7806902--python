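"""Melanin-emphasis baselines: grayscale, blue channel, and ICA.

The ICA baseline follows the classical skin-chromophore decomposition:
log-transformed RGB reflectance of skin lies, up to a per-pixel shading
offset along (1,1,1), in a plane spanned by the absorbance directions of
melanin and hemoglobin.  After projecting out the shading direction, a
2-source ICA on the masked skin pixels separates the two chromophore maps.
Re-synthesizing with a larger melanin weight yields a pigment-emphasized
image comparable to a UV capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA

_LOG_EPS = 1e-4
_U_SHADING = np.ones(3) / np.sqrt(3.0)


def grayscale(color: np.ndarray) -> np.ndarray:
    """Rec.601 luminance 0.299 R + 0.587 G + 0.114 B."""
    c = np.asarray(color, float)
    if c.ndim != 3 or c.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return c @ np.array([0.299, 0.587, 0.114])


def blue_channel(color: np.ndarray) -> np.ndarray:
    c = np.asarray(color, float)
    if c.ndim != 3 or c.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return c[:, :, 2].copy()


@dataclass
class IcaDecomposition:
    melanin_map: np.ndarray        # H x W component image (absorption units)
    hemoglobin_map: np.ndarray     # H x W
    mixing: np.ndarray             # 3 x 2: log-RGB direction per component
    mean_log_rgb: np.ndarray       # 3-vector, mean over masked pixels
    shading_map: np.ndarray        # H x W scalar coefficient along (1,1,1)
    skin_mask: np.ndarray          # H x W bool used for the fit
    shading_removed: bool = True


def ica_decompose(color: np.ndarray, skin_mask: np.ndarray,
                  seed: int = 0) -> IcaDecomposition:
    """Decompose a skin image into melanin and hemoglobin component maps.

    Steps: log-transform RGB; split off the per-pixel shading coefficient
    along (1,1,1); run 2-source FastICA on the masked pixels of the
    remaining 2-D chromaticity plane; orient each component so that larger
    values mean more absorption (darker skin), and label as melanin the
    component with the stronger relative blue-channel absorption
    (hemoglobin absorbs green most strongly, melanin's absorption keeps
    rising into the blue/UV).
    """
    c = np.asarray(color, float)
    if c.ndim != 3 or c.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    mask = skin_mask.astype(bool)
    if mask.sum() < 100:
        raise ValueError("need at least 100 masked skin pixels")
    h, w, _ = c.shape
    log_rgb = np.log(np.clip(c, _LOG_EPS, None)).reshape(-1, 3)
    mean_log = log_rgb[mask.ravel()].mean(axis=0)
    centered = log_rgb - mean_log
    shading = centered @ _U_SHADING                 # per-pixel scalar
    plane = centered - shading[:, None] * _U_SHADING

    # orthonormal basis of the plane orthogonal to (1,1,1)
    b1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    b2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)
    coords = plane @ np.stack([b1, b2], axis=1)     # (H*W, 2)

    fit_pts = coords[mask.ravel()]
    if np.linalg.matrix_rank(np.cov(fit_pts, rowvar=False), tol=1e-10) < 2:
        raise ValueError("degenerate pixel cloud: rank < 2 in the "
                         "chromaticity plane")
    ica = FastICA(n_components=2, algorithm="deflation", tol=1e-6,
                  max_iter=2000, random_state=seed)
    ica.fit(fit_pts)
    sources = ica.transform(coords)                 # (H*W, 2)
    mix2 = ica.mixing_                              # 2 x 2: coords = S @ mix2.T
    mix_rgb = np.stack([b1, b2], axis=1) @ mix2     # 3 x 2 log-RGB directions
    offset2 = ica.mean_                             # removed by transform

    # label: melanin = stronger blue absorption relative to green (within
    # the shading-free plane; sign-invariant ratio)
    def blue_green_ratio(v):
        return abs(v[2]) / (abs(v[1]) + 1e-12)

    mel_idx = int(np.argmax([blue_green_ratio(mix_rgb[:, 0]),
                             blue_green_ratio(mix_rgb[:, 1])]))
    hem_idx = 1 - mel_idx
    order = [mel_idx, hem_idx]

    # orient: more chromophore means more absorption, i.e. a lower blue
    # channel for melanin and a lower green channel for hemoglobin
    for k, ch in ((mel_idx, 2), (hem_idx, 1)):
        if mix_rgb[ch, k] > 0:
            mix_rgb[:, k] *= -1.0
            sources[:, k] *= -1.0
    return IcaDecomposition(
        melanin_map=sources[:, mel_idx].reshape(h, w),
        hemoglobin_map=sources[:, hem_idx].reshape(h, w),
        mixing=mix_rgb[:, order],
        mean_log_rgb=mean_log + np.stack([b1, b2], axis=1) @ offset2,
        shading_map=shading.reshape(h, w),
        skin_mask=mask)


def ica_synthesize(decomp: IcaDecomposition, w_melanin: float,
                   w_hemoglobin: float) -> np.ndarray:
    """Re-synthesize an RGB image from weighted components (shading and the
    mean chromaticity reapplied)."""
    h, w = decomp.melanin_map.shape
    comps = np.stack([w_melanin * decomp.melanin_map.ravel(),
                      w_hemoglobin * decomp.hemoglobin_map.ravel()], axis=1)
    log_rgb = (decomp.mean_log_rgb
               + comps @ decomp.mixing.T
               + decomp.shading_map.ravel()[:, None] * _U_SHADING)
    return np.exp(log_rgb).reshape(h, w, 3)


def ica_emphasize(decomp: IcaDecomposition, w_melanin: float,
                  w_hemoglobin: float, render: str = "blue") -> np.ndarray:
    """Single-channel melanin-emphasized rendering."""
    if w_melanin < 0 or w_hemoglobin < 0:
        raise ValueError("weights must be >= 0")
    rgb = ica_synthesize(decomp, w_melanin, w_hemoglobin)
    if render == "blue":
        return blue_channel(rgb)
    if render == "grayscale":
        return grayscale(rgb)
    raise ValueError("render must be 'blue' or 'grayscale'")


def weight_grid(step: float = 0.1, weight_sum: float = 2.0) -> list[tuple[float, float]]:
    n = round(weight_sum / step)
    if abs(n * step - weight_sum) > 1e-9:
        raise ValueError("step must divide weight_sum")
    return [(round(i * step, 10), round(weight_sum - i * step, 10))
            for i in range(n + 1)]


def weight_grid_search(decomps, uv_references, masks=None, step: float = 0.1,
                       weight_sum: float = 2.0, render: str = "blue"):
    """Scan (w_m, w_h) with w_m + w_h = weight_sum and pick the pair that
    minimizes the pooled median per-pixel L1 against the UV references.
    Ties go to the smaller melanin weight."""
    decomps = list(decomps)
    uv_references = list(uv_references)
    if not decomps or len(decomps) != len(uv_references):
        raise ValueError("need matching non-empty decomposition / reference sets")
    if masks is None:
        masks = [d.skin_mask for d in decomps]
    best = None
    for wm, wh in weight_grid(step, weight_sum):
        dists = []
        for d, ref, m in zip(decomps, uv_references, masks):
            out = ica_emphasize(d, wm, wh, render=render)
            dists.append(np.abs(out - np.asarray(ref, float))[m.astype(bool)])
        score = float(np.median(np.concatenate(dists)) * 255.0)
        if best is None or score < best[0] - 1e-12:
            best = (score, wm, wh)
    return best[1], best[2]


# reference melanin/hemoglobin weights for clinical facial photographs
CLINICAL_ICA_WEIGHTS = (1.3, 0.7)
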