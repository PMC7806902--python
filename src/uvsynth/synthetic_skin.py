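"""Paired color/UV skin phantoms with known ground truth.

Real paired visible-light/UV facial captures are clinical data and cannot be
shipped; this module renders small skin phantoms that reproduce the features
the pipeline depends on:

* a melanin map (smooth base + hard circular pigment spots) that darkens the
  UV channel strongly and the color channels weakly — UV light emphasizes
  pigment because melanin absorbs it, so a spot's contrast is higher in UV
  than in the visible image whenever ``color_spot_contrast < 1``;
* a smooth hemoglobin (redness) field affecting the red/green balance of the
  color image only;
* a shared multiplicative shading field and additive sensor noise;
* a piecewise-constant integer displacement field between the color and UV
  captures, emulating subject movement between the two exposures.  The field
  is constant on ``misalign_tile``-sized tiles so that a tile-based
  translation search has an exactly recoverable answer.

Everything is deterministic given ``PhantomParams.seed``; all intensities
live on [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

# UV absorption strength of melanin and per-channel visible absorption
# (blue attenuated most, red least — melanin's broad absorption slope).
K_UV = 0.9
VIS_ABSORB = np.array([0.45, 0.60, 0.80])
SKIN_TONE = np.array([0.85, 0.64, 0.55])
BASE_MELANIN = 0.25
BACKGROUND = 0.12
SHADING_AMPLITUDE = 0.12


@dataclass
class PhantomParams:
    """Knobs of the phantom renderer (pixels / dimensionless intensities)."""

    width: int = 192
    height: int = 192
    n_spots: int = 25
    spot_radius_range: tuple[int, int] = (2, 5)
    spot_melanin_boost: float = 0.5
    color_spot_contrast: float = 0.35
    hemoglobin_amplitude: float = 0.08
    shading_scale: float = 48.0
    noise_sigma: float = 0.01
    misalign_max: int = 0
    misalign_tile: int = 96
    seed: int = 0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("phantom must be at least 64x64 pixels")
        rmin, rmax = self.spot_radius_range
        if not (1 <= rmin <= rmax):
            raise ValueError("spot_radius_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.color_spot_contrast <= 1.0:
            raise ValueError("color_spot_contrast must be in [0, 1]")
        if not 0.0 < self.spot_melanin_boost <= 1.0:
            raise ValueError("spot_melanin_boost must be in (0, 1]")
        if self.misalign_max < 0:
            raise ValueError("misalign_max must be >= 0")
        if self.misalign_tile < 1:
            raise ValueError("misalign_tile must be >= 1")


@dataclass
class ImagePair:
    """One subject/view: color capture, UV capture, and ground truth."""

    color: np.ndarray            # H x W x 3 on [0, 1]
    uv: np.ndarray               # H x W on [0, 1]
    face_mask: np.ndarray        # H x W bool
    spot_mask: np.ndarray        # H x W bool, subset of face_mask
    shift_field: np.ndarray      # H x W x 2 int (dy, dx), UV relative to color
    true_uv: np.ndarray = field(repr=False, default=None)
    params: PhantomParams | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.uv.shape


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """Zero-mean unit-ish smooth random field."""
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=max(scale / 4.0, 1.0))
    s = f.std()
    return f / s if s > 0 else f


def _face_ellipse(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.46 * h, 0.42 * w
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(params: PhantomParams) -> ImagePair:
    """Render one paired color/UV phantom.

    The UV raster is produced by sampling the noise-free UV ground truth at
    positions displaced by the piecewise-constant shift field, then adding
    sensor noise; the color raster keeps the undisplaced geometry.
    """
    params.validate()
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)

    face = _face_ellipse(h, w)

    # melanin: smooth base + hard discs inside the face
    melanin = BASE_MELANIN + 0.03 * _smooth_field(rng, h, w, params.shading_scale / 2)
    spot_mask = np.zeros((h, w), dtype=bool)
    rmin, rmax = params.spot_radius_range
    margin = rmax + 2
    yy, xx = np.mgrid[0:h, 0:w]
    inner = _shrunken_ellipse(h, w, margin)
    cand = np.argwhere(inner)
    if params.n_spots > 0 and len(cand):
        idx = rng.choice(len(cand), size=params.n_spots, replace=False)
        for cy, cx in cand[idx]:
            r = int(rng.integers(rmin, rmax + 1))
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            spot_mask |= disc
    spot_mask &= face
    melanin = melanin + params.spot_melanin_boost * spot_mask

    shading = 1.0 + SHADING_AMPLITUDE * _smooth_field(rng, h, w, params.shading_scale)

    hemo = params.hemoglobin_amplitude * (
        0.5 + 0.5 * _smooth_field(rng, h, w, params.shading_scale / 2))

    # noise-free, alignment-free UV ground truth
    true_uv = np.clip(1.0 - K_UV * melanin, 0.0, 1.0) * shading
    true_uv = np.where(face, true_uv, BACKGROUND * shading)
    true_uv = np.clip(true_uv, 0.0, 1.0)

    # color capture: spots show only a fraction of their melanin boost
    mel_vis = (BASE_MELANIN
               + (melanin - BASE_MELANIN - params.spot_melanin_boost * spot_mask)
               + params.color_spot_contrast * params.spot_melanin_boost * spot_mask)
    color = np.empty((h, w, 3))
    for ch in range(3):
        skin = SKIN_TONE[ch] * (1.0 - VIS_ABSORB[ch] * mel_vis)
        if ch == 1:
            skin = skin * (1.0 - 0.6 * hemo)
        elif ch == 2:
            skin = skin * (1.0 - 0.3 * hemo)
        color[:, :, ch] = np.where(face, skin, BACKGROUND) * shading
    color = np.clip(color + rng.normal(0.0, params.noise_sigma, color.shape), 0, 1)

    # piecewise-constant displacement of the UV capture
    shift_field = np.zeros((h, w, 2), dtype=np.int64)
    if params.misalign_max > 0:
        t = params.misalign_tile
        nty = -(-h // t)
        ntx = -(-w // t)
        tiles = rng.integers(-params.misalign_max, params.misalign_max + 1,
                             size=(nty, ntx, 2))
        shift_field = np.repeat(np.repeat(tiles, t, axis=0), t, axis=1)[:h, :w]
    ry = np.clip(yy + shift_field[:, :, 0], 0, h - 1)
    rx = np.clip(xx + shift_field[:, :, 1], 0, w - 1)
    uv = true_uv[ry, rx]
    uv = np.clip(uv + rng.normal(0.0, params.noise_sigma, uv.shape), 0.0, 1.0)

    return ImagePair(color=color.astype(np.float64), uv=uv,
                     face_mask=face, spot_mask=spot_mask,
                     shift_field=shift_field, true_uv=true_uv, params=params)


def _shrunken_ellipse(h: int, w: int, margin: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.46 * h - margin, 0.42 * w - margin
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_cohort(n: int, params: PhantomParams,
                spot_density_gradient: bool = False) -> list[ImagePair]:
    """n phantoms with per-subject seeds derived from ``params.seed``.

    With ``spot_density_gradient`` the spot count rises monotonically across
    subjects, mimicking the accumulation of pigment spots with age.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if spot_density_gradient and n > 1:
        lo = max(1, params.n_spots // 4)
        counts = np.round(np.linspace(lo, params.n_spots, n)).astype(int)
    else:
        counts = np.full(n, params.n_spots)
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    cohort = []
    for i in range(n):
        p = PhantomParams(**{**asdict(params),
                             "n_spots": int(counts[i]), "seed": seeds[i]})
        p.spot_radius_range = tuple(p.spot_radius_range)
        cohort.append(make_phantom(p))
    return cohort


def true_uv_oracle(pair: ImagePair) -> np.ndarray:
    """Noise-free, alignment-free UV ground truth for a phantom pair."""
    if pair.true_uv is None:
        raise ValueError("pair was not produced by make_phantom")
    return pair.true_uv


def save_pair(pair: ImagePair, out_dir, subject: str, view: str = "front") -> None:
    """Write ``<subject>_<view>_{color,uv,face,spots}.png`` plus a JSON sidecar."""
    from .cli_io import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{subject}_{view}"
    write_image(out / f"{stem}_color.png", pair.color)
    write_image(out / f"{stem}_uv.png", pair.uv)
    write_image(out / f"{stem}_face.png", pair.face_mask.astype(float))
    write_image(out / f"{stem}_spots.png", pair.spot_mask.astype(float))
    if pair.params is not None:
        meta = asdict(pair.params)
        meta["spot_radius_range"] = list(meta["spot_radius_range"])
        (out / f"{stem}_params.json").write_text(json.dumps(meta, indent=2))
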