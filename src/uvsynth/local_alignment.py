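"""Local alignment of color and UV captures via temporal synthetic UV images.

Color and UV exposures of the same face are taken moments apart, so they
disagree by small local translations.  Aligning them directly is hard
because the two modalities look nothing alike; instead an L1-only generator
(trained without discriminator or alignment) produces a *temporal* synthetic
UV image from the color image, which is photometrically comparable to the
real UV capture.  Large tiles of the two UV-like images are then matched by
exhaustive integer-translation search minimizing mean per-pixel L1 on the
overlapping region, and each small training patch inherits the shift of the
tile whose center is nearest.

Sign convention (used everywhere): the stored shift (dy, dx) is the
translation applied to the color-side window — a training pair samples the
color image at ``window + shift`` and the UV image at ``window``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import patch_ops, uv_photo_net
from .patch_ops import PatchWindow
from .synthetic_skin import ImagePair


@dataclass
class TileShift:
    window: PatchWindow
    shift: tuple[int, int]        # (dy, dx) applied to the color-side patch
    score: float                  # mean per-pixel L1 at the optimum


@dataclass
class AlignmentResult:
    tiles: list[TileShift]

    def nearest_tile(self, window: PatchWindow) -> TileShift:
        """Tile whose center is closest to the window's center; ties go to
        the first tile in row-major planning order."""
        cy, cx = window.center
        best, best_d = None, np.inf
        for t in self.tiles:
            ty, tx = t.window.center
            d = (ty - cy) ** 2 + (tx - cx) ** 2
            if d < best_d - 1e-9:
                best, best_d = t, d
        return best

    def to_json(self) -> str:
        return json.dumps([{"window": [t.window.row0, t.window.col0,
                                       t.window.size],
                            "shift": list(t.shift), "score": t.score}
                           for t in self.tiles])

    @classmethod
    def from_json(cls, text: str) -> "AlignmentResult":
        return cls([TileShift(PatchWindow(*d["window"]), tuple(d["shift"]),
                              d["score"]) for d in json.loads(text)])


def temporal_uv(train_patches, val_patches,
                gen_config: uv_photo_net.GeneratorConfig,
                schedule: uv_photo_net.TrainSchedule,
                seed: int = 0) -> uv_photo_net.TrainState:
    """Train the L1-only surrogate generator (lambda = 0, no alignment)."""
    return uv_photo_net.train(train_patches, val_patches, gen_config,
                              schedule, lam=0.0, seed=seed)


def search_shift(uv_tile: np.ndarray, synthetic_tile: np.ndarray,
                 search_radius: int) -> TileShift:
    """Exhaustive scan over (dy, dx) in [-r, r]^2.

    A candidate samples the synthetic tile displaced by (dy, dx) and scores
    the mean per-pixel |uv - synthetic| on the valid overlap only, so large
    shifts are neither favored nor penalized by their smaller overlap.
    Ties break toward smaller |dy|+|dx|, then lexicographic (dy, dx).
    """
    uv = np.asarray(uv_tile, float)
    syn = np.asarray(synthetic_tile, float)
    if uv.shape != syn.shape:
        raise ValueError("tiles must have the same shape")
    h, w = uv.shape[:2]
    r = int(search_radius)
    if r < 0:
        raise ValueError("search_radius must be >= 0")
    if r >= min(h, w):
        raise ValueError("search_radius must be smaller than the tile")
    best = None
    for dy in range(-r, r + 1):
        ys0, ys1 = max(dy, 0), min(h + dy, h)       # synthetic rows sampled
        yu0, yu1 = max(-dy, 0), min(h - dy, h)
        for dx in range(-r, r + 1):
            xs0, xs1 = max(dx, 0), min(w + dx, w)
            xu0, xu1 = max(-dx, 0), min(w - dx, w)
            diff = np.abs(uv[yu0:yu1, xu0:xu1] - syn[ys0:ys1, xs0:xs1])
            score = float(diff.mean())
            key = (score, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx), score)
    return TileShift(window=PatchWindow(0, 0, h), shift=best[1], score=best[2])


def align_pair(uv_image: np.ndarray, synthetic_uv: np.ndarray,
               tile_size: int = 900, stride: int | None = None,
               search_radius: int = 30,
               region_mask: np.ndarray | None = None) -> AlignmentResult:
    """Tile both UV-like images and search the best shift per tile."""
    stride = stride or tile_size // 2
    grid = patch_ops.plan_grid(uv_image.shape[:2], tile_size, stride,
                               region_mask=region_mask,
                               min_mask_fraction=0.0 if region_mask is None else 0.2)
    uv_tiles = patch_ops.extract(uv_image, grid)
    syn_tiles = patch_ops.extract(synthetic_uv, grid)
    tiles = []
    for win, ut, st in zip(grid.windows, uv_tiles, syn_tiles):
        ts = search_shift(ut, st, search_radius)
        tiles.append(TileShift(window=win, shift=ts.shift, score=ts.score))
    return AlignmentResult(tiles=tiles)


def align_pairs(pairs: list[ImagePair], temporal_gen, patch_size: int,
                tile_size: int = 96, stride: int | None = None,
                search_radius: int = 8) -> list[AlignmentResult]:
    """Synthesize a temporal UV per pair and align it to the real UV.

    ``temporal_gen`` is either a trained generator (nn.UNet) or a callable
    ``pair -> H x W array`` surrogate (e.g. the phantom UV ground truth)."""
    results = []
    for pair in pairs:
        if callable(temporal_gen) and not hasattr(temporal_gen, "forward"):
            syn = temporal_gen(pair)
        else:
            syn = uv_photo_net.convert_image(
                temporal_gen, pair.color, face_map=pair.face_mask,
                patch_size=patch_size, stride=patch_size,
                min_mask_fraction=0.0)
        results.append(align_pair(pair.uv, syn, tile_size=tile_size,
                                  stride=stride, search_radius=search_radius,
                                  region_mask=pair.face_mask))
    return results


def apply_alignment(pair: ImagePair, result: AlignmentResult,
                    grid: patch_ops.PatchGrid):
    """Aligned (color_patch, uv_patch) training pairs for one subject.

    Each training window's color content is sampled at ``window + shift`` of
    its nearest tile; windows pushed out of bounds by the shift are dropped.
    """
    h, w = pair.uv.shape
    color_patches, uv_patches = [], []
    for win in grid.windows:
        tile = result.nearest_tile(win)
        dy, dx = (tile.shift if tile is not None else (0, 0))
        r0, c0 = win.row0 + dy, win.col0 + dx
        if r0 < 0 or c0 < 0 or r0 + win.size > h or c0 + win.size > w:
            continue
        if win.row0 + win.size > h or win.col0 + win.size > w:
            continue
        color_patches.append(pair.color[r0:r0 + win.size, c0:c0 + win.size])
        uv_patches.append(pair.uv[win.row0:win.row0 + win.size,
                                  win.col0:win.col0 + win.size])
    return color_patches, uv_patches


def save_alignment(result: AlignmentResult, path) -> None:
    Path(path).write_text(result.to_json())


def load_alignment(path) -> AlignmentResult:
    return AlignmentResult.from_json(Path(path).read_text())
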