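"""Tiled patch extraction and whole-image reassembly.

Windows are square, 0-based, half-open ``[row0, row0+size)`` in (row, col)
coordinates.  A grid is planned on a regular lattice; windows overhanging
the image are realized through padding ('reflect' or 'zero').  Assembly
averages overlapping windows with uniform weights, which makes
``assemble(extract(img))`` an exact round trip on disjoint grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class PatchWindow:
    row0: int
    col0: int
    size: int

    @property
    def center(self) -> tuple[float, float]:
        return (self.row0 + (self.size - 1) / 2.0,
                self.col0 + (self.size - 1) / 2.0)


@dataclass
class PatchGrid:
    windows: list[PatchWindow]
    stride: int
    image_shape: tuple[int, int]
    size: int
    pad_mode: str = "reflect"

    def to_json(self) -> str:
        return json.dumps({
            "stride": self.stride, "size": self.size,
            "image_shape": list(self.image_shape), "pad_mode": self.pad_mode,
            "windows": [[w.row0, w.col0, w.size] for w in self.windows]})

    @classmethod
    def from_json(cls, text: str) -> "PatchGrid":
        d = json.loads(text)
        return cls(windows=[PatchWindow(*w) for w in d["windows"]],
                   stride=d["stride"], image_shape=tuple(d["image_shape"]),
                   size=d["size"], pad_mode=d["pad_mode"])


def _lattice(extent: int, size: int, stride: int) -> list[int]:
    """Window origins covering [0, extent) with the last window clamped to
    end exactly at a lattice point (may overhang; realized by padding)."""
    if extent <= size:
        return [0]
    pos = list(range(0, extent - size + 1, stride))
    if pos[-1] + size < extent:
        pos.append(pos[-1] + stride)
    return pos


def plan_grid(image_shape: tuple[int, int], size: int, stride: int,
              region_mask: np.ndarray | None = None,
              min_mask_fraction: float = 0.0,
              pad_mode: str = "reflect") -> PatchGrid:
    """Plan a regular lattice of ``size`` x ``size`` windows.

    When ``region_mask`` is given only windows whose in-bounds mask coverage
    is at least ``min_mask_fraction`` (of the full window area) are kept.
    """
    h, w = image_shape[:2]
    if not 0 < stride <= size:
        raise ValueError("need 0 < stride <= size")
    if not 0.0 <= min_mask_fraction <= 1.0:
        raise ValueError("min_mask_fraction must be in [0, 1]")
    if size > h + size // 2 or size > w + size // 2:
        raise ValueError(f"window size {size} too large for image {image_shape}")
    if pad_mode not in ("reflect", "zero"):
        raise ValueError("pad_mode must be 'reflect' or 'zero'")
    windows = []
    for r in _lattice(h, size, stride):
        for c in _lattice(w, size, stride):
            if region_mask is not None:
                cov = region_mask[r:min(r + size, h), c:min(c + size, w)].sum()
                if cov / (size * size) < max(min_mask_fraction, 1e-12):
                    continue
            windows.append(PatchWindow(r, c, size))
    return PatchGrid(windows=windows, stride=stride, image_shape=(h, w),
                     size=size, pad_mode=pad_mode)


def _pad(image: np.ndarray, pad: int, mode: str) -> np.ndarray:
    widths = [(0, pad), (0, pad)] + [(0, 0)] * (image.ndim - 2)
    if mode == "reflect":
        return np.pad(image, widths, mode="reflect")
    return np.pad(image, widths, mode="constant")


def extract(image: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Patches in window order; overhanging windows padded per ``pad_mode``."""
    if image.shape[:2] != grid.image_shape:
        raise ValueError(
            f"image shape {image.shape[:2]} != grid shape {grid.image_shape}")
    pad = grid.size
    padded = _pad(image, pad, grid.pad_mode)
    return [padded[w.row0:w.row0 + w.size, w.col0:w.col0 + w.size].copy()
            for w in grid.windows]


def assemble(patches: list[np.ndarray], grid: PatchGrid,
             fill_value: float = 0.0,
             fill_image: np.ndarray | None = None) -> np.ndarray:
    """Reassemble a whole image from per-window patches.

    Overlapping pixels are averaged with uniform weights.  Pixels covered by
    no window take ``fill_image`` values where provided, else ``fill_value``.
    """
    if len(patches) != len(grid.windows):
        raise ValueError(
            f"{len(patches)} patches for {len(grid.windows)} windows")
    h, w = grid.image_shape
    trailing = patches[0].shape[2:] if patches else ()
    acc = np.zeros((h, w) + trailing, dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int64)
    for patch, win in zip(patches, grid.windows):
        if patch.shape[:2] != (win.size, win.size):
            raise ValueError("patch size does not match its window")
        r1 = min(win.row0 + win.size, h)
        c1 = min(win.col0 + win.size, w)
        acc[win.row0:r1, win.col0:c1] += patch[:r1 - win.row0, :c1 - win.col0]
        cnt[win.row0:r1, win.col0:c1] += 1
    covered = cnt > 0
    cdim = cnt if not trailing else cnt[..., None]
    out = np.divide(acc, np.maximum(cdim, 1))
    if fill_image is not None:
        out = np.where((covered if not trailing else covered[..., None]),
                       out, fill_image)
    else:
        out[~covered] = fill_value
    return out


def save_grid(grid: PatchGrid, path) -> None:
    Path(path).write_text(grid.to_json())


def load_grid(path) -> PatchGrid:
    return PatchGrid.from_json(Path(path).read_text())
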