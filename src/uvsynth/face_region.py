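"""Patch-level face / non-face classification and region-map assembly.

Small square patches of the color image are classified as face or
background by a compact CNN; the predicted labels are painted back onto the
image canvas to form a binary face-region map that restricts all downstream
training and evaluation to skin.  On phantoms the training labels come from
the known face mask; for real photographs an externally produced landmark
mask can be passed through the same labeling hook.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .patch_ops import PatchGrid, PatchWindow, extract


@dataclass(frozen=True)
class RegionLabel:
    window: PatchWindow
    label: str                    # "face" | "non_face"


@dataclass
class FaceClassifierConfig:
    patch_size: int = 24          # 120 at clinical photo scale
    depth: int = 3
    base_channels: int = 8
    steps: int = 1000
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0


@dataclass
class FaceClassifierState:
    net: "_PatchCNN"
    config: FaceClassifierConfig
    loss_trace: list = field(default_factory=list)


class _PatchCNN:
    """4 conv blocks (stride-2) + global average pool + dense sigmoid."""

    def __init__(self, patch_size: int, depth: int, base_channels: int,
                 seed: int):
        rng = np.random.default_rng(seed)
        self.patch_size = patch_size
        self.convs, self.acts = [], []
        ci = 3
        for i in range(depth):
            co = base_channels * 2 ** i
            self.convs.append(nn.Conv2d(ci, co, stride=2, rng=rng))
            self.acts.append(nn.ReLU())
            ci = co
        self.pool = nn.GlobalAvgPool()
        self.dense = nn.Dense(ci, 1, rng=rng)

    def layers(self):
        return [*self.convs, self.dense]

    def forward(self, x):
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        z = self.dense.forward(self.pool.forward(h))[:, 0]
        self._p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        return self._p

    def backward(self, dp):
        dz = (dp * self._p * (1 - self._p)).astype(nn.F32)
        dh = self.pool.backward(self.dense.backward(dz[:, None]))
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dh = conv.backward(act.backward(dh))
        return dh


def label_patches_from_mask(mask: np.ndarray, grid: PatchGrid,
                            face_threshold: float = 0.9) -> list[RegionLabel]:
    """Label windows by mask coverage: face iff coverage >= threshold,
    non_face iff coverage == 0; intermediate windows are dropped (they mix
    the two classes and would only blur the decision boundary)."""
    if not 0.0 < face_threshold <= 1.0:
        raise ValueError("face_threshold must be in (0, 1]")
    h, w = mask.shape
    labels = []
    for win in grid.windows:
        sub = mask[win.row0:min(win.row0 + win.size, h),
                   win.col0:min(win.col0 + win.size, w)]
        cov = sub.sum() / (win.size * win.size)
        if cov >= face_threshold:
            labels.append(RegionLabel(win, "face"))
        elif cov == 0.0:
            labels.append(RegionLabel(win, "non_face"))
    return labels


def _patch_tensor(image: np.ndarray, windows, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    pad = size
    padded = np.pad(image, ((0, pad), (0, pad), (0, 0)), mode="reflect")
    out = np.stack([padded[wn.row0:wn.row0 + size, wn.col0:wn.col0 + size]
                    for wn in windows])
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)).astype(nn.F32)


def train_face_classifier(images, labeled: list[list[RegionLabel]],
                          config: FaceClassifierConfig) -> FaceClassifierState:
    """Train the patch CNN on (image, labels) pairs with log loss."""
    xs, ys = [], []
    for img, labels in zip(images, labeled):
        if not labels:
            continue
        xs.append(_patch_tensor(img, [l.window for l in labels],
                                config.patch_size))
        ys.append(np.array([1.0 if l.label == "face" else 0.0
                            for l in labels], dtype=np.float64))
    if not xs:
        raise ValueError("no labeled patches")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    net = _PatchCNN(config.patch_size, config.depth, config.base_channels,
                    config.seed)
    opt = nn.Adam(net.layers(), lr=config.lr)
    state = FaceClassifierState(net=net, config=config)
    for step in range(config.steps):
        idx = rng.integers(0, x.shape[0], size=config.batch_size)
        xb, yb = x[idx], y[idx]
        p = np.clip(net.forward(xb), 1e-7, 1 - 1e-7)
        loss = float(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
        dp = ((p - yb) / (p * (1 - p))) / len(yb)
        net.backward(dp.astype(nn.F32))
        opt.step()
        state.loss_trace.append(loss)
    return state


def predict_labels(state: FaceClassifierState, image: np.ndarray,
                   grid: PatchGrid, batch: int = 64) -> np.ndarray:
    """Face probability per grid window."""
    probs = []
    for i in range(0, len(grid.windows), batch):
        xb = _patch_tensor(image, grid.windows[i:i + batch],
                           state.config.patch_size)
        probs.append(state.net.forward(xb))
    return np.concatenate(probs) if probs else np.zeros(0)


def assemble_region_map(image: np.ndarray, classifier: FaceClassifierState,
                        patch_size: int | None = None,
                        stride: int | None = None) -> np.ndarray:
    """Paint per-window face votes onto the canvas; overlapping votes are
    resolved by majority with ties going to face."""
    from . import patch_ops

    size = patch_size or classifier.config.patch_size
    stride = stride or size
    grid = patch_ops.plan_grid(image.shape[:2], size, stride)
    probs = predict_labels(classifier, image, grid)
    h, w = image.shape[:2]
    votes_face = np.zeros((h, w), dtype=np.int64)
    votes_all = np.zeros((h, w), dtype=np.int64)
    for win, p in zip(grid.windows, probs):
        r1, c1 = min(win.row0 + size, h), min(win.col0 + size, w)
        votes_all[win.row0:r1, win.col0:c1] += 1
        if p >= 0.5:
            votes_face[win.row0:r1, win.col0:c1] += 1
    return (2 * votes_face >= votes_all) & (votes_all > 0)


def save_classifier(state: FaceClassifierState, path) -> None:
    path = Path(path)
    arrays = {}
    for i, l in enumerate(state.net.layers()):
        for k, v in l.params.items():
            arrays[f"{i}_{k}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    from dataclasses import asdict
    path.with_suffix(".json").write_text(json.dumps(asdict(state.config)))


def load_classifier(path) -> FaceClassifierState:
    path = Path(path)
    config = FaceClassifierConfig(**json.loads(path.with_suffix(".json").read_text()))
    net = _PatchCNN(config.patch_size, config.depth, config.base_channels,
                    config.seed)
    data = np.load(path.with_suffix(".npz"))
    for i, l in enumerate(net.layers()):
        for k in l.params:
            l.params[k][...] = data[f"{i}_{k}"]
    return FaceClassifierState(net=net, config=config)
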