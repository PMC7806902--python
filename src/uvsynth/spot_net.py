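"""Pigment-spot segmentation with a U-net and a cross-entropy + Dice cost.

The segmenter shares the translation generator's U-net body but ends in a
two-channel softmax head.  Training minimizes
``ce_weight * CE + dice_weight * soft-Dice`` on (UV or synthetic-UV) patches
against binary spot masks, with random flips/rotations and brightness
jitter; early stopping keeps the parameters with the minimum validation
cost.  Detection runs patchwise over a whole image, assembles the
probability map, binarizes at 0.5 and intersects with an evaluation region
(e.g. a cheek mask).  The spot-area percentage — spot pixels over region
pixels, x100 — is the pipeline's skin-damage indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, patch_ops

DICE_EPS = 1.0


@dataclass
class SpotTrainConfig:
    patch_size: int = 64
    in_channels: int = 1
    depth: int = 3
    base_channels: int = 8
    dropout_rate: float = 0.5
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    brightness_jitter: float = 0.1
    batch_size: int = 8
    lr: float = 1e-3
    iterations: int = 1500
    val_every: int = 250
    seed: int = 0

    def validate(self):
        if self.ce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.ce_weight == 0 and self.dice_weight == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class SpotNetState:
    net: nn.UNet
    config: SpotTrainConfig
    val_cost_trace: list = field(default_factory=list)
    best_val_cost: tuple[float, int] | None = None


@dataclass
class SpotPrediction:
    prob_map: np.ndarray          # H x W in [0, 1]
    mask: np.ndarray              # H x W bool, prob >= 0.5, within region
    region: np.ndarray            # H x W bool


def dice_loss(prob_map: np.ndarray, truth_mask: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft Dice loss  1 - (2 sum(p t) + eps) / (sum p + sum t + eps)."""
    p = np.asarray(prob_map, float)
    t = np.asarray(truth_mask, float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    inter = float((p * t).sum())
    return 1.0 - (2.0 * inter + eps) / (float(p.sum()) + float(t.sum()) + eps)


def _softmax2(logits: np.ndarray) -> np.ndarray:
    """Channel softmax for a 2-channel NCHW logit tensor; returns the
    foreground probability (channel 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def _loss_and_grad(logits: np.ndarray, truth: np.ndarray,
                   ce_w: float, dice_w: float):
    """Combined cost and its gradient w.r.t. the logits (NCHW, 2 channels).

    CE is averaged over pixels; the Dice term is computed per batch (soft
    Dice over all pixels of the batch) so its gradient couples pixels, as
    the overlap statistic itself does.
    """
    p1 = _softmax2(logits)
    t = truth.astype(np.float64)
    npix = p1.size
    ce = float(-np.mean(t * np.log(np.clip(p1, 1e-7, None))
                        + (1 - t) * np.log(np.clip(1 - p1, 1e-7, None))))
    inter = float((p1 * t).sum())
    psum, tsum = float(p1.sum()), float(t.sum())
    dice = 1.0 - (2 * inter + DICE_EPS) / (psum + tsum + DICE_EPS)
    # d(dice)/dp = -(2 t (psum+tsum+eps) - (2 inter + eps)) / (psum+tsum+eps)^2
    denom = (psum + tsum + DICE_EPS)
    d_dice_dp = -(2 * t * denom - (2 * inter + DICE_EPS)) / denom ** 2
    d_ce_dp = (p1 - t) / np.clip(p1 * (1 - p1), 1e-7, None) / npix
    dp1 = ce_w * d_ce_dp + dice_w * d_dice_dp
    # through softmax: dz1 = p1 (1-p1) dp1, dz0 = -dz1
    dz1 = dp1 * p1 * (1 - p1)
    dlogits = np.stack([-dz1, dz1], axis=1).astype(nn.F32)
    return ce_w * ce + dice_w * dice, dlogits


def _prep(patches, channels):
    a = np.asarray(patches, dtype=nn.F32)
    if a.ndim == 3:
        a = a[:, :, :, None]
    return np.ascontiguousarray(a.transpose(0, 3, 1, 2))


def train_spot_net(train_inputs, train_masks, config: SpotTrainConfig,
                   val_inputs=None, val_masks=None) -> SpotNetState:
    """Train on patch arrays (N x S x S [x C]) and binary mask patches."""
    config.validate()
    x = _prep(train_inputs, config.in_channels)
    t = np.asarray(train_masks, dtype=np.float64)
    if t.sum() == 0:
        raise ValueError("training masks contain no positive pixel")
    xv = tv = None
    if val_inputs is not None and len(val_inputs):
        xv = _prep(val_inputs, config.in_channels)
        tv = np.asarray(val_masks, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    net = nn.UNet(config.in_channels, 2, depth=config.depth,
                  base_channels=config.base_channels,
                  dropout_rate=config.dropout_rate, head="linear",
                  seed=config.seed)
    opt = nn.Adam(net.layers(), lr=config.lr)
    state = SpotNetState(net=net, config=config)
    best = None

    def validate(it):
        nonlocal best
        if xv is None:
            return
        cost, nb = 0.0, 0
        for i in range(0, xv.shape[0], 16):
            logits = net.forward(xv[i:i + 16], train=False)
            c, _ = _loss_and_grad(logits, tv[i:i + 16], config.ce_weight,
                                  config.dice_weight)
            cost += c
            nb += 1
        cost /= max(nb, 1)
        state.val_cost_trace.append((it, cost))
        if best is None or cost < best[0]:
            best = (cost, it, net.get_state())
            state.best_val_cost = (cost, it)

    validate(0)
    for it in range(1, config.iterations + 1):
        idx = rng.integers(0, x.shape[0], size=config.batch_size)
        xb, tb = x[idx].copy(), t[idx].copy()
        for i in range(xb.shape[0]):      # flips, rotations, brightness
            if rng.random() < 0.5:
                xb[i] = xb[i, :, ::-1]
                tb[i] = tb[i, ::-1]
            if rng.random() < 0.5:
                xb[i] = xb[i, :, :, ::-1]
                tb[i] = tb[i, :, ::-1]
            k = int(rng.integers(0, 4))
            if k:
                xb[i] = np.rot90(xb[i], k, axes=(1, 2))
                tb[i] = np.rot90(tb[i], k, axes=(0, 1))
            if config.brightness_jitter > 0:
                xb[i] = np.clip(xb[i] * (1 + rng.uniform(
                    -config.brightness_jitter, config.brightness_jitter)), 0, 1)
        xb = np.ascontiguousarray(xb)
        logits = net.forward(xb, train=True, rng=rng)
        _, dlogits = _loss_and_grad(logits, np.ascontiguousarray(tb),
                                    config.ce_weight, config.dice_weight)
        net.backward(dlogits)
        opt.step()
        if it % config.val_every == 0 or it == config.iterations:
            validate(it)
    if best is not None:
        net.set_state(best[2])
    return state


def predict_prob(state: SpotNetState, patches) -> np.ndarray:
    """Foreground probability per patch (N x S x S)."""
    x = _prep(patches, state.config.in_channels)
    out = []
    for i in range(0, x.shape[0], 16):
        logits = state.net.forward(x[i:i + 16], train=False)
        out.append(_softmax2(logits))
    return np.concatenate(out)


def detect_spots(state: SpotNetState, image: np.ndarray,
                 region_mask: np.ndarray,
                 stride: int | None = None) -> SpotPrediction:
    """Patchwise inference, probability-map assembly, 0.5 binarization and
    intersection with the evaluation region."""
    size = state.config.patch_size
    region = region_mask.astype(bool)
    if not region.any():
        h, w = image.shape[:2]
        return SpotPrediction(prob_map=np.zeros((h, w)),
                              mask=np.zeros((h, w), bool), region=region)
    grid = patch_ops.plan_grid(image.shape[:2], size, stride or size,
                               region_mask=region, min_mask_fraction=0.0)
    patches = patch_ops.extract(image, grid)
    probs = predict_prob(state, np.stack(patches))
    prob_map = patch_ops.assemble(list(probs), grid, fill_value=0.0)
    mask = (prob_map >= 0.5) & region
    return SpotPrediction(prob_map=prob_map, mask=mask, region=region)


def spot_area_percentage(pred: SpotPrediction) -> float:
    """100 * |mask ∩ region| / |region|."""
    n_region = int(pred.region.sum())
    if n_region == 0:
        raise ValueError("empty evaluation region")
    return 100.0 * int((pred.mask & pred.region).sum()) / n_region
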