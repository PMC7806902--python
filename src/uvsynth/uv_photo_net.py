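"""Conditional-GAN translation of color skin patches into synthetic UV patches.

The generator is a U-net mapping an S x S x 3 color patch on [0,1] to an
S x S UV patch on [0,1]; the discriminator scores (color, candidate-UV)
pairs with a single probability.  Training minimizes, over generator G and
(maximizing) discriminator D,

    (1/|I|) sum_i [ meanpix |Y_i - G(X_i)| + lambda log(1 - D(X_i, G(X_i))) ]
      + (lambda/|J|) sum_j log D(X_j, Y_j)

with disjoint index sets I (fake) and J (real) within each batch, followed
by a discriminator-only and a generator-only refinement phase with early
stopping on a validation set.  With lambda = 0 the objective reduces to the
pure per-pixel L1 loss and the discriminator is never trained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn, patch_ops
from .baselines import grayscale

LOG_EPS = 1e-6


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    depth: int = 3
    base_channels: int = 4
    dropout_rate: float = 0.5
    dropout_levels: tuple[int, ...] | None = None   # None = two innermost
    input_size: int = 64
    in_channels: int = 3
    out_channels: int = 1

    def validate(self):
        if self.input_size % 2 ** self.depth:
            raise ValueError("input_size must be divisible by 2^depth")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class DiscriminatorConfig:
    depth: int = 3
    base_channels: int = 8


@dataclass
class TrainSchedule:
    joint_iters: int = 2000
    disc_only_iters: int = 100
    gen_only_iters: int = 400
    val_every: int = 250
    batch_size: int = 8
    lr: float = 1e-3
    # instance noise added to both real and fake discriminator inputs so the
    # discriminator cannot win on sensor-noise texture alone and must use
    # image structure; 0 disables
    instance_noise: float = 0.01
    # generator adversarial update form: True = the minimax term
    # log(1 - D(X, G(X))) exactly as written in the objective; False = the
    # non-saturating surrogate -log D(X, G(X)) (same fixed point, gradient
    # does not vanish once the discriminator confidently rejects fakes)
    saturating_adv: bool = True


@dataclass
class CganLossTerms:
    l1_term: float
    adv_gen_term: float
    disc_real_term: float
    disc_fake_term: float
    lam: float


@dataclass
class TrainState:
    gen: nn.UNet
    disc: nn.PairDiscriminator | None
    gen_config: GeneratorConfig
    disc_config: DiscriminatorConfig | None
    lam: float
    seed: int
    iteration: int = 0
    phase: str = "joint"
    best_val_l1: tuple[float, int] | None = None
    val_l1_trace: list = field(default_factory=list)     # (iter, mean L1)
    train_loss_trace: list = field(default_factory=list)  # (iter, G, D)


def build_generator(config: GeneratorConfig, seed: int = 0) -> nn.UNet:
    config.validate()
    return nn.UNet(config.in_channels, config.out_channels,
                   depth=config.depth, base_channels=config.base_channels,
                   dropout_rate=config.dropout_rate,
                   dropout_levels=config.dropout_levels,
                   head="sigmoid", seed=seed)


def build_discriminator(config: DiscriminatorConfig, gen_config: GeneratorConfig,
                        seed: int = 0) -> nn.PairDiscriminator:
    return nn.PairDiscriminator(
        gen_config.in_channels + gen_config.out_channels,
        depth=config.depth, base_channels=config.base_channels, seed=seed + 1)


# ---------------------------------------------------------------------------
# forward wrappers (HWC single-image interface)

def _to_nchw(x: np.ndarray) -> np.ndarray:
    if x.ndim == 2:
        x = x[:, :, None]
    return np.ascontiguousarray(x.transpose(2, 0, 1)[None]).astype(nn.F32)


def generator_forward(gen: nn.UNet, color_patch: np.ndarray) -> np.ndarray:
    """Inference-mode conversion of one S x S x 3 patch (dropout off)."""
    if color_patch.shape[0] != color_patch.shape[1]:
        raise ValueError("patch must be square")
    y = gen.forward(_to_nchw(color_patch), train=False)
    out = y[0].transpose(1, 2, 0)
    return out[:, :, 0] if out.shape[2] == 1 else out


def discriminator_forward(disc: nn.PairDiscriminator, color_patch: np.ndarray,
                          candidate_uv: np.ndarray) -> float:
    p = disc.forward(_to_nchw(color_patch), _to_nchw(candidate_uv))
    return float(p[0])


# ---------------------------------------------------------------------------
# losses (batch arrays NCHW; discriminator may be any object with a
# forward(cond, cand) -> probabilities, e.g. a stub in tests)

def _mean_pixel_l1(y: np.ndarray, g: np.ndarray) -> float:
    """(1/|I|) sum_i meanpix |Y_i - G(X_i)| for an NCHW batch."""
    return float(np.mean(np.abs(y.astype(np.float64) - g.astype(np.float64))))


def generator_loss(x: np.ndarray, y: np.ndarray, gen_out: np.ndarray,
                   disc, lam: float) -> tuple[float, CganLossTerms]:
    """Generator objective on a batch; ``disc`` is only consulted if
    lambda > 0, so the lambda = 0 ablation never touches a discriminator."""
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    l1 = _mean_pixel_l1(y, gen_out)
    adv = 0.0
    if lam > 0:
        p = np.clip(disc.forward(x, gen_out), LOG_EPS, 1 - LOG_EPS)
        adv = float(lam * np.mean(np.log(1.0 - p)))
    terms = CganLossTerms(l1_term=l1, adv_gen_term=adv,
                          disc_real_term=0.0, disc_fake_term=0.0, lam=lam)
    return l1 + adv, terms


def discriminator_loss(x_fake: np.ndarray, gen_out: np.ndarray,
                       x_real: np.ndarray, y_real: np.ndarray, disc,
                       fake_idx=None, real_idx=None) -> float:
    """- (1/|I|) sum log(1 - D(X, G(X))) - (1/|J|) sum log D(X, Y).

    When the sampler provides the index sets, their disjointness is
    enforced: overlapping fake/real indices destabilize training because
    the generator cost then sees its own real targets."""
    if fake_idx is not None and real_idx is not None:
        if set(map(int, fake_idx)) & set(map(int, real_idx)):
            raise ValueError("fake and real index sets must be disjoint")
    pf = np.clip(disc.forward(x_fake, gen_out), LOG_EPS, 1 - LOG_EPS)
    pr = np.clip(disc.forward(x_real, y_real), LOG_EPS, 1 - LOG_EPS)
    return float(-np.mean(np.log(1.0 - pf)) - np.mean(np.log(pr)))


# ---------------------------------------------------------------------------
# training

def _augment(xb, yb, rng):
    """Joint random vertical/horizontal flip and 90-degree rotation."""
    for i in range(xb.shape[0]):
        if rng.random() < 0.5:
            xb[i] = xb[i, :, ::-1]
            yb[i] = yb[i, :, ::-1]
        if rng.random() < 0.5:
            xb[i] = xb[i, :, :, ::-1]
            yb[i] = yb[i, :, :, ::-1]
        k = int(rng.integers(0, 4))
        if k:
            xb[i] = np.rot90(xb[i], k, axes=(1, 2))
            yb[i] = np.rot90(yb[i], k, axes=(1, 2))
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def _gen_step(gen, disc, opt, xb, yb, lam, rng, inst_noise=0.0,
              saturating=False):
    g = gen.forward(xb, train=True, rng=rng)
    n = g.size
    dg = (np.sign(g - yb) / n).astype(nn.F32)
    l1 = _mean_pixel_l1(yb, g)
    adv = 0.0
    if lam > 0 and disc is not None:
        g_in = g
        if inst_noise > 0:
            g_in = g + rng.normal(0, inst_noise, g.shape).astype(nn.F32)
        p = disc.forward(xb, g_in)
        adv = float(lam * np.mean(np.log(np.clip(1 - p, LOG_EPS, None))))
        if saturating:
            dp = (-lam / np.clip(1.0 - disc._p_raw, LOG_EPS, None)) / p.size
        else:
            # d/dp of -lam log p: does not vanish where D rejects fakes
            dp = (-lam / np.clip(disc._p_raw, LOG_EPS, None)) / p.size
        _, dcand = disc.backward(dp.astype(nn.F32))
        dg = dg + dcand
    gen.backward(dg)
    opt.step()
    return l1 + adv


def _accumulate(layers, stash):
    for l, s in zip(layers, stash):
        for k in l.grads:
            l.grads[k] = l.grads[k] + s[k]


def _disc_step(gen, disc, opt, xb, yb, rng, inst_noise=0.0):
    half = xb.shape[0] // 2
    xi, xj, yj = xb[:half], xb[half:], yb[half:]
    g = gen.forward(xi, train=True, rng=rng)
    if inst_noise > 0:
        g = g + rng.normal(0, inst_noise, g.shape).astype(nn.F32)
        yj = yj + rng.normal(0, inst_noise, yj.shape).astype(nn.F32)
    pf = disc.forward(xi, g)
    loss_f = float(-np.mean(np.log(np.clip(1 - pf, LOG_EPS, None))))
    dpf = (1.0 / np.clip(1.0 - disc._p_raw, LOG_EPS, None)) / pf.size
    disc.backward(dpf.astype(nn.F32))
    stash = [{k: v.copy() for k, v in l.grads.items()} for l in disc.layers()]
    pr = disc.forward(xj, yj)
    loss_r = float(-np.mean(np.log(np.clip(pr, LOG_EPS, None))))
    dpr = (-1.0 / np.clip(disc._p_raw, LOG_EPS, None)) / pr.size
    disc.backward(dpr.astype(nn.F32))
    _accumulate(disc.layers(), stash)
    opt.step()
    return loss_f + loss_r


def _val_l1(gen, xv, yv, batch: int = 16) -> float:
    tot, n = 0.0, 0
    for i in range(0, xv.shape[0], batch):
        g = gen.forward(xv[i:i + batch], train=False)
        tot += float(np.abs(g - yv[i:i + batch]).sum())
        n += g.size
    return tot / max(n, 1)


def _val_disc(gen, disc, xv, yv, batch: int = 16) -> float:
    tot, nb = 0.0, 0
    for i in range(0, xv.shape[0], batch):
        xb, yb = xv[i:i + batch], yv[i:i + batch]
        g = gen.forward(xb, train=False)
        tot += discriminator_loss(xb, g, xb, yb, disc)
        nb += 1
    return tot / max(nb, 1)


def train(train_patches, val_patches, gen_config: GeneratorConfig,
          schedule: TrainSchedule,
          disc_config: DiscriminatorConfig | None = None,
          lam: float = 0.005, seed: int = 0,
          log_path=None) -> TrainState:
    """Three-phase CGAN training on pre-extracted patch pairs.

    ``train_patches``/``val_patches`` are (X, Y) tuples with X of shape
    N x S x S x 3 and Y of shape N x S x S (or N x S x S x 1), on [0, 1].
    Phase 1 alternates discriminator and generator updates; phase 2 refines
    the discriminator alone (best by validation discriminator loss); phase 3
    refines the generator alone (best by validation mean per-pixel L1).
    With lambda = 0 only phase 1 runs and only the generator is updated.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    gen_config.validate()
    rng = np.random.default_rng(seed)
    xt = _patches_to_nchw(train_patches[0], 3)
    yt = _patches_to_nchw(train_patches[1], 1)
    if val_patches is not None and len(val_patches[0]):
        xv = _patches_to_nchw(val_patches[0], 3)
        yv = _patches_to_nchw(val_patches[1], 1)
    else:
        import warnings
        warnings.warn("empty validation set: early stopping disabled")
        xv = yv = None
    gen = build_generator(gen_config, seed=seed)
    disc = None
    if lam > 0:
        disc = build_discriminator(disc_config or DiscriminatorConfig(),
                                   gen_config, seed=seed)
    state = TrainState(gen=gen, disc=disc, gen_config=gen_config,
                       disc_config=disc_config if lam > 0 else None,
                       lam=lam, seed=seed)
    g_opt = nn.Adam(gen.layers(), lr=schedule.lr)
    d_opt = nn.Adam(disc.layers(), lr=schedule.lr) if disc else None
    log_rows = []

    def sample_batch():
        idx = rng.integers(0, xt.shape[0], size=schedule.batch_size)
        return _augment(xt[idx].copy(), yt[idx].copy(), rng)

    def validate(it, track_best=True):
        if xv is None:
            return None
        v = _val_l1(gen, xv, yv)
        state.val_l1_trace.append((it, v))
        if track_best and (state.best_val_l1 is None or v < state.best_val_l1[0]):
            state.best_val_l1 = (v, it)
            state._best_gen = gen.get_state()
            state._best_disc = disc.get_state() if disc else None
        return v

    # phase 1: alternating updates (generator-only when lambda == 0)
    state.phase = "joint"
    validate(0)
    for it in range(1, schedule.joint_iters + 1):
        xb, yb = sample_batch()
        d_loss = (_disc_step(gen, disc, d_opt, xb, yb, rng,
                              schedule.instance_noise) if disc else float("nan"))
        g_loss = _gen_step(gen, disc, g_opt, xb, yb, lam, rng,
                           schedule.instance_noise, schedule.saturating_adv)
        state.iteration = it
        state.train_loss_trace.append((it, g_loss, d_loss))
        if it % schedule.val_every == 0 or it == schedule.joint_iters:
            v = validate(it)
            log_rows.append((it, g_loss, d_loss, v))
    if xv is not None and getattr(state, "_best_gen", None) is not None:
        gen.set_state(state._best_gen)
        if disc is not None and state._best_disc is not None:
            disc.set_state(state._best_disc)

    if disc is not None:
        # phase 2: discriminator only, best by validation discriminator loss
        state.phase = "disc_only"
        best_d = (np.inf, disc.get_state())
        for it in range(1, schedule.disc_only_iters + 1):
            xb, yb = sample_batch()
            _disc_step(gen, disc, d_opt, xb, yb, rng,
                       schedule.instance_noise)
            if xv is not None and (it % schedule.val_every == 0
                                   or it == schedule.disc_only_iters):
                vd = _val_disc(gen, disc, xv, yv)
                if vd < best_d[0]:
                    best_d = (vd, disc.get_state())
        if xv is not None and np.isfinite(best_d[0]):
            disc.set_state(best_d[1])

        # phase 3: generator only, best by validation mean per-pixel L1
        state.phase = "gen_only"
        for it in range(1, schedule.gen_only_iters + 1):
            xb, yb = sample_batch()
            g_loss = _gen_step(gen, disc, g_opt, xb, yb, lam, rng,
                               schedule.instance_noise,
                               schedule.saturating_adv)
            total = schedule.joint_iters + it
            state.iteration = total
            if it % schedule.val_every == 0 or it == schedule.gen_only_iters:
                v = validate(total)
                log_rows.append((total, g_loss, float("nan"), v))
        if xv is not None and getattr(state, "_best_gen", None) is not None:
            gen.set_state(state._best_gen)

    state.phase = "done"
    if log_path is not None:
        lines = ["iteration\tg_loss\td_loss\tval_l1"]
        lines += [f"{i}\t{g}\t{d}\t{v}" for i, g, d, v in log_rows]
        Path(log_path).write_text("\n".join(lines) + "\n")
    return state


def _patches_to_nchw(arr, channels: int) -> np.ndarray:
    a = np.asarray(arr, dtype=nn.F32)
    if a.ndim == 3:
        a = a[:, :, :, None]
    if a.shape[3] != channels and channels == 1:
        a = a.mean(axis=3, keepdims=True)
    return np.ascontiguousarray(a.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# whole-image conversion

def convert_image(gen: nn.UNet, color: np.ndarray,
                  face_map: np.ndarray | None = None,
                  patch_size: int | None = None, stride: int | None = None,
                  min_mask_fraction: float = 0.3,
                  batch: int = 16) -> np.ndarray:
    """Plan grid -> extract -> convert each patch -> assemble.

    Pixels outside every converted window fall back to the grayscale of the
    input, so the returned image is defined everywhere.
    """
    if patch_size is None:
        raise ValueError("patch_size is required")
    grid = patch_ops.plan_grid(color.shape[:2], patch_size, stride or patch_size,
                               region_mask=face_map,
                               min_mask_fraction=min_mask_fraction)
    patches = patch_ops.extract(color, grid)
    outs = []
    for i in range(0, len(patches), batch):
        xb = np.ascontiguousarray(
            np.stack(patches[i:i + batch]).transpose(0, 3, 1, 2)).astype(nn.F32)
        yb = gen.forward(xb, train=False)
        outs.extend(yb[:, 0].astype(np.float64))
    return patch_ops.assemble(outs, grid, fill_image=grayscale(color))


# ---------------------------------------------------------------------------
# checkpoints

def save_state(state: TrainState, path) -> None:
    path = Path(path)
    arrays = {}
    for i, p in enumerate(state.gen.get_state()):
        for k, v in p.items():
            arrays[f"gen_{i}_{k}"] = v
    if state.disc is not None:
        for i, p in enumerate(state.disc.get_state()):
            for k, v in p.items():
                arrays[f"disc_{i}_{k}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    gcfg = asdict(state.gen_config)
    if gcfg.get("dropout_levels") is not None:
        gcfg["dropout_levels"] = list(gcfg["dropout_levels"])
    meta = {"gen_config": gcfg,
            "disc_config": asdict(state.disc_config) if state.disc_config else None,
            "lam": state.lam, "seed": state.seed,
            "iteration": state.iteration,
            "best_val_l1": list(state.best_val_l1) if state.best_val_l1 else None,
            "val_l1_trace": state.val_l1_trace}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_state(path) -> TrainState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    gcfg = dict(meta["gen_config"])
    if gcfg.get("dropout_levels") is not None:
        gcfg["dropout_levels"] = tuple(gcfg["dropout_levels"])
    gen_config = GeneratorConfig(**gcfg)
    gen = build_generator(gen_config, seed=meta["seed"])
    data = np.load(path.with_suffix(".npz"))
    gstate = []
    for i, p in enumerate(gen.get_state()):
        gstate.append({k: data[f"gen_{i}_{k}"] for k in p})
    gen.set_state(gstate)
    disc = None
    disc_config = None
    if meta["disc_config"] is not None:
        disc_config = DiscriminatorConfig(**meta["disc_config"])
        disc = build_discriminator(disc_config, gen_config, seed=meta["seed"])
        dstate = []
        for i, p in enumerate(disc.get_state()):
            dstate.append({k: data[f"disc_{i}_{k}"] for k in p})
        disc.set_state(dstate)
    state = TrainState(gen=gen, disc=disc, gen_config=gen_config,
                       disc_config=disc_config, lam=meta["lam"],
                       seed=meta["seed"], iteration=meta["iteration"],
                       phase="done",
                       best_val_l1=tuple(meta["best_val_l1"]) if meta["best_val_l1"] else None,
                       val_l1_trace=[tuple(t) for t in meta["val_l1_trace"]])
    return state
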