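"""Cross-contrast translation models: CycleGAN and DC2Anet.

Two generators map between the domains (A = T2W-like, B = FLAIR-like) and
two patch discriminators score realism.  CycleGAN trains unpaired with
adversarial + cycle-consistency losses; DC2Anet trains semi-supervised
with a conditional discriminator (scoring a source/candidate pair) and
four auxiliary supervised losses — voxel-wise L1, gradient-difference,
perceptual (discriminator features) and structural (1 - SSIM).

Total CycleGAN objective:
    L = lambda_GAN * (adversarial A->B + adversarial B->A)
        + lambda_cyc * (forward cycle L1 + backward cycle L1)
with defaults lambda_cyc = 10 and lambda_GAN = 1.

The training schedule follows the reference recipe: Adam (beta1 = 0.5),
constant learning rate 2e-4 then linear decay to 0, three generator
update iterations per discriminator iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter

from . import nn
from .phantom import PairedSlice

__all__ = [
    "GANSpec", "TrainSchedule", "TranslatorPair",
    "build_generator", "build_discriminator", "build_pair",
    "adversarial_loss", "cycle_consistency_loss", "cyclegan_total_loss",
    "auxiliary_losses", "ssim_loss", "dc2anet_sup_loss",
    "train", "translate", "save_checkpoint", "load_checkpoint",
]

_EPS = 1e-7
_SUP_TERMS = ("adversarial", "cycle", "voxel", "gradient", "perceptual",
              "structural")


@dataclass
class GANSpec:
    """Model configuration.  Reference-scale values: image_size 256,
    base_channels 64, 9 residual blocks; desk-scale tests use much smaller
    widths."""

    image_size: int = 256
    base_channels: int = 64
    n_res_blocks: int = 9
    lambda_cyc: float = 10.0
    lambda_gan: float = 1.0
    sup_weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in _SUP_TERMS}
    )
    model_kind: str = "cyclegan"  # or "dc2anet"
    adversarial_form: str = "log"  # "log" (cross-entropy) or "lsgan"

    def __post_init__(self) -> None:
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if self.lambda_cyc < 0 or self.lambda_gan < 0:
            raise ValueError("loss weights must be >= 0")
        if self.model_kind not in ("cyclegan", "dc2anet"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        missing = set(_SUP_TERMS) - set(self.sup_weights)
        if missing:
            raise ValueError(f"sup_weights missing terms: {sorted(missing)}")
        if any(v < 0 for v in self.sup_weights.values()):
            raise ValueError("sup_weights must be >= 0")


@dataclass
class TrainSchedule:
    """Optimization schedule.  Reference values: 400 epochs, batch 2,
    lr 2e-4 constant for 200 epochs then linearly decayed to 0, three
    generator iterations per discriminator iteration."""

    epochs: int = 400
    batch_size: int = 2
    lr_initial: float = 2e-4
    decay_start_epoch: int = 200
    gen_iters: int = 3
    disc_iters: int = 1
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """lr(e): constant before decay_start_epoch, then linear to 0 at
        ``epochs``."""
        if epoch < self.decay_start_epoch:
            return self.lr_initial
        span = self.epochs - self.decay_start_epoch
        frac = max(0.0, (self.epochs - epoch) / span)
        return self.lr_initial * frac


@dataclass
class TranslatorPair:
    G_A2B: nn.Sequential
    G_B2A: nn.Sequential
    D_B: nn.Sequential  # realism of domain-B images (outputs of G_A2B)
    D_A: nn.Sequential
    spec: GANSpec


def build_generator(spec: GANSpec, rng: np.random.Generator | None = None) -> nn.Sequential:
    """7x7 conv -> two stride-2 downsamples -> residual blocks -> two
    nearest-neighbour upsample stages -> 7x7 conv -> sigmoid, instance
    normalization throughout.  Maps [0,1] images to [0,1] images."""
    rng = rng or np.random.default_rng(0)
    c = spec.base_channels
    layers: list[nn.Module] = [
        nn.Conv2d(1, c, 7, 1, 3, rng=rng), nn.InstanceNorm2d(c), nn.ReLU(),
        nn.Conv2d(c, 2 * c, 3, 2, 1, rng=rng), nn.InstanceNorm2d(2 * c), nn.ReLU(),
        nn.Conv2d(2 * c, 4 * c, 3, 2, 1, rng=rng), nn.InstanceNorm2d(4 * c), nn.ReLU(),
    ]
    layers += [nn.ResBlock(4 * c, rng=rng) for _ in range(spec.n_res_blocks)]
    layers += [
        nn.Upsample2x(), nn.Conv2d(4 * c, 2 * c, 3, 1, 1, rng=rng),
        nn.InstanceNorm2d(2 * c), nn.ReLU(),
        nn.Upsample2x(), nn.Conv2d(2 * c, c, 3, 1, 1, rng=rng),
        nn.InstanceNorm2d(c), nn.ReLU(),
        nn.Conv2d(c, 1, 7, 1, 3, rng=rng), nn.Sigmoid(),
    ]
    return nn.Sequential(*layers)


def build_discriminator(
    spec: GANSpec, conditional: bool = False, rng: np.random.Generator | None = None
) -> nn.Sequential:
    """Strided-convolution patch classifier with instance normalization.

    The conditional variant consumes the channel-concatenation of the
    source image and the candidate target (2 input channels)."""
    rng = rng or np.random.default_rng(0)
    c = spec.base_channels
    in_ch = 2 if conditional else 1
    return nn.Sequential(
        nn.Conv2d(in_ch, c, 4, 2, 1, rng=rng), nn.LeakyReLU(0.2),
        nn.Conv2d(c, 2 * c, 4, 2, 1, rng=rng), nn.InstanceNorm2d(2 * c),
        nn.LeakyReLU(0.2),
        nn.Conv2d(2 * c, 4 * c, 4, 2, 1, rng=rng), nn.InstanceNorm2d(4 * c),
        nn.LeakyReLU(0.2),
        nn.Conv2d(4 * c, 1, 4, 1, 1, rng=rng), nn.Sigmoid(),
    )


def build_pair(spec: GANSpec, seed: int = 0) -> TranslatorPair:
    rng = np.random.default_rng(seed)
    conditional = spec.model_kind == "dc2anet"
    return TranslatorPair(
        G_A2B=build_generator(spec, rng),
        G_B2A=build_generator(spec, rng),
        D_B=build_discriminator(spec, conditional, rng),
        D_A=build_discriminator(spec, conditional, rng),
        spec=spec,
    )


# ---------------------------------------------------------------- losses


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).mean())


def _l1_grad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d mean|a - b| / da."""
    return np.sign(a - b) / a.size


def adversarial_loss(
    D: nn.Sequential, real_batch: np.ndarray, fake_batch: np.ndarray,
    form: str = "log",
) -> tuple[float, float]:
    """(generator term, discriminator term) for one discriminator.

    Log form (natural-log cross-entropy): the discriminator minimizes
    -E[log D(real)] - E[log(1 - D(fake))]; the generator minimizes
    -E[log D(fake)].  The least-squares variant replaces the logs with
    squared distances to the 1/0 targets.
    """
    d_real = np.clip(D.forward(real_batch), _EPS, 1 - _EPS)
    d_fake = np.clip(D.forward(fake_batch), _EPS, 1 - _EPS)
    if form == "log":
        disc = float(-np.log(d_real).mean() - np.log(1 - d_fake).mean())
        gen = float(-np.log(d_fake).mean())
    elif form == "lsgan":
        disc = float(((d_real - 1) ** 2).mean() + (d_fake**2).mean())
        gen = float(((d_fake - 1) ** 2).mean())
    else:
        raise ValueError(f"unknown adversarial form {form!r}")
    return gen, disc


def cycle_consistency_loss(
    G_A2B: nn.Sequential, G_B2A: nn.Sequential,
    batch_A: np.ndarray, batch_B: np.ndarray,
) -> float:
    """Mean L1 of the forward cycle A->B->A plus the backward cycle
    B->A->B."""
    if batch_A.shape[2:] != batch_B.shape[2:]:
        raise ValueError("domain batches must share spatial shape")
    rec_A = G_B2A.forward(G_A2B.forward(batch_A))
    rec_B = G_A2B.forward(G_B2A.forward(batch_B))
    return _l1(rec_A, batch_A) + _l1(rec_B, batch_B)


def cyclegan_total_loss(
    pair: TranslatorPair, batch_A: np.ndarray, batch_B: np.ndarray,
    spec: GANSpec | None = None,
) -> float:
    """lambda_GAN * (both generator adversarial terms) + lambda_cyc *
    cycle-consistency loss."""
    spec = spec or pair.spec
    fake_B = pair.G_A2B.forward(batch_A)
    fake_A = pair.G_B2A.forward(batch_B)
    gen_ab, _ = adversarial_loss(pair.D_B, batch_B, fake_B, spec.adversarial_form)
    gen_ba, _ = adversarial_loss(pair.D_A, batch_A, fake_A, spec.adversarial_form)
    cyc = cycle_consistency_loss(pair.G_A2B, pair.G_B2A, batch_A, batch_B)
    return spec.lambda_gan * (gen_ab + gen_ba) + spec.lambda_cyc * cyc


def _grad_diff_loss(gen: np.ndarray, tgt: np.ndarray, with_grad: bool = False):
    """Mean L1 between finite-difference gradient magnitudes along rows
    and columns."""
    loss = 0.0
    dgen = np.zeros_like(gen) if with_grad else None
    for axis in (2, 3):
        gu = np.abs(np.diff(gen, axis=axis))
        gv = np.abs(np.diff(tgt, axis=axis))
        loss += float(np.abs(gu - gv).mean())
        if with_grad:
            s = np.sign(gu - gv) * np.sign(np.diff(gen, axis=axis)) / gu.size
            sl_hi = [slice(None)] * 4
            sl_lo = [slice(None)] * 4
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            dgen[tuple(sl_hi)] += s
            dgen[tuple(sl_lo)] -= s
    return (loss, dgen) if with_grad else loss


def ssim_loss(
    gen: np.ndarray, tgt: np.ndarray, win: int = 7,
    c1: float = 0.01**2, c2: float = 0.03**2, with_grad: bool = False,
):
    """1 - mean SSIM over a box window (data range 1), optionally with the
    analytic gradient with respect to ``gen``.

    The box filter uses zero padding, which makes the filtering operator
    self-adjoint and the backward pass exact.
    """
    F = lambda a: uniform_filter(a, size=(1, 1, win, win), mode="constant")
    x, y = gen, tgt
    m1, m2 = F(x), F(y)
    e1, e12 = F(x * x), F(x * y)
    e2 = F(y * y)
    a1 = 2 * m1 * m2 + c1
    a2 = 2 * (e12 - m1 * m2) + c2
    b1 = m1 * m1 + m2 * m2 + c1
    b2 = (e1 - m1 * m1) + (e2 - m2 * m2) + c2
    s = (a1 * a2) / (b1 * b2)
    loss = float(1.0 - s.mean())
    if not with_grad:
        return loss
    n = s.size
    g_m1 = (2 * m2 * a2 - 2 * m2 * a1) / (b1 * b2) - s * (2 * m1 / b1 - 2 * m1 / b2)
    g_e1 = -s / b2
    g_e12 = 2 * a1 / (b1 * b2)
    ds_dx = F(g_m1) + 2 * x * F(g_e1) + y * F(g_e12)
    return loss, -ds_dx / n


def _perceptual_loss(
    disc: nn.Sequential, gen_in: np.ndarray, tgt_in: np.ndarray,
    with_grad: bool = False,
):
    """Mean L1 between the discriminator's intermediate activations for the
    generated and the target input.  When ``with_grad`` is set, the
    returned gradient is with respect to ``gen_in``."""
    _, f_tgt = disc.forward_collect(tgt_in)
    f_tgt = [f.copy() for f in f_tgt]
    out, f_gen = disc.forward_collect(gen_in)
    k = len(f_gen)
    loss = sum(_l1(a, b) for a, b in zip(f_gen, f_tgt)) / k
    if not with_grad:
        return loss
    inject: dict[int, np.ndarray] = {}
    fi = 0
    for i, layer in enumerate(disc.layers):
        if isinstance(layer, (nn.LeakyReLU, nn.ReLU)):
            inject[i] = _l1_grad(f_gen[fi], f_tgt[fi]) / k
            fi += 1
    dy = np.zeros_like(out)
    for i in reversed(range(len(disc.layers))):
        if i in inject:
            dy = dy + inject[i]
        dy = disc.layers[i].backward(dy)
    return loss, dy


def auxiliary_losses(
    generated: np.ndarray, target: np.ndarray,
    disc: nn.Sequential | None = None,
) -> dict[str, float]:
    """The four supervised auxiliary losses on an aligned batch pair:
    voxel-wise L1, gradient-difference, perceptual (needs a discriminator
    for its feature maps; omitted as 0 otherwise) and structural
    (1 - mean SSIM)."""
    if generated.shape != target.shape:
        raise ValueError("generated and target must share one shape")
    out = {
        "voxel": _l1(generated, target),
        "gradient": _grad_diff_loss(generated, target),
        "structural": ssim_loss(generated, target),
    }
    out["perceptual"] = (
        _perceptual_loss(disc, generated, target) if disc is not None else 0.0
    )
    return out


def _concat_cond(source: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    return np.concatenate([source, candidate], axis=1)


def dc2anet_sup_loss(
    pair: TranslatorPair, batch_A: np.ndarray, batch_B: np.ndarray,
    spec: GANSpec | None = None,
) -> float:
    """Supervised objective L_sup: weighted sum of the conditional
    adversarial generator terms, the dual cycle-consistency term, and the
    four auxiliary losses, for both mapping directions (unit weights by
    default)."""
    spec = spec or pair.spec
    if batch_A.shape != batch_B.shape:
        raise ValueError("supervised terms need aligned paired batches")
    w = spec.sup_weights
    fake_B = pair.G_A2B.forward(batch_A)
    fake_A = pair.G_B2A.forward(batch_B)
    gen_ab, _ = adversarial_loss(
        pair.D_B, _concat_cond(batch_A, batch_B), _concat_cond(batch_A, fake_B),
        spec.adversarial_form,
    )
    gen_ba, _ = adversarial_loss(
        pair.D_A, _concat_cond(batch_B, batch_A), _concat_cond(batch_B, fake_A),
        spec.adversarial_form,
    )
    cyc = cycle_consistency_loss(pair.G_A2B, pair.G_B2A, batch_A, batch_B)
    total = w["adversarial"] * (gen_ab + gen_ba) + w["cycle"] * cyc
    for gen_img, tgt, disc, src in (
        (fake_B, batch_B, pair.D_B, batch_A),
        (fake_A, batch_A, pair.D_A, batch_B),
    ):
        aux = auxiliary_losses(gen_img, tgt, disc=None)
        aux["perceptual"] = _perceptual_loss(
            disc, _concat_cond(src, gen_img), _concat_cond(src, tgt)
        )
        for k in ("voxel", "gradient", "perceptual", "structural"):
            total += w[k] * aux[k]
    return float(total)


# ---------------------------------------------------------------- training


def _bce_gen_grad(d: np.ndarray, form: str) -> np.ndarray:
    """d(generator adversarial term)/d(D output)."""
    if form == "log":
        return -1.0 / (np.maximum(d, _EPS) * d.size)
    return 2.0 * (d - 1.0) / d.size  # lsgan


def _gen_adv_backward(G, D, source, form, weight, conditional_src=None):
    """Fresh forward of one adversarial generator term, then backward into
    G's parameter grads.  Returns the loss value."""
    fake = G.forward(source)
    d_in = fake if conditional_src is None else _concat_cond(conditional_src, fake)
    d = D.forward(d_in)
    dc = np.clip(d, _EPS, 1 - _EPS)
    loss = float(-np.log(dc).mean()) if form == "log" else float(((dc - 1) ** 2).mean())
    dx = D.backward(weight * _bce_gen_grad(dc, form))
    if conditional_src is not None:
        dx = dx[:, 1:2]  # only the candidate channel feeds the generator
    G.backward(dx)
    return loss


def _gen_direction_backward(G_fwd, G_rev, D, source, form, w_adv, w_cyc,
                            conditional: bool = False):
    """One fused generator update direction: a single forward of G_fwd
    feeds both the adversarial branch (through D) and the cycle branch
    (through G_rev); the two input gradients are summed before the single
    G_fwd backward.  Returns (adversarial value, cycle value)."""
    fake = G_fwd.forward(source)
    d_in = _concat_cond(source, fake) if conditional else fake
    d = np.clip(D.forward(d_in), _EPS, 1 - _EPS)
    adv = float(-np.log(d).mean()) if form == "log" else float(((d - 1) ** 2).mean())
    dx_adv = D.backward(w_adv * _bce_gen_grad(d, form))
    if conditional:
        dx_adv = dx_adv[:, 1:2]
    rec = G_rev.forward(fake)
    cyc = _l1(rec, source)
    dx_cyc = G_rev.backward(w_cyc * _l1_grad(rec, source))
    G_fwd.backward(dx_adv + dx_cyc)
    return adv, cyc


def _cycle_backward(G_first, G_second, source, weight):
    """Forward cycle source -> G_first -> G_second ~ source, backward into
    both generators.  Returns the (unweighted) L1 value."""
    mid = G_first.forward(source)
    rec = G_second.forward(mid)
    loss = _l1(rec, source)
    dmid = G_second.backward(weight * _l1_grad(rec, source))
    G_first.backward(dmid)
    return loss


def _disc_step(D, real_in, fake_in, opt, lr, form):
    D.zero_grad()
    d_real = D.forward(real_in)
    dc = np.clip(d_real, _EPS, 1 - _EPS)
    if form == "log":
        loss = float(-np.log(dc).mean())
        D.backward(-1.0 / (np.maximum(dc, _EPS) * dc.size))
    else:
        loss = float(((dc - 1) ** 2).mean())
        D.backward(2.0 * (dc - 1.0) / dc.size)
    d_fake = D.forward(fake_in)
    dcf = np.clip(d_fake, _EPS, 1 - _EPS)
    if form == "log":
        loss += float(-np.log(1 - dcf).mean())
        D.backward(1.0 / (np.maximum(1 - dcf, _EPS) * dcf.size))
    else:
        loss += float((dcf**2).mean())
        D.backward(2.0 * dcf / dcf.size)
    opt.step(lr)
    return loss


def _zero_all(pair: TranslatorPair) -> None:
    for net in (pair.G_A2B, pair.G_B2A, pair.D_B, pair.D_A):
        net.zero_grad()


def train(
    dataset: list[PairedSlice],
    spec: GANSpec,
    schedule: TrainSchedule,
    verbose: bool = False,
) -> tuple[TranslatorPair, "pd.DataFrame"]:
    """Train a translator pair on paired slices; seeded and reproducible.

    Per batch step: ``gen_iters`` generator updates followed by
    ``disc_iters`` discriminator updates.  DC2Anet alternates one
    supervised step (conditional adversarial + cycle + the four auxiliary
    losses) with one unsupervised step (cycle-consistency only) on
    successive batches.  Returns the trained pair and a per-epoch loss
    history.
    """
    import pandas as pd

    if len(dataset) < 2:
        raise ValueError("need at least 2 training pairs")
    rng = np.random.default_rng(schedule.seed)
    pair = build_pair(spec, seed=schedule.seed)
    conditional = spec.model_kind == "dc2anet"
    form = spec.adversarial_form

    gen_params = pair.G_A2B.parameters() + pair.G_B2A.parameters()
    opt_gen = nn.Adam(gen_params, lr=schedule.lr_initial)
    opt_db = nn.Adam(pair.D_B.parameters(), lr=schedule.lr_initial)
    opt_da = nn.Adam(pair.D_A.parameters(), lr=schedule.lr_initial)

    A = np.stack([p.image_A for p in dataset])[:, None].astype(nn.DTYPE)
    B = np.stack([p.image_B for p in dataset])[:, None].astype(nn.DTYPE)
    n = len(dataset)
    history = []
    step_parity = 0
    for epoch in range(schedule.epochs):
        lr = schedule.learning_rate(epoch)
        order = rng.permutation(n)
        ep = {"adv": 0.0, "cycle": 0.0, "disc": 0.0, "sup_aux": 0.0, "batches": 0}
        for start in range(0, n - schedule.batch_size + 1, schedule.batch_size):
            idx = order[start : start + schedule.batch_size]
            bA, bB = A[idx], B[idx]
            supervised = conditional and step_parity % 2 == 0
            step_parity += 1

            for _ in range(schedule.gen_iters):
                _zero_all(pair)
                adv = cyc = aux_total = 0.0
                if not conditional:
                    a1, c1 = _gen_direction_backward(
                        pair.G_A2B, pair.G_B2A, pair.D_B, bA, form,
                        spec.lambda_gan, spec.lambda_cyc)
                    a2, c2 = _gen_direction_backward(
                        pair.G_B2A, pair.G_A2B, pair.D_A, bB, form,
                        spec.lambda_gan, spec.lambda_cyc)
                    adv += a1 + a2
                    cyc += c1 + c2
                elif supervised:
                    w = spec.sup_weights
                    a1, c1 = _gen_direction_backward(
                        pair.G_A2B, pair.G_B2A, pair.D_B, bA, form,
                        w["adversarial"], w["cycle"], conditional=True)
                    a2, c2 = _gen_direction_backward(
                        pair.G_B2A, pair.G_A2B, pair.D_A, bB, form,
                        w["adversarial"], w["cycle"], conditional=True)
                    adv += a1 + a2
                    cyc += c1 + c2
                    aux_total += _sup_aux_backward(pair, bA, bB, w)
                else:  # unsupervised step: cycle-consistency objective
                    cyc += _cycle_backward(pair.G_A2B, pair.G_B2A, bA,
                                           spec.lambda_cyc)
                    cyc += _cycle_backward(pair.G_B2A, pair.G_A2B, bB,
                                           spec.lambda_cyc)
                if not np.isfinite(adv + cyc + aux_total):
                    raise FloatingPointError(
                        f"non-finite generator loss at epoch {epoch}"
                    )
                opt_gen.step(lr)
                ep["adv"] += adv
                ep["cycle"] += cyc
                ep["sup_aux"] += aux_total

            for _ in range(schedule.disc_iters):
                fake_B = pair.G_A2B.forward(bA)
                fake_A = pair.G_B2A.forward(bB)
                if conditional:
                    dloss = _disc_step(pair.D_B, _concat_cond(bA, bB),
                                       _concat_cond(bA, fake_B), opt_db, lr, form)
                    dloss += _disc_step(pair.D_A, _concat_cond(bB, bA),
                                        _concat_cond(bB, fake_A), opt_da, lr, form)
                else:
                    dloss = _disc_step(pair.D_B, bB, fake_B, opt_db, lr, form)
                    dloss += _disc_step(pair.D_A, bA, fake_A, opt_da, lr, form)
                if not np.isfinite(dloss):
                    raise FloatingPointError(
                        f"non-finite discriminator loss at epoch {epoch}"
                    )
                ep["disc"] += dloss
            ep["batches"] += 1

        nb = max(ep["batches"], 1)
        row = {
            "epoch": epoch, "lr": lr,
            "adv_loss": ep["adv"] / (nb * schedule.gen_iters),
            "cycle_loss": ep["cycle"] / (nb * schedule.gen_iters),
            "sup_aux_loss": ep["sup_aux"] / (nb * schedule.gen_iters),
            "disc_loss": ep["disc"] / (nb * schedule.disc_iters),
        }
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:4d}  lr={lr:.2e}  cycle={row['cycle_loss']:.4f}"
                f"  adv={row['adv_loss']:.4f}  disc={row['disc_loss']:.4f}"
            )
    return pair, pd.DataFrame(history)


def _sup_aux_backward(pair: TranslatorPair, bA, bB, w) -> float:
    """Backward passes of the four auxiliary supervised losses for both
    directions; accumulates generator gradients, returns the summed value."""
    total = 0.0
    for G, D, src, tgt in (
        (pair.G_A2B, pair.D_B, bA, bB),
        (pair.G_B2A, pair.D_A, bB, bA),
    ):
        fake = G.forward(src)
        dfake = np.zeros_like(fake)
        total += w["voxel"] * _l1(fake, tgt)
        dfake += w["voxel"] * _l1_grad(fake, tgt)
        gl, gg = _grad_diff_loss(fake, tgt, with_grad=True)
        total += w["gradient"] * gl
        dfake += w["gradient"] * gg
        sl, sg = ssim_loss(fake, tgt, with_grad=True)
        total += w["structural"] * sl
        dfake += w["structural"] * sg
        pl, pg = _perceptual_loss(
            D, _concat_cond(src, fake), _concat_cond(src, tgt), with_grad=True
        )
        total += w["perceptual"] * pl
        dfake += w["perceptual"] * pg[:, 1:2]
        G.backward(dfake)
    return total


def translate(
    pair: TranslatorPair, image: np.ndarray, direction: str = "A2B"
) -> np.ndarray:
    """Apply one trained generator to a single [0,1] 2D image."""
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("input intensities must lie in [0, 1]")
    G = {"A2B": pair.G_A2B, "B2A": pair.G_B2A}.get(direction)
    if G is None:
        raise ValueError("direction must be 'A2B' or 'B2A'")
    out = G.forward(image[None, None])
    return out[0, 0]


# ------------------------------------------------------------- checkpoints


def save_checkpoint(path: str | Path, pair: TranslatorPair,
                    schedule: TrainSchedule | None = None) -> None:
    """Store spec, schedule and all network weights (npz + json sidecar)."""
    path = Path(path)
    arrays = {}
    for name, net in (("G_A2B", pair.G_A2B), ("G_B2A", pair.G_B2A),
                      ("D_B", pair.D_B), ("D_A", pair.D_A)):
        for i, p in enumerate(net.parameters()):
            arrays[f"{name}__{i}"] = p.value
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"spec": asdict(pair.spec)}
    if schedule is not None:
        meta["schedule"] = asdict(schedule)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TranslatorPair:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = GANSpec(**meta["spec"])
    pair = build_pair(spec, seed=0)
    data = np.load(path.with_suffix(".npz"))
    for name, net in (("G_A2B", pair.G_A2B), ("G_B2A", pair.G_B2A),
                      ("D_B", pair.D_B), ("D_A", pair.D_A)):
        for i, p in enumerate(net.parameters()):
            p.value[...] = data[f"{name}__{i}"]
    return pair
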