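"""Loss composition and optimization schedule for task-assisted training.

The paired model combines five losses: the generation loss GEN (task-network
discrepancy between the synthetic image's task prediction and the ground
truth annotation), the task loss TL (same discrepancy on the real image,
used to train the task network itself), the adversarial generator loss GAN,
and the discriminator losses DR / DG on real and generated images.  Each
optimization step alternates one Adam update of the discriminator, one of
the generator and one of the task network, in that order.  Disabling the
task term and replacing GEN by a pixel-wise MSE recovers the plain
conditional-GAN baseline ("pix2pix" ablation).

The unpaired cycle variant adds the cycle-reconstruction loss CYC and
computes GEN as the (frozen, pretrained) task network's discrepancy between
the real fixed-domain image and its end-of-cycle reconstruction; the live
cycle carries no task term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .nets import Generator, PatchDiscriminator, TaskNetwork, _make_dropout_masks

__all__ = [
    "LossWeights",
    "LossBundle",
    "TrainingStateError",
    "Adam",
    "tagan_losses",
    "tagan_step",
    "cycle_losses",
    "fit_tagan",
]


class TrainingStateError(RuntimeError):
    """A loss component became non-finite; carries the offending batch."""

    def __init__(self, message: str, batch_dump: dict | None = None):
        super().__init__(message)
        self.batch_dump = batch_dump or {}


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the loss components.

    ``class_weights`` scales each task-output channel's contribution to
    GEN/TL (the published live model weighted the fibre class by 2.5 against
    class imbalance).  ``adversarial`` selects sigmoid binary cross-entropy
    (default) or least-squares adversarial losses.  ``ablation`` replaces
    GEN by a pixel-wise MSE against the real image, removing task
    assistance.
    """

    lambda_gen: float = 100.0
    lambda_gan: float = 1.0
    lambda_cyc: float = 10.0
    class_weights: tuple[float, ...] | None = None
    adversarial: str = "bce"
    ablation: bool = False


@dataclass
class LossBundle:
    """One evaluation of every loss component (all non-negative)."""

    gen: float
    tl: float
    gan: float
    dr: float
    dg: float
    cyc: float = 0.0
    weights: LossWeights = field(default_factory=LossWeights)

    @property
    def total(self) -> float:
        w = self.weights
        return (
            w.lambda_gen * self.gen + self.tl + w.lambda_gan * self.gan
            + self.dr + self.dg + w.lambda_cyc * self.cyc
        )

    def check_finite(self, batch_dump: dict | None = None) -> "LossBundle":
        vals = dict(gen=self.gen, tl=self.tl, gan=self.gan, dr=self.dr,
                    dg=self.dg, cyc=self.cyc)
        bad = [k for k, v in vals.items() if not np.isfinite(v)]
        if bad:
            raise TrainingStateError(
                f"non-finite loss component(s): {bad}", batch_dump
            )
        return self


# ---------------------------------------------------------------------------
# Loss primitives (autograd-compatible)
# ---------------------------------------------------------------------------

def _softplus(x):
    return anp.logaddexp(0.0, x)


def _adv_real(logits, kind):
    """Adversarial loss for logits that should be classified as real."""
    if kind == "bce":
        return anp.mean(_softplus(-logits))
    return anp.mean((logits - 1.0) ** 2)


def _adv_fake(logits, kind):
    """Adversarial loss for logits that should be classified as fake."""
    if kind == "bce":
        return anp.mean(_softplus(logits))
    return anp.mean(logits ** 2)


def _weighted_mse(pred, target, class_weights):
    if class_weights is None:
        return anp.mean((pred - target) ** 2)
    w = anp.asarray(class_weights, dtype=np.float64)
    per_class = anp.mean((pred - target) ** 2, axis=(0, 2, 3))
    return anp.sum(w * per_class) / len(w)


def _call(fn_or_net, *args):
    if hasattr(fn_or_net, "apply"):
        return fn_or_net.apply(*args)
    return fn_or_net(*args)


def _batched(x):
    x = np.asarray(x, dtype=np.float64)
    return x[None, None] if x.ndim == 2 else (x[None] if x.ndim == 3 else x)


# ---------------------------------------------------------------------------
# Paired TA-GAN losses
# ---------------------------------------------------------------------------

def tagan_losses(
    real_hr: np.ndarray,
    fake_hr: np.ndarray,
    annotation: np.ndarray,
    task_net,
    discriminator,
    lr_input: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> LossBundle:
    """Evaluate every paired-training loss component on one batch.

    ``task_net`` maps an image to its task prediction; ``discriminator``
    maps ``(lr, img)`` to patch logits.  Both may be trained networks or
    plain callables (stubs).  Pure: same inputs give the same bundle.
    """
    real_hr, fake_hr = _batched(real_hr), _batched(fake_hr)
    annotation, lr_input = _batched(annotation), _batched(lr_input)
    kind = weights.adversarial

    if weights.ablation:
        gen = float(np.mean((fake_hr - real_hr) ** 2))
    else:
        gen = float(_weighted_mse(
            _batched(_call(task_net, fake_hr)), annotation, weights.class_weights
        ))
    tl = float(_weighted_mse(
        _batched(_call(task_net, real_hr)), annotation, weights.class_weights
    ))
    d_fake = _call(discriminator, lr_input, fake_hr)
    d_real = _call(discriminator, lr_input, real_hr)
    gan = float(_adv_real(d_fake, kind))
    dr = float(_adv_real(d_real, kind))
    dg = float(_adv_fake(d_fake, kind))
    dump = {"lr": lr_input, "real_hr": real_hr, "fake_hr": fake_hr}
    return LossBundle(gen=gen, tl=tl, gan=gan, dr=dr, dg=dg,
                      weights=weights).check_finite(dump)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam on a parameter pytree (momenta beta1=0.5, beta2=0.999)."""

    def __init__(self, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, params, grads):
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        if self.m is None:
            self.m = np.zeros_like(flat_p)
            self.v = np.zeros_like(flat_p)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * flat_g
        self.v = self.beta2 * self.v + (1 - self.beta2) * flat_g ** 2
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return unflatten(flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _clip_grads(grads, cap: float | None):
    """Global-norm gradient clipping; returns (grads, clipped?)."""
    if cap is None:
        return grads, False
    flat, unflatten = flatten(grads)
    norm = float(np.linalg.norm(flat))
    if norm <= cap or norm == 0.0:
        return grads, False
    return unflatten(flat * (cap / norm)), True


# ---------------------------------------------------------------------------
# One alternating update step
# ---------------------------------------------------------------------------

def tagan_step(
    batch: dict,
    nets: tuple[Generator, PatchDiscriminator, TaskNetwork],
    optimizers: dict[str, Adam],
    weights: LossWeights = LossWeights(),
    frozen_task: bool = False,
    grad_clip: float | None = 100.0,
    rng: np.random.Generator | None = None,
    events: list | None = None,
) -> LossBundle:
    """One scheduled update: discriminator, then generator, then task network.

    ``batch`` holds ``lr``, ``hr`` and ``annotation`` arrays (N, C, H, W).
    In ``frozen_task`` mode (pretrained live task network) the third update
    is skipped and the task parameters are untouched.  ``events``, when
    given, records the update order for instrumentation.
    """
    gen, disc, task = nets
    lr = _batched(batch["lr"])
    hr = _batched(batch["hr"])
    ann = _batched(batch["annotation"])
    kind = weights.adversarial
    rng = rng or np.random.default_rng(0)
    masks = _make_dropout_masks(rng, gen.spec, lr.shape[-2:], lr.shape[0])

    # -- discriminator ----------------------------------------------------
    fake_const = np.asarray(gen.forward(gen.params, lr, masks))

    def loss_d(p):
        dr = _adv_real(disc.forward(p, lr, hr), kind)
        dg = _adv_fake(disc.forward(p, lr, fake_const), kind)
        return 0.5 * (dr + dg)

    _, g_d = value_and_grad(loss_d)(disc.params)
    g_d, _ = _clip_grads(g_d, grad_clip)
    disc.params = optimizers["d"].step(disc.params, g_d)
    if events is not None:
        events.append("discriminator")

    # -- generator ---------------------------------------------------------
    def loss_g(p):
        fake = gen.forward(p, lr, masks)
        gan = _adv_real(disc.forward(disc.params, lr, fake), kind)
        if weights.ablation:
            gen_term = anp.mean((fake - hr) ** 2)
        else:
            gen_term = _weighted_mse(task.forward(task.params, fake), ann,
                                     weights.class_weights)
        return weights.lambda_gan * gan + weights.lambda_gen * gen_term

    _, g_g = value_and_grad(loss_g)(gen.params)
    g_g, _ = _clip_grads(g_g, grad_clip)
    gen.params = optimizers["g"].step(gen.params, g_g)
    if events is not None:
        events.append("generator")

    # -- task network ------------------------------------------------------
    if not frozen_task:
        def loss_t(p):
            return _weighted_mse(task.forward(p, hr), ann, weights.class_weights)

        _, g_t = value_and_grad(loss_t)(task.params)
        g_t, _ = _clip_grads(g_t, grad_clip)
        task.params = optimizers["t"].step(task.params, g_t)
        if events is not None:
            events.append("task")

    fake_now = np.asarray(gen.forward(gen.params, lr, masks))
    return tagan_losses(hr, fake_now, ann, task, disc, lr, weights)


def fit_tagan(
    dataset: Sequence[dict],
    nets: tuple[Generator, PatchDiscriminator, TaskNetwork],
    n_steps: int,
    batch_size: int = 4,
    seed: int = 0,
    weights: LossWeights = LossWeights(),
    frozen_task: bool = False,
    lr: float = 2e-4,
) -> list[LossBundle]:
    """Small training loop: random minibatches, constant learning rate.

    ``dataset`` is a sequence of items with ``lr``, ``hr`` and
    ``annotation`` single-image arrays.  Returns the per-step loss bundles.
    No early stopping is applied; checkpointing/selection is the caller's
    concern.
    """
    rng = np.random.default_rng(seed)
    opts = {k: Adam(lr=lr) for k in ("d", "g", "t")}
    history: list[LossBundle] = []
    for _ in range(n_steps):
        idx = rng.choice(len(dataset), size=min(batch_size, len(dataset)), replace=False)
        batch = {
            key: np.stack([_batched(dataset[i][key])[0] for i in idx])
            for key in ("lr", "hr", "annotation")
        }
        history.append(
            tagan_step(batch, nets, opts, weights, frozen_task=frozen_task, rng=rng)
        )
    return history


# ---------------------------------------------------------------------------
# Unpaired cycle losses
# ---------------------------------------------------------------------------

def cycle_losses(
    fixed_real: np.ndarray,
    live_real: np.ndarray,
    G_f2l: Callable,
    G_l2f: Callable,
    D_f: Callable,
    D_l: Callable,
    task_net_fixed,
    weights: LossWeights = LossWeights(),
) -> LossBundle:
    """Evaluate the unpaired (cycle) loss components.

    Generators and discriminators are callables (``G(img) -> img``,
    ``D(img) -> logits``); ``task_net_fixed`` is the pretrained, frozen
    segmentation network of the fixed domain.  GEN compares its predictions
    on the real fixed image and the end-of-cycle reconstruction; the live
    cycle has no task term by construction.
    """
    kind = weights.adversarial
    fixed_real = np.asarray(fixed_real, dtype=np.float64)
    live_real = np.asarray(live_real, dtype=np.float64)

    live_gen = _call(G_f2l, fixed_real)      # fixed -> live
    fixed_rec = _call(G_l2f, live_gen)       # back to fixed
    fixed_gen = _call(G_l2f, live_real)      # live -> fixed
    live_rec = _call(G_f2l, fixed_gen)       # back to live

    cyc = float(np.mean((fixed_rec - fixed_real) ** 2)
                + np.mean((live_rec - live_real) ** 2))
    gan = float(_adv_real(_call(D_l, live_gen), kind)
                + _adv_real(_call(D_f, fixed_gen), kind))
    dr = float(_adv_real(_call(D_f, fixed_real), kind)
               + _adv_real(_call(D_l, live_real), kind))
    dg = float(_adv_fake(_call(D_f, fixed_gen), kind)
               + _adv_fake(_call(D_l, live_gen), kind))
    gen = float(np.mean(
        (np.asarray(_call(task_net_fixed, fixed_real))
         - np.asarray(_call(task_net_fixed, fixed_rec))) ** 2
    ))
    return LossBundle(gen=gen, tl=0.0, gan=gan, dr=dr, dg=dg, cyc=cyc,
                      weights=weights).check_finite()
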