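"""Network families: generator, patch discriminator and task network.

The three families mirror the pix2pix convention the method builds on: an
encoder--decoder generator with skip connections ("U-Net" geometry, dropout
in the decoder so Monte-Carlo sampling is possible), a patch-based
conditional discriminator, and a task network that is either a U-Net or a
ResNet.  They are implemented as pure-numpy functional networks whose
gradients come from reverse-mode autodiff (HIPS autograd), so training runs
on one CPU with no deep-learning framework.  Default widths and depths are
scaled for desk-size images; the full 7-level U-Net-128 geometry is
reachable through :class:`GeneratorSpec`.

Arrays are channel-first: a batch is ``(N, C, H, W)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np
from autograd.scipy.signal import convolve as ag_convolve

__all__ = [
    "GeneratorSpec",
    "EnsembleStack",
    "Generator",
    "PatchDiscriminator",
    "TaskNetwork",
    "build_networks",
    "mc_dropout_sample",
    "assemble_live_input",
    "sigmoid",
]

TASK_KINDS = ("binary_seg", "semantic_seg", "localization")


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape descriptor for the encoder-decoder generator / U-Net task net.

    ``depth`` is the number of 2x down/up levels (7 reproduces the U-Net-128
    convention at 128-px inputs; the desk default is 3), ``base_width`` the
    channel count of the first level, doubled per level and capped at
    ``max_width``.
    """

    in_channels: int = 1
    out_channels: int = 1
    depth: int = 3
    base_width: int = 8
    max_width: int = 32
    dropout_rate: float = 0.5
    norm: str = "batch"

    def width(self, level: int) -> int:
        return min(self.base_width * 2 ** level, self.max_width)


# ---------------------------------------------------------------------------
# Functional building blocks
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _conv2d(x, w, b):
    """Same-size kxk (k odd) correlation over an (N,C,H,W) batch.

    im2col + einsum formulation: an order of magnitude faster under
    reverse-mode autodiff than FFT convolution at these kernel sizes.
    """
    k = w.shape[-1]
    p = k // 2
    h, wd = x.shape[2], x.shape[3]
    if k == 1:
        out = anp.einsum("nchw,co->nohw", x, w[:, :, 0, 0])
        return out + b[None, :, None, None]
    xp = anp.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant")
    patches = anp.stack(
        [xp[:, :, i : i + h, j : j + wd] for i in range(k) for j in range(k)],
        axis=2,
    )  # (N, C, k*k, H, W)
    wk = anp.reshape(w, (w.shape[0], w.shape[1], k * k))  # (C, O, k*k)
    out = anp.einsum("nckhw,cok->nohw", patches, wk)
    return out + b[None, :, None, None]


def _norm(x, gamma, beta, kind):
    if kind == "none":
        return x
    # batch norm over batch + spatial axes (batch statistics always; with a
    # single sample this reduces to instance normalization)
    mu = anp.mean(x, axis=(0, 2, 3), keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=(0, 2, 3), keepdims=True)
    xn = (x - mu) / anp.sqrt(var + 1e-5)
    return xn * gamma[None, :, None, None] + beta[None, :, None, None]


def _leaky_relu(x, slope=0.2):
    return anp.maximum(x, slope * x)


def _avgpool2(x):
    n, c, h, w = x.shape
    return anp.mean(anp.reshape(x, (n, c, h // 2, 2, w // 2, 2)), axis=(3, 5))


def _upsample2(x):
    return anp.repeat(anp.repeat(x, 2, axis=2), 2, axis=3)


def _init_conv(rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
    scale = np.sqrt(2.0 / (c_in * k * k))
    return {
        "w": rng.normal(0.0, scale, size=(c_in, c_out, k, k)),
        "b": np.zeros(c_out),
    }


def _init_norm(c: int):
    return {"gamma": np.ones(c), "beta": np.zeros(c)}


def _pad_to_multiple(x: np.ndarray, m: int):
    """Reflect-pad spatial dims up to a multiple of m; returns (padded, crop)."""
    h, w = x.shape[-2:]
    ph, pw = (-h) % m, (-w) % m
    if ph == 0 and pw == 0:
        return x, (h, w)
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="reflect"), (h, w)


# ---------------------------------------------------------------------------
# U-Net (generator and default task network)
# ---------------------------------------------------------------------------

def init_unet(rng: np.random.Generator, spec: GeneratorSpec) -> dict:
    widths = [spec.width(i) for i in range(spec.depth)]
    params: dict = {"enc": [], "dec": [], "skipn": []}
    c = spec.in_channels
    for wd in widths:
        params["enc"].append({"conv": _init_conv(rng, c, wd), "norm": _init_norm(wd)})
        c = wd
    bottom = spec.width(spec.depth)
    params["mid"] = {"conv": _init_conv(rng, c, bottom), "norm": _init_norm(bottom)}
    c = bottom
    for wd in reversed(widths):
        params["dec"].append(
            {"conv": _init_conv(rng, c + wd, wd), "norm": _init_norm(wd)}
        )
        c = wd
    params["out"] = _init_conv(rng, c, spec.out_channels, k=1)
    return params


def unet_apply(params: dict, x, spec: GeneratorSpec, dropout_masks=None):
    """Forward pass.  ``dropout_masks`` (one per decoder level) enables the
    decoder dropout used for MC sampling; ``None`` runs deterministically."""
    skips = []
    h = x
    for blk in params["enc"]:
        h = _conv2d(h, blk["conv"]["w"], blk["conv"]["b"])
        h = _leaky_relu(_norm(h, blk["norm"]["gamma"], blk["norm"]["beta"], spec.norm))
        skips.append(h)
        h = _avgpool2(h)
    h = _conv2d(h, params["mid"]["conv"]["w"], params["mid"]["conv"]["b"])
    h = _leaky_relu(_norm(h, params["mid"]["norm"]["gamma"], params["mid"]["norm"]["beta"], spec.norm))
    for i, blk in enumerate(params["dec"]):
        h = _upsample2(h)
        h = anp.concatenate([h, skips[-(i + 1)]], axis=1)
        h = _conv2d(h, blk["conv"]["w"], blk["conv"]["b"])
        h = anp.maximum(h, 0.0)
        h = _norm(h, blk["norm"]["gamma"], blk["norm"]["beta"], spec.norm)
        if dropout_masks is not None:
            h = h * dropout_masks[i]
    return _conv2d(h, params["out"]["w"], params["out"]["b"])


def _make_dropout_masks(
    rng: np.random.Generator, spec: GeneratorSpec, shape_hw: tuple[int, int], n_batch: int
):
    """Per-decoder-level inverted-dropout masks for one stochastic pass."""
    if spec.dropout_rate <= 0:
        return None
    masks = []
    h, w = shape_hw
    widths = [spec.width(i) for i in range(spec.depth)]
    sizes = [(h // 2 ** i, w // 2 ** i) for i in range(spec.depth)]
    for wd, (hh, ww) in zip(reversed(widths), reversed(sizes)):
        keep = 1.0 - spec.dropout_rate
        m = (rng.random((n_batch, wd, hh, ww)) < keep) / keep
        masks.append(m)
    return masks


# ---------------------------------------------------------------------------
# ResNet task network
# ---------------------------------------------------------------------------

def init_resnet(rng: np.random.Generator, spec: GeneratorSpec, n_blocks: int = 9) -> dict:
    w0 = spec.base_width
    params = {
        "head": {"conv": _init_conv(rng, spec.in_channels, w0), "norm": _init_norm(w0)},
        "blocks": [],
        "out": _init_conv(rng, w0, spec.out_channels, k=1),
    }
    for _ in range(n_blocks):
        params["blocks"].append(
            {
                "c1": _init_conv(rng, w0, w0),
                "n1": _init_norm(w0),
                "c2": _init_conv(rng, w0, w0),
                "n2": _init_norm(w0),
            }
        )
    return params


def resnet_apply(params: dict, x, spec: GeneratorSpec):
    h = _conv2d(x, params["head"]["conv"]["w"], params["head"]["conv"]["b"])
    h = _leaky_relu(_norm(h, params["head"]["norm"]["gamma"], params["head"]["norm"]["beta"], spec.norm))
    for blk in params["blocks"]:
        r = _conv2d(h, blk["c1"]["w"], blk["c1"]["b"])
        r = anp.maximum(_norm(r, blk["n1"]["gamma"], blk["n1"]["beta"], spec.norm), 0.0)
        r = _conv2d(r, blk["c2"]["w"], blk["c2"]["b"])
        r = _norm(r, blk["n2"]["gamma"], blk["n2"]["beta"], spec.norm)
        h = h + r
    return _conv2d(h, params["out"]["w"], params["out"]["b"])


# ---------------------------------------------------------------------------
# Network wrappers
# ---------------------------------------------------------------------------

class _Net:
    """A functional network plus its parameter pytree."""

    def __init__(self, spec: GeneratorSpec, params: dict):
        self.spec = spec
        self.params = params

    def n_parameters(self) -> int:
        from autograd.misc import flatten

        return flatten(self.params)[0].size

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        return x


class Generator(_Net):
    """Encoder-decoder generator with skip connections and decoder dropout."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__(spec, init_unet(rng, spec))

    def forward(self, params, x, dropout_masks=None):
        return unet_apply(params, x, self.spec, dropout_masks)

    def apply(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the generator; pass ``rng`` to sample a fresh dropout mask."""
        xb = self._as_batch(x)
        m = 2 ** self.spec.depth
        xp, (h, w) = _pad_to_multiple(xb, m)
        masks = None
        if rng is not None and self.spec.dropout_rate > 0:
            masks = _make_dropout_masks(rng, self.spec, xp.shape[-2:], xp.shape[0])
        out = self.forward(self.params, xp, masks)
        out = np.asarray(out)[..., :h, :w]
        return out[0] if np.asarray(x).ndim <= 3 else out

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One MC-dropout stochastic forward pass (dropout kept active)."""
        if self.spec.dropout_rate <= 0:
            warnings.warn("dropout_rate is 0: MC samples will be identical")
        return self.apply(x, rng=rng)


class TaskNetwork(_Net):
    """Auxiliary task network: U-Net (default) or ResNet architecture.

    Output is raw (unsquashed) scores with one channel per task class;
    binarize with a logistic mapping and threshold (default 0.5).
    """

    def __init__(
        self,
        spec: GeneratorSpec,
        rng: np.random.Generator,
        arch: str = "unet",
        n_blocks: int = 9,
    ):
        self.arch = arch
        spec = replace(spec, dropout_rate=0.0)
        if arch == "unet":
            params = init_unet(rng, spec)
        elif arch == "resnet":
            params = init_resnet(rng, spec, n_blocks)
        else:
            raise ValueError(f"unknown task architecture {arch!r}")
        super().__init__(spec, params)

    def forward(self, params, x):
        if self.arch == "unet":
            return unet_apply(params, x, self.spec)
        return resnet_apply(params, x, self.spec)

    def apply(self, x: np.ndarray) -> np.ndarray:
        xb = self._as_batch(x)
        m = 2 ** self.spec.depth if self.arch == "unet" else 1
        xp, (h, w) = _pad_to_multiple(xb, m)
        out = np.asarray(self.forward(self.params, xp))[..., :h, :w]
        return out[0] if np.asarray(x).ndim <= 3 else out

    def segment(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binarized segmentation: logistic(score) > threshold per class."""
        return (1.0 / (1.0 + np.exp(-self.apply(x)))) > threshold


class PatchDiscriminator(_Net):
    """Conditional patch classifier: scores local patches as real/fake.

    Input is the low-resolution conditioning image concatenated with the
    candidate high-resolution image; output is a grid of patch logits.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator, base_width: int = 8, n_levels: int = 3):
        spec = GeneratorSpec(
            in_channels=in_channels, out_channels=1, depth=n_levels,
            base_width=base_width, dropout_rate=0.0,
        )
        params: dict = {"convs": []}
        c = in_channels
        for i in range(n_levels):
            wd = spec.width(i)
            params["convs"].append({"conv": _init_conv(rng, c, wd), "norm": _init_norm(wd)})
            c = wd
        params["out"] = _init_conv(rng, c, 1, k=3)
        super().__init__(spec, params)

    def forward(self, params, lr, img):
        h = anp.concatenate([lr, img], axis=1)
        for blk in params["convs"]:
            h = _conv2d(h, blk["conv"]["w"], blk["conv"]["b"])
            h = _leaky_relu(_norm(h, blk["norm"]["gamma"], blk["norm"]["beta"], self.spec.norm))
            h = _avgpool2(h)
        return _conv2d(h, params["out"]["w"], params["out"]["b"])

    def apply(self, lr: np.ndarray, img: np.ndarray) -> np.ndarray:
        lrb, imgb = self._prep(lr), self._prep(img)
        return np.asarray(self.forward(self.params, lrb, imgb))

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[None]
        xp, _ = _pad_to_multiple(x, 2 ** len(self.params["convs"]))
        return xp


def build_networks(
    task_kind: str,
    spec: GeneratorSpec | None = None,
    class_names: tuple[str, ...] = (),
    task_arch: str = "unet",
    seed: int = 0,
) -> tuple[Generator, PatchDiscriminator, TaskNetwork]:
    """Instantiate the three TA-GAN networks for one auxiliary task.

    ``task_kind`` is ``binary_seg``, ``semantic_seg`` (supply
    ``class_names``) or ``localization``; the task network's output channel
    count matches the task.
    """
    if task_kind not in TASK_KINDS:
        raise ValueError(f"task_kind must be one of {TASK_KINDS}")
    spec = spec or GeneratorSpec()
    if task_kind == "semantic_seg":
        if not class_names:
            raise ValueError("semantic_seg requires class_names")
        task_channels = len(class_names)
    else:
        task_channels = 1
    rng = np.random.default_rng(seed)
    gen = Generator(spec, rng)
    disc = PatchDiscriminator(spec.in_channels + spec.out_channels, rng)
    task_spec = replace(spec, in_channels=spec.out_channels, out_channels=task_channels)
    task = TaskNetwork(task_spec, rng, arch=task_arch)
    return gen, disc, task


# ---------------------------------------------------------------------------
# MC-dropout ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleStack:
    """K dropout-sampled synthetic images with binarized segmentations.

    ``count_map`` counts, per class and pixel, in how many of the K samples
    the segmentation was positive (0..K).
    """

    samples: np.ndarray          # (K, H, W) or (K, C_out, H, W)
    binarized_segs: np.ndarray   # (K, C, H, W) of {0,1}
    count_map: np.ndarray        # (C, H, W) integers in [0, K]
    K: int
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        recount = self.binarized_segs.sum(axis=0)
        if not np.array_equal(recount, self.count_map):
            raise ValueError("count_map must equal the sum of binarized segs")


def mc_dropout_sample(
    generator,
    x: np.ndarray,
    K: int = 10,
    seed: int | np.random.Generator = 0,
    task_net: TaskNetwork | None = None,
    binarize_threshold: float = 0.5,
) -> EnsembleStack:
    """Draw K stochastic generator outputs and their binarized segmentations.

    ``generator`` is anything with a ``sample(x, rng)`` method (a trained
    :class:`Generator` or a stub).  With a ``task_net`` each sample is
    segmented by it; otherwise the sample itself is thresholded.
    Deterministic given ``seed``.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples, segs = [], []
    for _ in range(K):
        s = np.asarray(generator.sample(x, rng))
        samples.append(s)
        if task_net is not None:
            seg = task_net.segment(s, threshold=binarize_threshold)
        else:
            img = s if s.ndim == 3 else s[None]
            lo, hi = img.min(), img.max()
            if hi > lo:
                seg = (img - lo) / (hi - lo) > binarize_threshold
            else:
                seg = np.zeros(img.shape, dtype=bool)
        segs.append(seg[None] if seg.ndim == 2 else seg)
    samples = np.stack(samples)
    segs = np.stack([s.reshape((-1,) + s.shape[-2:]) for s in segs]).astype(np.uint8)
    return EnsembleStack(
        samples=samples,
        binarized_segs=segs,
        count_map=segs.sum(axis=0),
        K=K,
        binarize_threshold=binarize_threshold,
    )


def assemble_live_input(
    confocal_fov: np.ndarray,
    sted_subregion: np.ndarray | None,
    subregion_rect: tuple[int, int, int, int] | None,
) -> np.ndarray:
    """Three-channel conditioning input for the live generator.

    Channel 1 is the confocal field of view; channel 2 carries the acquired
    STED subregion pasted at its position (zero elsewhere); channel 3 is a
    binary matrix marking the subregion.  Passing ``None`` for the subregion
    yields all-zero channels 2-3 (no STED acquired yet).
    """
    fov = np.asarray(confocal_fov, dtype=np.float64)
    ch2 = np.zeros_like(fov)
    ch3 = np.zeros_like(fov)
    if subregion_rect is not None:
        r0, c0, h, w = subregion_rect
        if r0 < 0 or c0 < 0 or r0 + h > fov.shape[0] or c0 + w > fov.shape[1]:
            raise ValueError(f"subregion {subregion_rect} outside the FOV {fov.shape}")
        if sted_subregion is None or sted_subregion.shape != (h, w):
            raise ValueError("sted_subregion must match the rectangle extent")
        ch2[r0 : r0 + h, c0 : c0 + w] = sted_subregion
        ch3[r0 : r0 + h, c0 : c0 + w] = 1.0
    return np.stack([fov, ch2, ch3])
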