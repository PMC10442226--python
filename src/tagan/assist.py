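"""Closed-loop acquisition decision engine.

Implements the per-frame assistance protocol run on the microscope: acquire
a confocal field of view, draw an MC-dropout ensemble of synthetic STED
images, rank 2x2-um subregions by Horn--Schunck optical flow between
consecutive ensemble samples, acquire the most variable subregion outside
the region of interest (ROI) with STED, condition a second ensemble on it,
segment the central ROI, and decide whether a full STED image of the ROI is
warranted.  Two trigger policies are provided: the Dice-coefficient (DC)
policy fires when the mean Dice between the ensemble segmentations and the
segmentation of the last real STED falls strictly below a threshold
(default 0.5), and the variability-score (VS) policy fires when the
proportion of high-variability foreground pixels rises strictly above 0.5.
A photon-dose ledger tracks the light delivered per modality.

The engine talks to hardware through a two-method driver
(``acquire_confocal(rect)`` / ``acquire_sted(rect)``); the in-repo driver is
backed by the nanodomain simulator, so the whole loop runs at desk scale.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from . import simulate as sim
from .metrics import overlap_metrics
from .nets import assemble_live_input, mc_dropout_sample

logger = logging.getLogger("tagan.assist")

__all__ = [
    "FlowField",
    "DecisionRecord",
    "LoopGeometry",
    "horn_schunck_flow",
    "block_mean",
    "ensemble_flow_map",
    "select_subregion",
    "dice_trigger",
    "variability_score",
    "SimulatedMicroscope",
    "GroundTruthGenerator",
    "ThresholdSegmenter",
    "scripted_change_provider",
    "run_assisted_sequence",
    "light_dose_summary",
]


# ---------------------------------------------------------------------------
# Optical flow
# ---------------------------------------------------------------------------

_HS_AVG = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


@dataclass
class FlowField:
    """Dense displacement field between two frames.

    ``u`` is the displacement along axis 0 (rows), ``v`` along axis 1
    (columns), in pixels.
    """

    u: np.ndarray
    v: np.ndarray
    energies: list[float] = field(default_factory=list)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def block_map(self, block: int) -> np.ndarray:
        return block_mean(self.magnitude, block)


def _hs_derivatives(i1: np.ndarray, i2: np.ndarray):
    """Horn--Schunck forward-difference derivative estimates.

    Row derivative (axis 0), column derivative (axis 1) and the temporal
    difference, each averaged over the 2x2x2 cube of the two frames.
    """
    kr = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
    kc = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
    kt = 0.25 * np.ones((2, 2))
    ir = ndimage.correlate(i1, kr, mode="nearest") + ndimage.correlate(i2, kr, mode="nearest")
    ic = ndimage.correlate(i1, kc, mode="nearest") + ndimage.correlate(i2, kc, mode="nearest")
    it = ndimage.correlate(i2, kt, mode="nearest") - ndimage.correlate(i1, kt, mode="nearest")
    return ir, ic, it


def horn_schunck_flow(
    img1: np.ndarray,
    img2: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 100,
    track_energy: bool = False,
) -> FlowField:
    """Horn--Schunck optical flow: brightness constancy + alpha^2 smoothness.

    Iterates the classic coupled update with the 8-neighbour averaging
    kernel.  ``track_energy`` records the regularized energy after each
    iteration (it is non-increasing on well-posed inputs).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    i1 = np.asarray(img1, dtype=np.float64)
    i2 = np.asarray(img2, dtype=np.float64)
    if i1.shape != i2.shape:
        raise ValueError("images must share a shape")
    scale = max(i1.max(), i2.max(), 1.0)
    i1, i2 = i1 / scale, i2 / scale
    ir, ic, it = _hs_derivatives(i1, i2)
    den = alpha ** 2 + ir ** 2 + ic ** 2
    u = np.zeros_like(i1)
    v = np.zeros_like(i1)
    energies: list[float] = []
    for _ in range(n_iter):
        ubar = ndimage.convolve(u, _HS_AVG, mode="nearest")
        vbar = ndimage.convolve(v, _HS_AVG, mode="nearest")
        t = (ir * ubar + ic * vbar + it) / den
        u = ubar - ir * t
        v = vbar - ic * t
        if track_energy:
            resid = ir * u + ic * v + it
            gu = np.gradient(u)
            gv = np.gradient(v)
            smooth = sum(np.sum(g ** 2) for g in (*gu, *gv))
            energies.append(float(np.sum(resid ** 2) + alpha ** 2 * smooth))
    return FlowField(u=u, v=v, energies=energies)


def block_mean(image: np.ndarray, block: int) -> np.ndarray:
    """Mean-pool an image into (H/block, W/block) blocks; exact division only."""
    h, w = image.shape
    if h % block or w % block:
        raise ValueError(f"image shape {(h, w)} not divisible by block {block}")
    return image.reshape(h // block, block, w // block, block).mean(axis=(1, 3))


def ensemble_flow_map(
    samples: np.ndarray | Sequence[np.ndarray],
    alpha: float = 1.0,
    n_iter: int = 100,
    block: int = 100,
) -> np.ndarray:
    """Block-pooled mean optical-flow magnitude over consecutive sample pairs.

    Flow is computed between samples (1-2, 2-3, ...), the K-1 magnitude maps
    are averaged, and the result is mean-pooled into ``block`` x ``block``
    regions (the published geometry pools 500x500 px into a 5x5 map).
    Identical pairs short-circuit to zero flow.
    """
    samples = [np.asarray(s, dtype=np.float64) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two ensemble samples")
    mag = np.zeros_like(samples[0])
    for a, b in zip(samples[:-1], samples[1:]):
        if not np.array_equal(a, b):
            mag += horn_schunck_flow(a, b, alpha=alpha, n_iter=n_iter).magnitude
    mag /= len(samples) - 1
    return block_mean(mag, block)


def select_subregion(
    block_map: np.ndarray,
    roi_blocks: np.ndarray | set,
    block_px: int = 100,
) -> tuple[int, int, int, int]:
    """Pixel rectangle of the most variable block outside the ROI.

    ``roi_blocks`` is a boolean mask over the block grid (or a set of
    (i, j) indices).  Ties break to the first eligible block in row-major
    order.  Returns a half-open rectangle (row0, col0, height, width).
    """
    bm = np.asarray(block_map, dtype=np.float64)
    if isinstance(roi_blocks, set):
        mask = np.zeros(bm.shape, dtype=bool)
        for (i, j) in roi_blocks:
            mask[i, j] = True
    else:
        mask = np.asarray(roi_blocks, dtype=bool)
    if mask.all():
        raise ValueError("every block lies inside the ROI")
    masked = np.where(mask, -np.inf, bm)
    flat = int(np.argmax(masked))  # first maximum in row-major order
    i, j = np.unravel_index(flat, bm.shape)
    return (int(i) * block_px, int(j) * block_px, block_px, block_px)


# ---------------------------------------------------------------------------
# Trigger policies
# ---------------------------------------------------------------------------

def dice_trigger(
    ensemble_segs: np.ndarray,
    reference_seg: np.ndarray,
    theta: float = 0.5,
) -> tuple[float, bool]:
    """Mean Dice of K ensemble segmentations against the reference STED's.

    Triggers strictly below ``theta``; a pair of empty masks scores Dice 1
    (no evidence of change).
    """
    ref = np.asarray(reference_seg, dtype=bool)
    dcs = [overlap_metrics(np.asarray(s, dtype=bool), ref)["dice"] for s in ensemble_segs]
    mean_dc = float(np.mean(dcs))
    return mean_dc, mean_dc < theta


def variability_score(
    count_map: np.ndarray,
    K: int = 10,
    consensus: float = 0.8,
    theta: float = 0.5,
) -> tuple[float, np.ndarray, bool]:
    """Fraction of foreground pixels with non-consensus ensemble predictions.

    Foreground pixels have a positive count (zero-count, mostly background,
    pixels are ignored).  A foreground pixel is *low-variability* when at
    least ``consensus`` of the K samples agree -- counts in
    {1..K(1-consensus)} or {K*consensus+1..K} ({1,2} and {9,10} at K=10) --
    and *high-variability* otherwise (counts 3..8).  The score is
    high / (high + low); an acquisition is triggered strictly above
    ``theta`` (0.5 is the tipping point where high outnumber low).  Returns
    (vs, variability map with codes 0=background 1=low 2=high, triggered).
    """
    cm = np.asarray(count_map)
    if cm.min() < 0 or cm.max() > K:
        raise ValueError(f"count map values must lie in [0, {K}]")
    lo_band = int(np.floor(K * (1.0 - consensus) + 1e-9))
    hi_band = int(np.floor(K * consensus + 1e-9)) + 1
    fg = cm >= 1
    low = fg & ((cm <= lo_band) | (cm >= hi_band))
    high = fg & ~low
    vmap = np.zeros(cm.shape, dtype=np.int8)
    vmap[low] = 1
    vmap[high] = 2
    n_low, n_high = int(low.sum()), int(high.sum())
    if n_low + n_high == 0:
        logger.info("variability score on empty foreground; defined as 0")
        return 0.0, vmap, False
    vs = n_high / (n_high + n_low)
    return float(vs), vmap, vs > theta


# ---------------------------------------------------------------------------
# Simulated microscope and stubs
# ---------------------------------------------------------------------------

@dataclass
class LoopGeometry:
    """Field-of-view geometry of the assisted loop, in pixels.

    Defaults follow the published setup at 20 nm px: a 500x500 px (10x10 um)
    FOV pooled into 5x5 blocks of 100x100 px (2x2 um), with the central 3x3
    blocks (300x300 px, 6x6 um) as the ROI.
    """

    fov_px: int = 500
    block_px: int = 100
    roi_blocks_half: int = 1   # central (2h+1)x(2h+1) blocks form the ROI

    @property
    def n_blocks(self) -> int:
        return self.fov_px // self.block_px

    @property
    def roi_block_mask(self) -> np.ndarray:
        n = self.n_blocks
        c = n // 2
        h = self.roi_blocks_half
        m = np.zeros((n, n), dtype=bool)
        m[c - h : c + h + 1, c - h : c + h + 1] = True
        return m

    @property
    def roi_rect(self) -> tuple[int, int, int, int]:
        n, c, h, b = self.n_blocks, self.n_blocks // 2, self.roi_blocks_half, self.block_px
        r0 = (c - h) * b
        ext = (2 * h + 1) * b
        return (r0, r0, ext, ext)


class SimulatedMicroscope:
    """Virtual sample + microscope driver backed by the optical simulator.

    ``provider(frame)`` returns the ground-truth datamap of the FOV at each
    frame (a time-evolving sample).  Every acquisition renders the requested
    rectangle with Poisson noise, applies expected-value photobleaching to
    the running signal level, and logs the photon dose delivered.  A
    hardware backend only needs to reimplement ``acquire_confocal`` and
    ``acquire_sted``.
    """

    def __init__(
        self,
        provider: Callable[[int], sim.Datamap],
        seed: int = 0,
        confocal: sim.ImagingConfig = sim.CONFOCAL,
        sted: sim.ImagingConfig = sim.STED,
        geometry: LoopGeometry = LoopGeometry(),
    ):
        self.provider = provider
        self.rng = np.random.default_rng(seed)
        self.configs = {"confocal": confocal, "sted": sted}
        self.geometry = geometry
        self.frame = 0
        self._survival = 1.0
        self.acquisitions: list[dict] = []

    # -- sample state ------------------------------------------------------
    def set_frame(self, frame: int) -> None:
        self.frame = frame

    def current_datamap(self) -> sim.Datamap:
        dm = self.provider(self.frame)
        return dataclasses.replace(dm, counts=dm.counts * self._survival)

    # -- driver interface --------------------------------------------------
    def _acquire(self, modality: str, rect: tuple[int, int, int, int]) -> sim.AcquiredImage:
        cfg = self.configs[modality]
        img = sim.render_image(
            self.current_datamap(), cfg, self.rng, frame_index=self.frame, region=rect
        )
        self._survival *= 1.0 - cfg.bleach_fraction
        dose = cfg.dose_rate * cfg.dwell_time * rect[2] * rect[3]
        self.acquisitions.append(
            {"frame": self.frame, "modality": modality, "rect": rect, "dose": dose}
        )
        return img

    def acquire_confocal(self, rect: tuple[int, int, int, int]) -> sim.AcquiredImage:
        return self._acquire("confocal", rect)

    def acquire_sted(self, rect: tuple[int, int, int, int]) -> sim.AcquiredImage:
        return self._acquire("sted", rect)


class GroundTruthGenerator:
    """Ground-truth-aware generator stub for closed-loop experiments.

    Emulates a perfectly trained live generator with explicit epistemic
    uncertainty: each MC sample renders the noise-free STED image of either
    the sample's *current* ground truth or the structure remembered from the
    *last real STED acquisition* (probability ``mix_prob``).  While the
    remembered reference matches the truth the ensemble is unanimous; after
    an unobserved structural change the samples disagree exactly where the
    structure changed.  ``mix_prob=0`` gives a deterministic perfect
    generator (always current truth).
    """

    def __init__(self, scope: SimulatedMicroscope, mix_prob: float = 0.5):
        self.scope = scope
        self.mix_prob = mix_prob
        self.reference_datamap: sim.Datamap | None = None

    def notify_reference(self, datamap: sim.Datamap) -> None:
        self.reference_datamap = datamap

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        current = self.scope.current_datamap()
        use_ref = (
            self.reference_datamap is not None
            and self.mix_prob > 0
            and rng.random() < self.mix_prob
        )
        dm = self.reference_datamap if use_ref else current
        cfg = self.scope.configs["sted"]
        return sim.render_image(dm, cfg, noise_free=True).pixels


class ThresholdSegmenter:
    """Smoothing + fraction-of-max threshold segmentation stub.

    Stands in for the live segmentation network in simulator-backed loop
    experiments; labelled synthetic, not a trained model.
    """

    def __init__(self, sigma: float = 2.0, frac: float = 0.3):
        self.sigma = sigma
        self.frac = frac

    def segment(self, image: np.ndarray, threshold: float | None = None) -> np.ndarray:
        img = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), self.sigma)
        span = img.max() - img.min()
        if span <= 0:
            return np.zeros(img.shape, dtype=bool)
        return (img - img.min()) / span > self.frac


def scripted_change_provider(
    seed: int,
    geometry: LoopGeometry = LoopGeometry(),
    change_frame: int = 8,
) -> Callable[[int], sim.Datamap]:
    """A time-evolving FOV whose ROI structure is remodelled at one frame.

    Two distinct spine datamaps are embedded at different positions inside
    the ROI; the provider returns the first before ``change_frame`` and the
    second from it onward, emulating an abrupt activity-dependent
    remodelling event.
    """
    rng = np.random.default_rng(seed)
    fov = geometry.fov_px
    r0, c0, ext, _ = geometry.roi_rect

    def embed(dm: sim.Datamap, pos: tuple[int, int]) -> sim.Datamap:
        counts = np.zeros((fov, fov))
        mask = np.zeros((fov, fov), dtype=bool)
        g = dm.counts.shape[0]
        counts[pos[0] : pos[0] + g, pos[1] : pos[1] + g] = dm.counts
        mask[pos[0] : pos[0] + g, pos[1] : pos[1] + g] = dm.spine_mask
        centers = tuple((r + pos[0], c + pos[1]) for (r, c) in dm.centers)
        return sim.Datamap(counts=counts, spine_mask=mask, centers=centers,
                           pixel_size_nm=dm.pixel_size_nm)

    g = 64
    before = sim.random_datamap(rng, n_domains=int(rng.integers(2, 7)))
    after = sim.random_datamap(rng, n_domains=int(rng.integers(2, 7)))
    # disjoint quadrants of the ROI so the segmentations barely overlap
    pos_a = (r0 + 8, c0 + 8)
    pos_b = (r0 + ext - g - 8, c0 + ext - g - 8)
    dm_a = embed(before, pos_a)
    dm_b = embed(after, pos_b)

    def provider(frame: int) -> sim.Datamap:
        return dm_a if frame < change_frame else dm_b

    return provider


# ---------------------------------------------------------------------------
# The closed loop
# ---------------------------------------------------------------------------

@dataclass
class DecisionRecord:
    """Per-frame log entry of the assisted acquisition loop."""

    frame_index: int
    policy: str
    value: float
    threshold: float
    triggered: bool
    reference_frame: int
    subregion_rect: tuple[int, int, int, int] | None
    cumulative_dose: dict[str, float]
    acquisitions: list[dict] = field(default_factory=list)

    def check(self) -> None:
        if self.policy == "dc":
            assert self.triggered == (self.value < self.threshold)
        elif self.policy == "vs":
            assert self.triggered == (self.value > self.threshold)


def run_assisted_sequence(
    scope: SimulatedMicroscope,
    policy: str,
    generator,
    segmenter,
    n_frames: int = 15,
    seed: int = 0,
    K: int = 10,
    theta: float = 0.5,
    consensus: float = 0.8,
    flow_alpha: float = 1.0,
    flow_iters: int = 30,
) -> tuple[list[DecisionRecord], dict[int, sim.AcquiredImage]]:
    """Run the full per-frame assistance protocol on a virtual sample.

    Per frame: (1) confocal FOV, (2) K dropout syntheses, (3) optical-flow
    subregion choice outside the ROI, (4) STED acquisition of that
    subregion, (5) K conditioned syntheses, (6) segmentation of the central
    ROI, (7) trigger evaluation, acquiring a full STED image of the ROI when
    the policy fires.  Initial and final reference STED images of the ROI
    are always acquired.  Returns the per-frame decision records and the
    real STED images by frame.
    """
    if policy not in ("dc", "vs"):
        raise ValueError(f"unknown policy {policy!r} (expected 'dc' or 'vs')")
    geom = scope.geometry
    roi = geom.roi_rect
    rng = np.random.default_rng(seed)
    records: list[DecisionRecord] = []
    sted_frames: dict[int, sim.AcquiredImage] = {}

    def notify(dm: sim.Datamap) -> None:
        if hasattr(generator, "notify_reference"):
            generator.notify_reference(dm)

    def roi_crop(fov_img: np.ndarray) -> np.ndarray:
        r0, c0, h, w = roi
        return fov_img[r0 : r0 + h, c0 : c0 + w]

    # initial reference STED of the ROI
    scope.set_frame(0)
    ref_img = scope.acquire_sted(roi)
    notify(scope.current_datamap())
    ref_seg = segmenter.segment(ref_img.pixels)
    ref_frame = 0
    sted_frames[0] = ref_img

    for f in range(1, n_frames + 1):
        scope.set_frame(f)
        dose_before = len(scope.acquisitions)
        conf = scope.acquire_confocal((0, 0, geom.fov_px, geom.fov_px))

        x0 = assemble_live_input(conf.pixels, None, None)
        ens0 = mc_dropout_sample(generator, x0, K=K, seed=rng)
        flat0 = [np.asarray(s).reshape(s.shape[-2:]) for s in ens0.samples]
        bmap = ensemble_flow_map(flat0, alpha=flow_alpha, n_iter=flow_iters,
                                 block=geom.block_px)
        sub_rect = select_subregion(bmap, geom.roi_block_mask, geom.block_px)
        sub_img = scope.acquire_sted(sub_rect)

        x1 = assemble_live_input(conf.pixels, sub_img.pixels, sub_rect)
        ens1 = mc_dropout_sample(generator, x1, K=K, seed=rng)
        segs = np.stack([
            segmenter.segment(roi_crop(np.asarray(s).reshape(s.shape[-2:])))
            for s in ens1.samples
        ])

        if policy == "dc":
            value, triggered = dice_trigger(segs, ref_seg, theta)
        else:
            count_map = segs.astype(np.int64).sum(axis=0)
            value, _, triggered = variability_score(count_map, K=K,
                                                    consensus=consensus, theta=theta)

        if triggered:
            ref_img = scope.acquire_sted(roi)
            notify(scope.current_datamap())
            ref_seg = segmenter.segment(ref_img.pixels)
            ref_frame = f
            sted_frames[f] = ref_img

        cum = {"confocal": 0.0, "sted": 0.0}
        for a in scope.acquisitions:
            cum[a["modality"]] += a["dose"]
        rec = DecisionRecord(
            frame_index=f,
            policy=policy,
            value=value,
            threshold=theta,
            triggered=triggered,
            reference_frame=ref_frame,
            subregion_rect=sub_rect,
            cumulative_dose=cum,
            acquisitions=scope.acquisitions[dose_before:],
        )
        rec.check()
        logger.info(
            "frame %d: %s=%.3f triggered=%s", f, policy, value, triggered
        )
        records.append(rec)

    # final reference STED
    scope.set_frame(n_frames + 1)
    sted_frames[n_frames + 1] = scope.acquire_sted(roi)
    notify(scope.current_datamap())
    return records, sted_frames


# ---------------------------------------------------------------------------
# Photon-dose accounting
# ---------------------------------------------------------------------------

def _rect_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> int:
    """Pixel count of the intersection of two half-open rectangles."""
    dr = min(a[0] + a[2], b[0] + b[2]) - max(a[0], b[0])
    dc = min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1])
    return max(dr, 0) * max(dc, 0)


def light_dose_summary(
    records: list[DecisionRecord],
    confocal: sim.ImagingConfig = sim.CONFOCAL,
    sted: sim.ImagingConfig = sim.STED,
    geometry: LoopGeometry = LoopGeometry(),
    include_references: bool = True,
) -> dict:
    """Cumulative ROI photon dose and reduction vs an always-STED baseline.

    The reduction is ``1 - dose_assisted / dose_all_sted`` over the central
    ROI, the baseline being one full STED ROI acquisition per frame of the
    same sequence length.  Reference acquisitions at the sequence ends are
    counted when ``include_references`` (both conventions are reported).
    """
    roi = geometry.roi_rect
    roi_px = roi[2] * roi[3]
    rates = {"confocal": confocal, "sted": sted}
    n_frames = len(records)

    def roi_dose(acqs) -> dict[str, float]:
        out = {"confocal": 0.0, "sted": 0.0}
        for a in acqs:
            cfg = rates[a["modality"]]
            out[a["modality"]] += cfg.dose_rate * cfg.dwell_time * _rect_overlap(a["rect"], roi)
        return out

    per_frame = roi_dose([a for r in records for a in r.acquisitions])
    ref_dose = {"confocal": 0.0,
                "sted": 2.0 * sted.dose_rate * sted.dwell_time * roi_px}
    baseline = n_frames * sted.dose_rate * sted.dwell_time * roi_px

    assisted_excl = sum(per_frame.values())
    assisted_incl = assisted_excl + sum(ref_dose.values())
    baseline_incl = baseline + sum(ref_dose.values())
    n_sted = sum(1 for r in records if r.triggered)
    return {
        "n_frames": n_frames,
        "n_sted_triggered": n_sted,
        "roi_dose_assisted": per_frame,
        "reduction_excluding_references": 1.0 - assisted_excl / baseline if baseline else 0.0,
        "reduction_including_references": 1.0 - assisted_incl / baseline_incl if baseline else 0.0,
    }
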