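"""Simulated nanodomain samples and a simplified optical forward model.

This module generates the latent ground truth of the simulated dendritic-spine
dataset -- *datamaps*, grids of fluorophore counts per pixel containing 1-6
punctate nanodomains placed near the spine edge -- and renders confocal-like
and STED-like photon-count images from any datamap.

The forward model is deliberately simple: the imaged photon mean is the
datamap convolved with a Gaussian point-spread function (PSF), scaled by a
photon yield per molecule, plus a uniform background, with Poisson shot
noise.  The PSF full width at half maximum (FWHM) encodes each modality's
resolution (default 250 nm confocal, 50 nm STED at 20 nm pixels), so a pair
of nanodomains 60 nm apart is resolvable in the STED render but not in the
confocal one.  Photobleaching is modelled as binomial thinning of the
molecule counts, with a much larger per-acquisition loss for STED.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PIXEL_SIZE_NM",
    "Datamap",
    "ImagingConfig",
    "AcquiredImage",
    "ConstraintError",
    "CONFOCAL",
    "STED",
    "generate_spine_shape",
    "place_nanodomains",
    "build_datamap",
    "validate_datamap",
    "render_image",
    "apply_bleaching",
    "DatasetConfig",
    "generate_dataset",
    "random_datamap",
]

#: Default sampling of the simulated microscope, nanometres per pixel.
PIXEL_SIZE_NM: float = 20.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConstraintError(RuntimeError):
    """A geometric constraint could not be satisfied within the retry budget."""


@dataclass(frozen=True)
class Datamap:
    """Ground-truth fluorophore-count grid with nanodomain positions.

    ``counts`` holds molecules per pixel; it is zero outside ``spine_mask``.
    ``centers`` are 0-based (row, col) pixel centres of the nanodomains.
    """

    counts: np.ndarray
    spine_mask: np.ndarray
    centers: tuple[tuple[int, int], ...]
    pixel_size_nm: float = PIXEL_SIZE_NM

    @property
    def n_domains(self) -> int:
        return len(self.centers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition settings of one imaging modality.

    dose_rate is the photon dose applied to the sample per second of
    scanning; dwell_time is seconds per pixel; bleach_fraction is the
    expected fraction of fluorophores lost per acquisition.
    """

    modality: str
    psf_fwhm_nm: float
    photons_per_molecule: float = 3.0
    background_rate: float = 1.0
    dose_rate: float = 0.0
    dwell_time: float = 5e-6
    bleach_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")
        if not 0.0 <= self.bleach_fraction < 1.0:
            raise ValueError("bleach_fraction must lie in [0, 1)")


#: Default modality configs.  Dose rates are the printed per-second photon
#: doses for a 6 x 6 um region; FWHMs are chosen so that sub-100-nm pairs are
#: STED-resolvable and confocal-unresolvable at 20 nm pixels.
CONFOCAL = ImagingConfig(
    modality="confocal",
    psf_fwhm_nm=250.0,
    dose_rate=1.168e13,
    bleach_fraction=0.002,
)
STED = ImagingConfig(
    modality="sted",
    psf_fwhm_nm=50.0,
    dose_rate=1.543e18,
    bleach_fraction=0.05,
)


@dataclass(frozen=True)
class AcquiredImage:
    """A photon-count raster plus its acquisition metadata.

    ``region`` is a half-open rectangle (row0, col0, height, width) locating
    the raster inside the field of view.
    """

    pixels: np.ndarray
    modality: str
    pixel_size_nm: float = PIXEL_SIZE_NM
    frame_index: int = 0
    region: tuple[int, int, int, int] | None = None


# ---------------------------------------------------------------------------
# Spine shapes
# ---------------------------------------------------------------------------

def _rasterize_mushroom(
    grid_size: int,
    head_a: float,
    head_b: float,
    neck_w: float,
    neck_len: float,
    theta: float,
    shift: tuple[float, float],
) -> np.ndarray:
    """Rasterize a mushroom-spine silhouette: ellipse head + rectangular neck.

    The shape is defined in a local frame (head centred at origin, neck
    extending along -y), rotated by ``theta`` and translated by ``shift``.
    """
    rr, cc = np.mgrid[0:grid_size, 0:grid_size]
    # map grid coords into the local shape frame
    y = rr - grid_size / 2.0 - shift[0]
    x = cc - grid_size / 2.0 - shift[1]
    ct, st = np.cos(theta), np.sin(theta)
    xl = ct * x + st * y
    yl = -st * x + ct * y
    head = (xl / head_a) ** 2 + (yl / head_b) ** 2 <= 1.0
    neck = (np.abs(xl) <= neck_w / 2.0) & (yl <= 0.0) & (yl >= -(head_b + neck_len))
    return head | neck


def generate_spine_shape(
    rng: np.random.Generator,
    area_min_um2: float = 0.12,
    area_max_um2: float = 0.48,
    grid_size: int = 64,
    pixel_size_nm: float = PIXEL_SIZE_NM,
    max_retries: int = 10_000,
) -> np.ndarray:
    """Draw a random mushroom-spine mask whose area falls in the given window.

    The head is an ellipse with random axes, the neck a rectangle, and the
    union is rotated and translated at random inside the grid.  Candidate
    shapes are rescaled toward a target area sampled uniformly in the window
    and rejected until the rasterized area lands inside
    ``[area_min_um2, area_max_um2]`` (within 2% rasterization tolerance when
    the window is degenerate) with the mask fully inside the grid.
    """
    if not 0 < area_min_um2 <= area_max_um2:
        raise ValueError("need 0 < area_min_um2 <= area_max_um2")
    if grid_size < 32:
        raise ConstraintError("grid_size must be at least 32 pixels")
    px_area_um2 = (pixel_size_nm * 1e-3) ** 2
    lo_px = area_min_um2 / px_area_um2
    hi_px = area_max_um2 / px_area_um2
    degenerate = (hi_px - lo_px) < 0.02 * lo_px

    for _ in range(max_retries):
        target_px = rng.uniform(lo_px, hi_px)
        aspect = rng.uniform(0.55, 1.0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        neck_frac = rng.uniform(0.25, 0.45)   # neck width / head minor axis
        neck_len_frac = rng.uniform(0.3, 0.9)
        # analytic first guess for the head semi-axes, then one refinement
        scale = 1.0
        mask = None
        for _ in range(3):
            head_a = scale * np.sqrt(target_px / (np.pi * aspect)) * 0.95
            head_b = aspect * head_a
            neck_w = neck_frac * 2.0 * min(head_a, head_b)
            neck_len = neck_len_frac * head_b
            # farthest point from the head centre: ellipse rim or neck tip
            extent = max(head_a, head_b + neck_len)
            if extent >= grid_size / 2.0 - 1:
                break
            margin = grid_size / 2.0 - extent - 1.0
            shift = rng.uniform(-margin, margin, size=2)
            mask = _rasterize_mushroom(
                grid_size, head_a, head_b, neck_w, neck_len, theta, tuple(shift)
            )
            area = int(mask.sum())
            if area == 0:
                mask = None
                break
            if abs(area - target_px) <= max(1.0, 0.01 * target_px):
                break
            scale *= np.sqrt(target_px / area)
        if mask is None:
            continue
        area = int(mask.sum())
        ok_area = lo_px <= area <= hi_px or (
            degenerate and abs(area - target_px) <= 0.02 * target_px
        )
        if not ok_area:
            continue
        # fully inside the grid: no mask pixel on the border
        if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
            continue
        n_comp = ndimage.label(mask)[1]
        if n_comp != 1:
            continue
        return mask
    raise ConstraintError(
        "could not rasterize a spine mask satisfying the area window "
        f"[{area_min_um2}, {area_max_um2}] um^2 in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Nanodomain placement
# ---------------------------------------------------------------------------

def edge_distance_map(spine_mask: np.ndarray, pixel_size_nm: float = PIXEL_SIZE_NM) -> np.ndarray:
    """Distance (nm) from each spine pixel to the nearest non-spine pixel."""
    return ndimage.distance_transform_edt(spine_mask) * pixel_size_nm


def place_nanodomains(
    spine_mask: np.ndarray,
    n_domains: int,
    rng: np.random.Generator,
    min_sep_nm: float = 40.0,
    max_edge_nm: float = 140.0,
    pixel_size_nm: float = PIXEL_SIZE_NM,
    max_retries: int = 10_000,
) -> tuple[tuple[int, int], ...]:
    """Place nanodomain centres on the spine edge band by rejection sampling.

    Every centre lies strictly closer than ``max_edge_nm`` to the spine edge
    and every pair of centres is at least ``min_sep_nm`` apart.
    """
    if not 1 <= n_domains <= 6:
        raise ValueError("n_domains must be in [1, 6]")
    if not spine_mask.any():
        raise ConstraintError("spine mask is empty")
    dist_nm = edge_distance_map(spine_mask, pixel_size_nm)
    eligible = np.argwhere(spine_mask & (dist_nm < max_edge_nm))
    if len(eligible) < n_domains:
        raise ConstraintError(
            f"edge band has only {len(eligible)} eligible pixels for "
            f"{n_domains} nanodomains (max_edge_nm={max_edge_nm})"
        )
    min_sep_px = min_sep_nm / pixel_size_nm
    for _ in range(max_retries):
        picks = eligible[rng.choice(len(eligible), size=n_domains, replace=False)]
        diff = picks[:, None, :] - picks[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(n_domains, k=1)
        if n_domains == 1 or (d[iu] >= min_sep_px).all():
            return tuple((int(r), int(c)) for r, c in picks)
    raise ConstraintError(
        f"could not place {n_domains} centres with pairwise separation >= "
        f"{min_sep_nm} nm in {max_retries} attempts (violated: min_sep_nm)"
    )


def build_datamap(
    spine_mask: np.ndarray,
    centers: Sequence[tuple[int, int]],
    base_density: float = 5.0,
    domain_amplitude: float = 50.0,
    domain_size_px: int = 1,
    pixel_size_nm: float = PIXEL_SIZE_NM,
) -> Datamap:
    """Assemble a datamap: uniform spine density plus bright nanodomain pixels.

    A nanodomain is ``domain_size_px`` x ``domain_size_px`` pixels (one pixel
    = 20 x 20 nm by default) of ``base_density + domain_amplitude`` molecules.
    """
    if base_density <= 0 or domain_amplitude <= base_density:
        raise ValueError("need base_density > 0 and domain_amplitude > base_density")
    counts = np.where(spine_mask, base_density, 0.0)
    half = domain_size_px // 2
    for (r, c) in centers:
        if not spine_mask[r, c]:
            raise ValueError(f"nanodomain centre {(r, c)} lies outside the spine mask")
        counts[r - half : r + half + domain_size_px - 2 * half,
               c - half : c + half + domain_size_px - 2 * half] += domain_amplitude
    return Datamap(
        counts=counts.astype(np.float64),
        spine_mask=spine_mask.astype(bool),
        centers=tuple((int(r), int(c)) for r, c in centers),
        pixel_size_nm=pixel_size_nm,
    )


def validate_datamap(
    dm: Datamap,
    min_sep_nm: float = 40.0,
    max_edge_nm: float = 140.0,
    area_min_um2: float = 0.12,
    area_max_um2: float = 0.48,
) -> list[str]:
    """Brute-force re-check of every datamap invariant; returns violations.

    Independent of the generator's bookkeeping: distances are recomputed from
    raw coordinates and the mask with explicit loops over pixel pairs.
    """
    problems: list[str] = []
    mask = dm.spine_mask
    if (np.asarray(dm.counts) < 0).any():
        problems.append("negative counts")
    if np.any((dm.counts != 0) & ~mask):
        problems.append("nonzero counts outside spine mask")
    area_um2 = mask.sum() * (dm.pixel_size_nm * 1e-3) ** 2
    if not (area_min_um2 - 1e-9 <= area_um2 <= area_max_um2 + 1e-9):
        problems.append(f"spine area {area_um2:.4f} um^2 outside window")
    bg = np.argwhere(~mask)
    for (r, c) in dm.centers:
        if not mask[r, c]:
            problems.append(f"centre {(r, c)} outside mask")
            continue
        d_edge = np.sqrt(((bg - (r, c)) ** 2).sum(1)).min() * dm.pixel_size_nm
        if d_edge >= max_edge_nm:
            problems.append(f"centre {(r, c)} is {d_edge:.1f} nm from edge")
    for i in range(len(dm.centers)):
        for j in range(i + 1, len(dm.centers)):
            (r1, c1), (r2, c2) = dm.centers[i], dm.centers[j]
            d = np.hypot(r1 - r2, c1 - c2) * dm.pixel_size_nm
            if d < min_sep_nm:
                problems.append(f"centres {i},{j} only {d:.1f} nm apart")
    return problems


# ---------------------------------------------------------------------------
# Optical forward model
# ---------------------------------------------------------------------------

def render_image(
    datamap: Datamap,
    config: ImagingConfig,
    rng: np.random.Generator | None = None,
    noise_free: bool = False,
    frame_index: int = 0,
    region: tuple[int, int, int, int] | None = None,
) -> AcquiredImage:
    """Render a photon-count image of a datamap for one modality.

    The per-pixel photon mean is
    ``photons_per_molecule * (counts (*) GaussianPSF(fwhm)) + background``;
    the output is a Poisson draw from that mean unless ``noise_free``.
    """
    sigma_px = config.psf_fwhm_nm * _FWHM_TO_SIGMA / datamap.pixel_size_nm
    counts = np.asarray(datamap.counts, dtype=np.float64)
    if region is not None:
        r0, c0, h, w = region
        if r0 < 0 or c0 < 0 or r0 + h > counts.shape[0] or c0 + w > counts.shape[1]:
            raise ValueError("region does not fit inside the field of view")
    blurred = ndimage.gaussian_filter(counts, sigma_px, mode="constant")
    mean = config.photons_per_molecule * blurred + config.background_rate
    if region is not None:
        r0, c0, h, w = region
        mean = mean[r0 : r0 + h, c0 : c0 + w]
    if noise_free:
        pixels = mean
    else:
        if rng is None:
            raise ValueError("rng is required for Poisson sampling")
        pixels = rng.poisson(mean).astype(np.int64)
    return AcquiredImage(
        pixels=pixels,
        modality=config.modality,
        pixel_size_nm=datamap.pixel_size_nm,
        frame_index=frame_index,
        region=region,
    )


def apply_bleaching(
    datamap: Datamap, config: ImagingConfig, rng: np.random.Generator
) -> Datamap:
    """Photobleach a datamap: binomial thinning with survival 1 - bleach_fraction."""
    if config.bleach_fraction == 0.0:
        return datamap
    n = np.floor(datamap.counts).astype(np.int64)
    frac = datamap.counts - n
    survive = rng.binomial(n, 1.0 - config.bleach_fraction).astype(np.float64)
    survive += frac * (1.0 - config.bleach_fraction)
    return dataclasses.replace(datamap, counts=survive)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Counts and geometry of the simulated nanodomain dataset.

    Defaults reproduce the published dataset: 200 train-pool datamaps for
    each nanodomain count N in 1..6 (1,200 total, split 90/10 into 1,080
    training / 120 validation), a 75-map test set (15 per N in 2..6) and an
    80-map two-domain test set whose pair distances cover 40-450 nm.
    """

    per_n_train: int = 200
    train_n_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    val_fraction: float = 0.1
    test1_per_n: int = 15
    test1_n_values: tuple[int, ...] = (2, 3, 4, 5, 6)
    test2_count: int = 80
    test2_dist_range_nm: tuple[float, float] = (40.0, 450.0)
    grid_size: int = 64
    pixel_size_nm: float = PIXEL_SIZE_NM
    area_min_um2: float = 0.12
    area_max_um2: float = 0.48
    base_density: float = 5.0
    domain_amplitude: float = 50.0
    out_dir: str | None = None
    force: bool = False


def random_datamap(
    rng: np.random.Generator, n_domains: int, cfg: DatasetConfig | None = None
) -> Datamap:
    """One random datamap: spine shape, edge-band nanodomains, counts."""
    cfg = cfg or DatasetConfig()
    mask = generate_spine_shape(
        rng, cfg.area_min_um2, cfg.area_max_um2, cfg.grid_size, cfg.pixel_size_nm
    )
    centers = place_nanodomains(mask, n_domains, rng, pixel_size_nm=cfg.pixel_size_nm)
    return build_datamap(
        mask, centers, cfg.base_density, cfg.domain_amplitude,
        pixel_size_nm=cfg.pixel_size_nm,
    )


def _two_domain_datamap(
    rng: np.random.Generator, dist_nm: float, cfg: DatasetConfig
) -> Datamap:
    """A two-nanodomain datamap whose centre separation is close to dist_nm."""
    d_px = dist_nm / cfg.pixel_size_nm
    for _ in range(4000):
        mask = generate_spine_shape(
            rng, cfg.area_min_um2, cfg.area_max_um2, cfg.grid_size, cfg.pixel_size_nm
        )
        dist_map = edge_distance_map(mask, cfg.pixel_size_nm)
        eligible = np.argwhere(mask & (dist_map < 140.0))
        if len(eligible) < 2:
            continue
        first = eligible[rng.choice(len(eligible), size=min(len(eligible), 40), replace=False)]
        elig_set = {(int(r), int(c)) for r, c in eligible}
        for (r0, c0) in first:
            angles = rng.uniform(0, 2 * np.pi, size=48)
            for a in angles:
                r1 = int(round(r0 + d_px * np.sin(a)))
                c1 = int(round(c0 + d_px * np.cos(a)))
                if (r1, c1) == (r0, c0) or (r1, c1) not in elig_set:
                    continue
                actual = np.hypot(r1 - r0, c1 - c0) * cfg.pixel_size_nm
                lo_nm, hi_nm = cfg.test2_dist_range_nm
                if not lo_nm <= actual <= hi_nm:
                    continue
                if abs(actual - dist_nm) > 0.75 * cfg.pixel_size_nm:
                    continue
                return build_datamap(
                    mask, [(int(r0), int(c0)), (r1, c1)],
                    cfg.base_density, cfg.domain_amplitude,
                    pixel_size_nm=cfg.pixel_size_nm,
                )
    raise ConstraintError(
        f"could not place a nanodomain pair {dist_nm:.0f} nm apart"
    )


def generate_dataset(
    cfg: DatasetConfig,
    rng: np.random.Generator | int,
    collect: list | None = None,
) -> pd.DataFrame:
    """Generate the full simulated dataset and return its manifest.

    Each manifest row describes one item (id, split, n_domains, pair distance
    for the two-domain test set, seed, and file paths when ``cfg.out_dir`` is
    set).  With an output directory the datamap, confocal render, STED render
    and cubic-root localization target are written as TIFF files.  Passing a
    list as ``collect`` appends every ``(item_id, Datamap)`` to it (in-memory
    use without file output).
    """
    from . import io as tio
    from .annotate import cubic_root_localization_map

    if isinstance(rng, (int, np.integer)):
        root = np.random.SeedSequence(int(rng))
    else:
        root = np.random.SeedSequence(rng.integers(0, 2**31 - 1))
    write = cfg.out_dir is not None
    if write:
        if os.path.isdir(cfg.out_dir) and os.listdir(cfg.out_dir) and not cfg.force:
            raise FileExistsError(
                f"output directory {cfg.out_dir!r} is not empty (use force)"
            )
        os.makedirs(cfg.out_dir, exist_ok=True)

    items: list[dict] = []

    def emit(item_id: str, split: str, dm: Datamap, child: np.random.SeedSequence) -> None:
        if collect is not None:
            collect.append((item_id, dm))
        srng = np.random.default_rng(child)
        row = {
            "id": item_id,
            "split": split,
            "n_domains": dm.n_domains,
            "seed": int(child.entropy) if isinstance(child.entropy, int) else 0,
            "pair_distance_nm": (
                float(np.hypot(
                    dm.centers[0][0] - dm.centers[1][0],
                    dm.centers[0][1] - dm.centers[1][1],
                ) * dm.pixel_size_nm) if dm.n_domains == 2 else np.nan
            ),
        }
        if write:
            conf = render_image(dm, CONFOCAL, srng)
            sted = render_image(dm, STED, srng)
            loc = cubic_root_localization_map(dm.centers, dm.shape)
            base = os.path.join(cfg.out_dir, item_id)
            tio.write_tiff(base + "_datamap.tif", dm.counts, cfg.pixel_size_nm)
            tio.write_tiff(base + "_confocal.tif", conf.pixels, cfg.pixel_size_nm)
            tio.write_tiff(base + "_sted.tif", sted.pixels, cfg.pixel_size_nm)
            tio.write_tiff(base + "_locmap.tif", loc.astype(np.float32), cfg.pixel_size_nm)
            row.update(
                datamap_path=base + "_datamap.tif",
                confocal_path=base + "_confocal.tif",
                sted_path=base + "_sted.tif",
                locmap_path=base + "_locmap.tif",
            )
        items.append(row)

    # -- train pool -------------------------------------------------------
    pool: list[tuple[int, np.random.SeedSequence]] = []
    n_pool = cfg.per_n_train * len(cfg.train_n_values)
    children = root.spawn(n_pool)
    k = 0
    for n in cfg.train_n_values:
        for _ in range(cfg.per_n_train):
            pool.append((n, children[k]))
            k += 1
    split_rng = np.random.default_rng(root.spawn(1)[0])
    order = split_rng.permutation(n_pool)
    n_val = int(round(cfg.val_fraction * n_pool))
    val_idx = set(order[:n_val].tolist())
    for i, (n, child) in enumerate(pool):
        dm = random_datamap(np.random.default_rng(child), n, cfg)
        emit(f"train{i:04d}", "validation" if i in val_idx else "train", dm, child)

    # -- test set 1: 2..6 nanodomains ------------------------------------
    t1_children = root.spawn(cfg.test1_per_n * len(cfg.test1_n_values))
    k = 0
    for n in cfg.test1_n_values:
        for _ in range(cfg.test1_per_n):
            dm = random_datamap(np.random.default_rng(t1_children[k]), n, cfg)
            emit(f"test1_{k:03d}", "test1", dm, t1_children[k])
            k += 1

    # -- test set 2: two domains, distance swept over the stated range ----
    lo, hi = cfg.test2_dist_range_nm
    t2_children = root.spawn(cfg.test2_count)
    dist_rng = np.random.default_rng(root.spawn(1)[0])
    for k in range(cfg.test2_count):
        d = dist_rng.uniform(lo, hi)
        dm = _two_domain_datamap(np.random.default_rng(t2_children[k]), d, cfg)
        emit(f"test2_{k:03d}", "test2", dm, t2_children[k])

    manifest = pd.DataFrame(items)
    if write:
        manifest.to_csv(os.path.join(cfg.out_dir, "manifest.csv"), index=False)
    return manifest
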