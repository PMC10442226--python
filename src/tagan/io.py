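"""TIFF round-tripping, run configuration, checkpoints and test fixtures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "FormatError",
    "write_tiff",
    "read_tiff",
    "RunConfig",
    "save_checkpoint",
    "load_checkpoint",
    "make_fixtures",
    "bundle_hashes",
]


class FormatError(ValueError):
    """An input raster is not a grayscale TIFF this package understands."""


def write_tiff(path, image: np.ndarray, pixel_size_nm: float | None = None) -> str:
    """Write a grayscale raster losslessly (16-bit counts, 8-bit masks).

    Integer photon counts are stored as uint16, boolean masks as uint8 and
    floating-point maps as float32.  The pixel size is stored in the image
    description and survives a round trip.
    """
    image = np.asarray(image)
    if image.dtype == bool:
        out = image.astype(np.uint8)
    elif np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() > np.iinfo(np.uint16).max:
            raise FormatError("integer image outside the uint16 range")
        out = image.astype(np.uint16)
    else:
        out = image.astype(np.float32)
    desc = json.dumps({"pixel_size_nm": pixel_size_nm}) if pixel_size_nm else None
    tifffile.imwrite(str(path), out, description=desc)
    return str(path)


def read_tiff(path) -> tuple[np.ndarray, float | None]:
    """Read a grayscale single/multi-page TIFF; returns (array, pixel size).

    RGB inputs and unreadable files raise :class:`FormatError` naming the
    offending dialect rather than crashing downstream.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            if page.samplesperpixel != 1:
                raise FormatError(
                    f"{path}: expected grayscale, got {page.samplesperpixel} "
                    "samples per pixel (RGB/multisample TIFF unsupported)"
                )
            arr = tf.asarray()
            px = None
            desc = page.description
            if desc:
                try:
                    px = json.loads(desc).get("pixel_size_nm")
                except (json.JSONDecodeError, AttributeError):
                    px = None
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt containers
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    return arr, px


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Strict-schema configuration for the CLI entry points.

    Defaults mirror the published operating point: K = 10 MC samples, 80%
    consensus band, trigger thresholds 0.5, task weights lambda_GEN 100 /
    lambda_GAN 1 / lambda_CYC 10, Adam at 2e-4.
    """

    seed: int = 0
    data_dir: str = "."
    out_dir: str = "out"
    task_kind: str = "localization"
    class_names: list[str] = field(default_factory=list)
    lambda_gen: float = 100.0
    lambda_gan: float = 1.0
    lambda_cyc: float = 10.0
    learning_rate: float = 2e-4
    n_steps: int = 300
    batch_size: int = 4
    theta_dc: float = 0.5
    theta_vs: float = 0.5
    K: int = 10
    consensus: float = 0.8
    n_frames: int = 15

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net, seed: int | None = None) -> str:
    """Single-file archive of a network: spec, weights, seed provenance."""
    spec = dataclasses.asdict(net.spec)
    blob = {
        "spec": spec,
        "arch": getattr(net, "arch", "unet"),
        "class": type(net).__name__,
        "params": net.params,
        "seed": seed,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)
    return str(path)


def load_checkpoint(path):
    """Rebuild a network from :func:`save_checkpoint` output."""
    from . import nets

    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    spec = nets.GeneratorSpec(**blob["spec"])
    rng = np.random.default_rng(0)
    cls = blob["class"]
    if cls == "Generator":
        net = nets.Generator(spec, rng)
    elif cls == "TaskNetwork":
        net = nets.TaskNetwork(spec, rng, arch=blob.get("arch", "unet"))
    elif cls == "PatchDiscriminator":
        net = nets.PatchDiscriminator(spec.in_channels, rng)
    else:
        raise FormatError(f"unknown checkpoint class {cls!r}")
    net.params = blob["params"]
    return net


# ---------------------------------------------------------------------------
# Deterministic fixture bundle
# ---------------------------------------------------------------------------

def _bacterial_phantom(size: int = 96) -> dict:
    """Synthetic two-lobe dividing-cell phantom (SIM-like image + LR mask).

    Two overlapping discs with a bright outer rim and a bright septum at
    their interface; the LR annotation is the whole-cell union mask.  A
    synthetic stand-in for the real bacterial dataset.
    """
    rr, cc = np.mgrid[0:size, 0:size]
    c1 = ((rr - size / 2) ** 2 + (cc - size / 2 + 11) ** 2) <= 15 ** 2
    c2 = ((rr - size / 2) ** 2 + (cc - size / 2 - 11) ** 2) <= 15 ** 2
    union = c1 | c2
    from scipy import ndimage

    rim = union & ~ndimage.binary_erosion(union, iterations=2)
    septum = union & (np.abs(cc - size / 2) <= 1) & ndimage.binary_erosion(union, iterations=3)
    img = 10.0 + 120.0 * rim + 120.0 * septum + 30.0 * union
    return {"sim_image": img, "lr_mask": union.astype(np.uint8),
            "septum": septum, "rim": rim}


def _cluster_phantom(rng: np.random.Generator, size: int = 128) -> dict:
    """Two-channel phantom of Gaussian protein clusters."""
    from scipy import ndimage

    imgs = []
    centers = []
    for ch in range(2):
        img = np.zeros((size, size))
        pts = rng.integers(16, size - 16, size=(6, 2))
        for (r, c) in pts:
            img[r, c] = rng.uniform(80, 150)
        imgs.append(ndimage.gaussian_filter(img, 2.5) * 50 + 2.0)
        centers.append(pts)
    return {"channels": imgs, "true_centers": centers}


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic mini-bundle used across the test suite.

    Contains six datamaps spanning 1-6 nanodomains, a scripted-change
    acquisition scenario seed, a two-lobe bacterial phantom and a
    two-channel cluster phantom.  Builds in a few seconds on one CPU.
    """
    from . import simulate as sim

    root = np.random.SeedSequence(seed)
    dm_seeds = root.spawn(6)
    datamaps = [
        sim.random_datamap(np.random.default_rng(dm_seeds[n - 1]), n)
        for n in range(1, 7)
    ]
    rng = np.random.default_rng(root.spawn(1)[0])
    return {
        "datamaps": datamaps,
        "scripted_change_seed": int(np.random.default_rng(root.spawn(1)[0]).integers(2 ** 31 - 1)),
        "bacterial_phantom": _bacterial_phantom(),
        "cluster_phantom": _cluster_phantom(rng),
    }


def bundle_hashes(bundle: dict) -> dict[str, str]:
    """Stable content hashes of the fixture bundle (reproducibility check)."""
    out = {}
    for i, dm in enumerate(bundle["datamaps"]):
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(dm.counts).tobytes())
        h.update(repr(dm.centers).encode())
        out[f"datamap{i}"] = h.hexdigest()
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(bundle["bacterial_phantom"]["sim_image"]).tobytes())
    out["bacterial_phantom"] = h.hexdigest()
    for ch, img in enumerate(bundle["cluster_phantom"]["channels"]):
        h = hashlib.sha256(np.ascontiguousarray(img).tobytes())
        out[f"cluster_ch{ch}"] = h.hexdigest()
    return out
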