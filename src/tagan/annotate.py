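"""Task-target construction and dataset preparation.

Every auxiliary-task annotation used to steer the generator is built here:

* cubic-root distance maps to the nearest nanodomain centre (localization
  target for the simulated dataset),
* Gaussian-blurred weighted-centroid maps for protein clusters,
* a-trous B3-spline wavelet segmentation of punctate clusters,
* high-resolution dividing-cell boundary masks derived from SIM images,

plus the sliding-window coverage-filtered cropping and the corner/dihedral
augmentation used to prepare training sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure

__all__ = [
    "AnnotationStack",
    "cubic_root_localization_map",
    "centroid_localization_map",
    "atrous_wavelet_planes",
    "wavelet_segment_clusters",
    "hr_division_annotation",
    "crop_with_coverage_filter",
    "augment_corners_and_dihedral",
    "DIHEDRAL_TRANSFORMS",
]

CHANNEL_KINDS = ("binary_mask", "semantic_mask", "localization_map")


@dataclass
class AnnotationStack:
    """Named per-image task targets sharing one raster geometry.

    ``channels`` maps a name to a 2-D raster; ``kinds`` tags each channel as
    a binary mask, semantic mask or localization map.
    """

    channels: dict[str, np.ndarray]
    kinds: dict[str, str]
    class_names: list[str] = field(default_factory=list)
    pixel_size_nm: float = 20.0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"annotation channels disagree on shape: {shapes}")
        for name, arr in self.channels.items():
            kind = self.kinds.get(name)
            if kind not in CHANNEL_KINDS:
                raise ValueError(f"channel {name!r} has unknown kind {kind!r}")
            if kind in ("binary_mask", "semantic_mask"):
                if not np.isin(np.unique(arr), (0, 1)).all():
                    raise ValueError(f"mask channel {name!r} is not 0/1-valued")
            elif (np.asarray(arr) < 0).any():
                raise ValueError(f"localization channel {name!r} has negatives")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def cubic_root_localization_map(
    centers: Sequence[tuple[int, int]], grid_shape: tuple[int, int]
) -> np.ndarray:
    """Map of the cubic root of the pixel distance to the nearest centre.

    The value is exactly 0 at every centre pixel; distances are Euclidean in
    pixel units.
    """
    if len(centers) == 0:
        raise ValueError("localization map is undefined without centres")
    marker = np.ones(grid_shape, dtype=np.uint8)
    for (r, c) in centers:
        if not (0 <= r < grid_shape[0] and 0 <= c < grid_shape[1]):
            raise ValueError(f"centre {(r, c)} outside grid {grid_shape}")
        marker[r, c] = 0
    dist = ndimage.distance_transform_edt(marker)
    return np.cbrt(dist)


def centroid_localization_map(
    image: np.ndarray,
    cluster_masks: np.ndarray,
    sigma: float = 2.0,
) -> np.ndarray:
    """Impulse at each cluster's intensity-weighted centroid, blurred sigma=2.

    ``cluster_masks`` is a labelled mask (0 = background).  Centroids are
    weighted by the raw image intensities; a zero-intensity cluster falls
    back to its unweighted centroid.  Centroid coordinates round to the
    nearest pixel, ties toward the lower index.
    """
    labels = np.asarray(cluster_masks)
    if labels.shape != image.shape:
        raise ValueError("image and cluster_masks must share a shape")
    out = np.zeros(image.shape, dtype=np.float64)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        w = np.asarray(image, dtype=np.float64)[rr, cc]
        if w.sum() <= 0:
            w = np.ones_like(w)
        r = float((rr * w).sum() / w.sum())
        c = float((cc * w).sum() / w.sum())
        # round half toward the lower index
        ri = int(np.ceil(r - 0.5))
        ci = int(np.ceil(c - 0.5))
        out[ri, ci] += 1.0
    if sigma > 0:
        out = ndimage.gaussian_filter(out, sigma)
    return out


# ---------------------------------------------------------------------------
# Wavelet cluster segmentation
# ---------------------------------------------------------------------------

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def atrous_wavelet_planes(image: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Undecimated a-trous B3-spline wavelet planes W_1..W_n of an image."""
    a_prev = np.asarray(image, dtype=np.float64)
    planes = []
    for j in range(1, n_scales + 1):
        holes = 2 ** (j - 1)
        kernel = np.zeros((len(_B3) - 1) * holes + 1)
        kernel[::holes] = _B3
        a_next = ndimage.convolve1d(a_prev, kernel, axis=0, mode="reflect")
        a_next = ndimage.convolve1d(a_next, kernel, axis=1, mode="reflect")
        planes.append(a_prev - a_next)
        a_prev = a_next
    return planes


def wavelet_segment_clusters(
    image: np.ndarray,
    scales: Iterable[int] = (3, 4),
    min_area: int = 5,
    min_wh: int = 3,
    k: float = 3.0,
    apply_filters: bool = True,
) -> np.ndarray:
    """Segment punctate clusters by a-trous wavelet hard thresholding.

    A pixel is detected when its wavelet coefficient exceeds ``k`` times the
    median absolute deviation of that scale plane, at every requested scale
    (product rule over scales 3 and 4 by default).  With ``apply_filters``
    connected components smaller than ``min_area`` pixels or whose bounding
    box is narrower/shorter than ``min_wh`` are removed; switch it off to
    keep every detected cluster.  Returns a labelled mask.
    """
    img = np.asarray(image, dtype=np.float64)
    if (img < 0).any():
        raise ValueError("expected a non-negative single-channel image")
    scales = sorted(set(int(s) for s in scales))
    planes = atrous_wavelet_planes(img, max(scales))
    det = np.ones(img.shape, dtype=bool)
    for s in scales:
        w = planes[s - 1]
        mad = np.median(np.abs(w - np.median(w)))
        det &= w > k * mad
    labeled, _ = ndimage.label(det)
    if apply_filters and labeled.max():
        keep = np.zeros(labeled.max() + 1, dtype=bool)
        for p in measure.regionprops(labeled):
            r0, c0, r1, c1 = p.bbox
            if p.area >= min_area and (r1 - r0) >= min_wh and (c1 - c0) >= min_wh:
                keep[p.label] = True
        labeled = np.where(keep[labeled], labeled, 0)
        labeled, _ = ndimage.label(labeled > 0)
    return labeled


# ---------------------------------------------------------------------------
# Dividing-cell boundary annotation (bright-field / SIM dataset)
# ---------------------------------------------------------------------------

def _minmax(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    return np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)


def hr_division_annotation(
    sim_image: np.ndarray,
    lr_whole_cell_mask: np.ndarray,
    threshold_frac: float = 0.2,
    sigma: float = 1.0,
) -> np.ndarray:
    """High-resolution annotation of the boundary between dividing cells.

    Sobel gradient magnitude of the (min-max normalized) SIM image, Gaussian
    blurred (sigma=1), thresholded at ``threshold_frac`` of its maximum,
    yields outer membranes plus division septa; the cell-border mask derived
    the same way from the low-resolution whole-cell annotation is subtracted,
    leaving the septum pixels.
    """
    if sim_image.shape != lr_whole_cell_mask.shape:
        raise ValueError("SIM image and LR mask must be co-registered")
    grad = ndimage.gaussian_filter(skfilters.sobel(_minmax(sim_image)), sigma)
    if grad.max() <= 0:
        return np.zeros(sim_image.shape, dtype=np.uint8)
    hr = grad >= threshold_frac * grad.max()
    lr_border = ndimage.gaussian_filter(
        skfilters.sobel(np.asarray(lr_whole_cell_mask, dtype=np.float64)), sigma
    ) > 0
    return np.clip(hr.astype(np.int8) - lr_border.astype(np.int8), 0, 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------

def crop_with_coverage_filter(
    images: Mapping[str, np.ndarray],
    annotation: np.ndarray,
    crop: int = 256,
    overlap: int = 128,
    min_annotated_frac: float = 0.03,
) -> list[dict]:
    """Sliding-window crops kept only when sufficiently annotated.

    All channels in ``images`` are cropped with identical geometry (stride =
    ``crop - overlap``); a candidate is kept iff the fraction of nonzero
    annotation pixels inside it is at least ``min_annotated_frac``.
    """
    if not 0 <= min_annotated_frac < 1:
        raise ValueError("min_annotated_frac must be in [0, 1)")
    if not 0 <= overlap < crop:
        raise ValueError("need 0 <= overlap < crop")
    h, w = annotation.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} exceeds image size {(h, w)}")
    for name, arr in images.items():
        if arr.shape[:2] != (h, w):
            raise ValueError(f"channel {name!r} shape mismatch")
    stride = crop - overlap
    kept = []
    for r0 in range(0, h - crop + 1, stride):
        for c0 in range(0, w - crop + 1, stride):
            ann = annotation[r0 : r0 + crop, c0 : c0 + crop]
            frac = float(np.count_nonzero(ann)) / ann.size
            if frac >= min_annotated_frac:
                kept.append(
                    {
                        "row0": r0,
                        "col0": c0,
                        "annotated_frac": frac,
                        "annotation": ann.copy(),
                        "channels": {
                            name: arr[r0 : r0 + crop, c0 : c0 + crop].copy()
                            for name, arr in images.items()
                        },
                    }
                )
    return kept


#: The 8 elements of the dihedral group D4 as array transforms.
DIHEDRAL_TRANSFORMS = tuple(
    (lambda a, k=k, f=f: np.rot90(np.fliplr(a) if f else a, k))
    for f in (False, True)
    for k in range(4)
)


def augment_corners_and_dihedral(
    image: np.ndarray, corner_crop: int = 128
) -> list[np.ndarray]:
    """Corner-crop + flip/rotation augmentation.

    Crops the four corners to ``corner_crop`` squares and applies the 8
    dihedral transforms to each (32 outputs).  When the image already equals
    the corner size the cropping stage is skipped (8 outputs).
    """
    h, w = image.shape[:2]
    if h < corner_crop or w < corner_crop:
        raise ValueError(f"image {(h, w)} smaller than corner crop {corner_crop}")
    if (h, w) == (corner_crop, corner_crop):
        corners = [image]
    else:
        s = corner_crop
        corners = [
            image[:s, :s], image[:s, -s:], image[-s:, :s], image[-s:, -s:]
        ]
    return [t(c).copy() for c in corners for t in DIHEDRAL_TRANSFORMS]
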