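"""Microtubule-network quantification in fluorescence images.

The pipeline mirrors the standard Fiji workflow for scoring how much of
a cell is occupied by polymerized microtubules: a Hessian-based tubeness
ridge filter at a fixed scale picks out curvilinear bright structures,
the response is converted to 8-bit, binarized at a single threshold
shared by all images of a comparison batch, and the thresholded area is
expressed as a percent of the cell-contour area.  Pearson colocalization
and threshold-based colony counting round out the particle-analysis
toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, remove_small_holes

__all__ = [
    "tubeness",
    "to_8bit",
    "ridge_noise_floor",
    "polymerized_percent",
    "batch_polymerized_percent",
    "derive_cell_mask",
    "area_percent",
    "pearson_colocalization",
    "count_colonies",
    "MTQuantResult",
]


def _signed_ridge(image, sigma: float) -> np.ndarray:
    """Unclamped ridge strength -l2 (positive on bright ridges, noise-symmetric
    around 0 on background)."""
    # reflective boundaries: a constant image has zero response everywhere
    H = hessian_matrix(image, sigma=sigma, mode="reflect", use_gaussian_derivatives=True)
    return -hessian_matrix_eigvals(H)[-1]


def tubeness(image, sigma: float = 1.0) -> np.ndarray:
    """Hessian ridge (tubeness) response for bright curvilinear structures.

    At each pixel the Hessian of the Gaussian-smoothed image at scale
    ``sigma`` is computed; with eigenvalues l1 >= l2, the response is
    ``|l2|`` where l2 < 0 and 0 elsewhere.  A bright ridge on a dark
    background has a strongly negative second eigenvalue across the
    ridge, so the response traces filament centerlines and is zero on
    flat background.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if min(img.shape) < 7:
        raise ValueError("image must be at least 7x7 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return np.clip(_signed_ridge(img, sigma), 0.0, None)


def to_8bit(image, mode: str = "minmax", lo: float | None = None, hi: float | None = None):
    """Linear conversion to 8-bit with clipping.

    ``mode='minmax'`` scales the image's own range to 0-255 (a constant
    image maps to all zeros); ``mode='fixed'`` scales the window
    ``[lo, hi]``, which keeps the conversion identical across a batch.
    Returns ``(uint8 image, metadata dict)``.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if mode == "minmax":
        lo, hi = float(img.min()), float(img.max())
        if hi <= lo:
            return np.zeros(img.shape, dtype=np.uint8), {"mode": mode, "lo": lo, "hi": hi}
    elif mode == "fixed":
        if lo is None or hi is None:
            raise ValueError("fixed mode needs lo and hi")
        if lo >= hi:
            raise ValueError("fixed mode requires lo < hi")
    else:
        raise ValueError(f"mode must be 'minmax' or 'fixed', got {mode!r}")
    scaled = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8), {"mode": mode, "lo": float(lo), "hi": float(hi)}


@dataclass
class MTQuantResult:
    """Polymerized-microtubule quantification for one image."""

    percent: float
    threshold: int
    cell_area_px: int
    structure_area_px: int
    response: np.ndarray
    structure_mask: np.ndarray


def derive_cell_mask(image, blur_sigma: float = 10.0) -> np.ndarray:
    """Cell-contour mask from the tubulin channel: heavy Gaussian blur + Otsu."""
    img = np.asarray(image, dtype=float)
    blurred = ndimage.gaussian_filter(img, blur_sigma)
    return blurred > threshold_otsu(blurred)


def ridge_noise_floor(image, cell_mask, sigma: float = 1.0, k: float = 3.0) -> float:
    """Noise-floor binarization threshold for the tubeness response.

    On background the unclamped ridge strength fluctuates symmetrically
    around ~0, so its sub-median half inside the cell is essentially
    noise even when filaments cover much of the cell.  The robust SD of
    that half (MAD-based) estimates the response noise; the threshold is
    ``k`` times it.  Returned in response (not 8-bit) units.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(cell_mask, dtype=bool)
    r = _signed_ridge(img, sigma)[mask]
    med = np.median(r)
    lower = r[r < med]
    if lower.size == 0:
        return 0.0
    sd = 1.4826 * np.median(np.abs(lower - med))
    return float(k * sd)


def area_percent(structure_mask, cell_mask) -> float:
    """100 * |structure inside cell| / |cell|."""
    cell = np.asarray(cell_mask, dtype=bool)
    structure = np.asarray(structure_mask, dtype=bool)
    if structure.shape != cell.shape:
        raise ValueError("masks must be congruent")
    if not cell.any():
        raise ValueError("cell mask is empty")
    return 100.0 * int((structure & cell).sum()) / int(cell.sum())


def polymerized_percent(
    image,
    cell_mask,
    sigma: float = 1.0,
    threshold: int | None = None,
    scale_hi: float | None = None,
    closing_radius: int = 3,
    min_hole_px: int = 64,
) -> MTQuantResult:
    """Percent of the cell area occupied by tubule-like structures.

    Pipeline: tubeness(sigma) -> 8-bit -> binarize strictly above
    ``threshold`` -> particle cleanup (morphological closing with a
    ``closing_radius``-px disk, then filling enclosed holes smaller
    than ``min_hole_px``; ridge filters trace filament centerlines, so
    closing recovers the interior of dense filament mats where the
    ridge response drops) -> intersect with ``cell_mask`` ->
    100 * structure area / cell area.

    ``threshold`` is on the 8-bit scale; if None it is derived from the
    ridge-response noise floor of THIS image (``ridge_noise_floor``).
    For batch comparisons derive both threshold and ``scale_hi`` once
    from a control image (``batch_polymerized_percent``) so every image
    is converted and binarized identically.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if mask.shape != img.shape:
        raise ValueError("cell mask must be congruent with the image")
    if not mask.any():
        raise ValueError("cell mask is empty")
    response = tubeness(img, sigma=sigma)
    hi = float(response.max()) if scale_hi is None else float(scale_hi)
    if hi <= 0:
        hi = 1.0
    resp8, _ = to_8bit(response, mode="fixed", lo=0.0, hi=hi)
    if threshold is None:
        floor = ridge_noise_floor(img, mask, sigma=sigma)
        threshold = int(np.floor(255.0 * min(floor, hi) / hi))
    structure = resp8 > threshold
    if closing_radius > 0:
        structure = closing(structure, disk(closing_radius))
    if min_hole_px > 0:
        structure = remove_small_holes(structure, max_size=min_hole_px)
    structure &= mask
    cell_area = int(mask.sum())
    structure_area = int(structure.sum())
    return MTQuantResult(
        percent=100.0 * structure_area / cell_area,
        threshold=int(threshold),
        cell_area_px=cell_area,
        structure_area_px=structure_area,
        response=response,
        structure_mask=structure,
    )


def batch_polymerized_percent(
    images,
    cell_masks,
    sigma: float = 1.0,
    control_index: int = 0,
    threshold: int | None = None,
    **kwargs,
) -> list[MTQuantResult]:
    """Score a comparison batch with one shared threshold and 8-bit window.

    The 8-bit window is fixed(0, batch max tubeness response); the
    threshold, unless given, is the ridge-noise floor of the control
    image, then reused for every image — the "same threshold for
    comparison" convention.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    masks = [np.asarray(m, dtype=bool) for m in cell_masks]
    if len(images) != len(masks) or not images:
        raise ValueError("need equal, non-zero numbers of images and masks")
    responses = [tubeness(im, sigma=sigma) for im in images]
    hi = max(float(r.max()) for r in responses)
    if hi <= 0:
        hi = 1.0
    if threshold is None:
        floor = ridge_noise_floor(images[control_index], masks[control_index], sigma=sigma)
        threshold = int(np.floor(255.0 * min(floor, hi) / hi))
    return [
        polymerized_percent(im, m, sigma=sigma, threshold=threshold, scale_hi=hi, **kwargs)
        for im, m in zip(images, masks)
    ]


def pearson_colocalization(ch1, ch2, mask=None) -> float:
    """Pearson correlation of two channels' intensities inside a mask.

    Returns NaN (undefined) when either channel is constant within the
    mask rather than fabricating a coefficient.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must be congruent")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask must be congruent with the channels")
    x, y = a[mask], b[mask]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def count_colonies(image, min_area_px2: int = 9, threshold: float | None = None) -> int:
    """Count connected components strictly larger than ``min_area_px2``.

    The image is binarized at ``threshold`` (Otsu if None; boolean input
    is used as-is) and components are labeled with 8-connectivity.  A
    component of exactly ``min_area_px2`` pixels does not count.
    """
    img = np.asarray(image)
    if img.dtype == bool:
        binary = img
    else:
        img = img.astype(float)
        if not np.all(np.isfinite(img)):
            raise ValueError("image contains non-finite pixels")
        if threshold is None:
            if img.min() == img.max():
                return 0
            threshold = threshold_otsu(img)
        binary = img > threshold
    labels = label(binary, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas > min_area_px2))
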