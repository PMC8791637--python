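"""Nascent-adhesion segmentation, counting, area, and partitioning.

The counting chain reproduces a published ImageJ macro workflow for
punctate adhesions in a paxillin channel:

    rolling-ball background subtraction (radius 50, sliding)
    -> CLAHE (block 19, 256 bins, max slope 6)
    -> exponential intensity remap ("Exp")
    -> linear contrast stretch (0.35% saturated)
    -> Laplacian-of-Gaussian blob filter (sigma 2)
    -> "Default dark" auto-threshold (iterative intermeans on 256 bins)
    -> particle analysis (size 5-1000 px^2, circularity 0.00-1.00,
       8-connectivity)

The chain first normalizes the field to a 0-255 working range, which makes
the count exactly invariant under global intensity scaling.  Alongside the
chain this module implements the fixed-threshold total-adhesion-area
measurement (16-bit window 5500-65535), an automated adhesion partition
coefficient (three-class Otsu standing in for the manual two-step
thresholding), and GFP-expression gating of cells (mean 1000-5000 a.u.
after background subtraction, inclusive).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_multiotsu
from skimage.measure import label as sk_label, regionprops
from skimage.restoration import rolling_ball

from .core_io import ImageStack, with_provenance
from .errors import ParameterError, SegmentationError

logger = logging.getLogger("phaseq")

__all__ = [
    "rolling_ball_background",
    "clahe",
    "exp_transform",
    "enhance_contrast",
    "log_filter",
    "intermeans_threshold",
    "threshold_default_dark",
    "count_particles",
    "count_adhesions",
    "total_adhesion_area",
    "adhesion_partition_coefficient",
    "gate_cells_by_gfp",
]

EXP_CURVATURE_DEFAULT = 8.0 * math.log(2.0)  # compresses the lower half-range >= 4x


def _pixels2d(image: ImageStack | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError("expected a 2D image")
    return arr.astype(np.float64)


def rolling_ball_background(
    image: ImageStack | np.ndarray, radius_px: int = 50
) -> np.ndarray:
    """Subtract a rolling-ball background estimate; result is non-negative.

    The ball couples spatial and intensity extent, so the image should be
    in a display-like range (the counting chain feeds it a 0-255 float
    field) for ImageJ-comparable behaviour.
    """
    arr = _pixels2d(image)
    if radius_px >= min(arr.shape):
        raise ParameterError("rolling-ball radius must be smaller than the image")
    background = rolling_ball(arr, radius=radius_px)
    return np.clip(arr - background, 0.0, None)


def clahe(
    image: ImageStack | np.ndarray,
    blocksize: int = 19,
    histogram_bins: int = 256,
    max_slope: float = 6.0,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The ImageJ "max slope" clip (histogram clipped at ``max_slope`` times
    the uniform bin height) maps to a normalized clip limit of
    ``max_slope / histogram_bins``.  Output is rescaled back to the input's
    peak so the chain stays in one working range.  A constant image is
    returned unchanged.
    """
    if blocksize < 3:
        raise ParameterError("blocksize must be >= 3")
    arr = _pixels2d(image)
    peak = arr.max()
    if peak <= arr.min():
        return arr.copy()
    eq = equalize_adapthist(
        arr / peak,
        kernel_size=blocksize,
        clip_limit=max_slope / histogram_bins,
        nbins=histogram_bins,
    )
    return eq * peak


def exp_transform(
    image: ImageStack | np.ndarray,
    curvature: float = EXP_CURVATURE_DEFAULT,
    display_max: float | None = None,
) -> np.ndarray:
    """Monotone convex exponential remap suppressing dim background.

    ``v -> M * (exp(c * v / M) - 1) / (exp(c) - 1)`` with working-range
    maximum ``M`` (the image max unless given) and curvature ``c``.  The
    endpoints 0 and M are preserved; interior values map strictly below the
    identity.
    """
    arr = _pixels2d(image)
    m = float(arr.max()) if display_max is None else float(display_max)
    if m <= 0:
        return arr.copy()
    if curvature <= 0:
        raise ParameterError("curvature must be > 0")
    return m * np.expm1(curvature * arr / m) / math.expm1(curvature)


def enhance_contrast(
    image: ImageStack | np.ndarray,
    saturated_percent: float = 0.35,
    out_max: float | None = None,
) -> np.ndarray:
    """Linear rescale clipping ``saturated_percent`` of pixels to the range.

    Half the saturated mass is clipped at each tail (ImageJ "Enhance
    Contrast" semantics, value-changing).  A constant image is returned
    unchanged (logged).
    """
    arr = _pixels2d(image)
    m = float(arr.max()) if out_max is None else float(out_max)
    flat = np.sort(arr, axis=None)
    n = flat.size
    k = int(n * saturated_percent / 200.0)
    low, high = float(flat[k]), float(flat[n - 1 - k])
    if high <= low:
        logger.info("enhance_contrast: constant image, returned unchanged")
        return arr.copy()
    return np.clip((arr - low) / (high - low) * m, 0.0, m)


def log_filter(
    image: ImageStack | np.ndarray, sigma: float = 2.0, out_max: float | None = None
) -> np.ndarray:
    """Laplacian-of-Gaussian blob response, bright blobs high-valued.

    The sign is flipped so bright blobs are maxima, the negative side lobes
    (the dark rings around blobs) are clipped at zero, and the result is
    rescaled to ``[0, out_max]`` (input max by default).  Flat background
    therefore sits at 0 — the dark-background convention the subsequent
    "Default dark" threshold expects.
    """
    arr = _pixels2d(image)
    m = float(arr.max()) if out_max is None else float(out_max)
    # the truncated discrete LoG kernel does not sum exactly to zero; remove
    # that bias so a constant image maps to an exactly-zero response
    bias = ndimage.gaussian_laplace(
        np.ones((1, 1)), sigma=sigma, mode="nearest"
    ).item()
    response = np.clip(-(ndimage.gaussian_laplace(arr, sigma=sigma) - bias * arr), 0.0, None)
    peak = response.max()
    if peak <= 0 or m <= 0:
        return np.zeros_like(arr)
    return response / peak * m


def intermeans_threshold(hist: np.ndarray) -> int:
    """ImageJ "Default" threshold bin from a histogram.

    Iterative intermeans: starting from the lowest occupied bin, the
    candidate index advances while ``index + 1`` is still below the average
    of the two class means; the returned bin is the rounded average at the
    stopping point.  Foreground is everything *above* the returned bin.
    """
    hist = np.asarray(hist, dtype=np.float64)
    occupied = np.nonzero(hist > 0)[0]
    if occupied.size == 0:
        raise ParameterError("empty histogram")
    lo, hi = int(occupied[0]), int(occupied[-1])
    if lo == hi:
        return lo
    bins = np.arange(hist.size, dtype=np.float64)
    moving = lo
    while True:
        below = hist[lo : moving + 1]
        above = hist[moving + 1 : hi + 1]
        mean_below = float(np.dot(bins[lo : moving + 1], below) / below.sum())
        mean_above = float(np.dot(bins[moving + 1 : hi + 1], above) / above.sum())
        result = (mean_below + mean_above) / 2.0
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return int(round(result))


def threshold_default_dark(
    image: ImageStack | np.ndarray, nbins: int = 256
) -> np.ndarray:
    """Binary mask by the iterative-intermeans ("Default dark") threshold.

    The histogram uses integer bins 0-255 for 8-bit-range integer images
    and ``nbins`` uniform bins over [min, max] otherwise; foreground is
    strictly above the threshold bin (dark-background convention, with the
    macro's mask inversion absorbed so adhesions are foreground).  A
    constant image yields an empty mask (logged).
    """
    arr = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError("expected a 2D image")
    if arr.max() <= arr.min():
        logger.info("threshold_default_dark: constant image, empty mask")
        return np.zeros(arr.shape, dtype=bool)
    if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
        hist = np.bincount(arr.ravel().astype(np.int64), minlength=256)
        idx = intermeans_threshold(hist)
        return arr > idx
    lo, hi = float(arr.min()), float(arr.max())
    hist, edges = np.histogram(arr, bins=nbins, range=(lo, hi))
    idx = intermeans_threshold(hist)
    return arr > edges[idx + 1]


def count_particles(
    mask: np.ndarray,
    min_area: float = 5.0,
    max_area: float = 1000.0,
    min_circ: float = 0.0,
    max_circ: float = 1.0,
    intensity_image: np.ndarray | None = None,
) -> tuple[int, pd.DataFrame]:
    """Connected-component particle analysis with area/circularity filters.

    8-connectivity; circularity ``4 pi area / perimeter^2`` clipped to 1
    (discretization can push small objects above 1).  Bounds are inclusive.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = sk_label(mask, connectivity=2)
    rows = []
    next_id = 0
    for prop in regionprops(labels, intensity_image=intensity_image):
        area = float(prop.area)
        if not min_area <= area <= max_area:
            continue
        perim = float(prop.perimeter)
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * math.pi * area / perim**2)
        if not min_circ <= circ <= max_circ:
            continue
        rows.append(
            {
                "adhesion_id": next_id,
                "area_px2": area,
                "circularity": circ,
                "centroid_y": float(prop.centroid[0]),
                "centroid_x": float(prop.centroid[1]),
                "mean_intensity": float(prop.intensity_mean)
                if intensity_image is not None
                else np.nan,
            }
        )
        next_id += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "adhesion_id",
            "area_px2",
            "circularity",
            "centroid_y",
            "centroid_x",
            "mean_intensity",
        ],
    )
    return len(table), table


def _confirmed_against_original(
    mask: np.ndarray, raw: np.ndarray, min_contrast: float
) -> np.ndarray:
    """Drop mask components not brighter than their local surroundings.

    Automated surrogate for the workflow's visual-confirmation step: a real
    punctum is brighter than the membrane/cytoplasm around it in the
    *original* image, whereas foreground manufactured by the
    contrast-normalizing stages (noise blobs, CLAHE block artifacts) is
    not.  A component is kept when its mean original intensity exceeds
    ``min_contrast`` times the mean of a surrounding annulus.
    """
    labels = sk_label(mask, connectivity=2)
    keep = np.zeros(mask.shape, dtype=bool)
    all_fg = ndimage.binary_dilation(mask, iterations=1)
    for prop in regionprops(labels):
        sl = tuple(
            slice(max(0, s.start - 6), s.stop + 6) for s in prop.slice
        )
        comp = labels[sl] == prop.label
        ring = ndimage.binary_dilation(comp, iterations=5) & ~all_fg[sl]
        if not ring.any():
            continue
        inside = raw[sl][comp].mean()
        around = raw[sl][ring].mean()
        if around <= 0 or inside >= min_contrast * around:
            keep[sl] |= comp
    return keep


def count_adhesions(
    image: ImageStack | np.ndarray,
    rolling_radius_px: int = 50,
    clahe_blocksize: int = 19,
    clahe_bins: int = 256,
    clahe_max_slope: float = 6.0,
    exp_curvature: float = EXP_CURVATURE_DEFAULT,
    saturated_percent: float = 0.35,
    log_sigma: float = 2.0,
    min_area: float = 5.0,
    max_area: float = 1000.0,
    min_circ: float = 0.0,
    max_circ: float = 1.0,
    roi_mask: np.ndarray | None = None,
    min_confirm_contrast: float = 1.5,
) -> tuple[int, pd.DataFrame]:
    """Full adhesion-counting chain on a single-cell paxillin field.

    The field is first normalized to a 0-255 float working range (making
    the count invariant under global gain), then passed through the printed
    operator chain; per-object records carry the original image's mean
    intensity inside each counted object.

    ``roi_mask`` optionally restricts the thresholded mask to the cell
    interior (the role hand-outlining plays in the source workflow).
    ``min_confirm_contrast`` controls the visual-confirmation surrogate
    (see :func:`_confirmed_against_original`); set it to 0 to disable.
    """
    raw = _pixels2d(image)
    peak = raw.max()
    if peak <= 0:
        return 0, count_particles(np.zeros(raw.shape, bool))[1]
    work = raw / peak * 255.0
    work = rolling_ball_background(work, radius_px=rolling_radius_px)
    work = clahe(
        work,
        blocksize=clahe_blocksize,
        histogram_bins=clahe_bins,
        max_slope=clahe_max_slope,
    )
    work = exp_transform(work, curvature=exp_curvature, display_max=255.0)
    work = enhance_contrast(work, saturated_percent=saturated_percent, out_max=255.0)
    work = log_filter(work, sigma=log_sigma, out_max=255.0)
    mask = threshold_default_dark(work)
    if roi_mask is not None:
        if roi_mask.shape != mask.shape:
            raise ParameterError("roi_mask shape differs from image")
        mask = mask & np.asarray(roi_mask, dtype=bool)
    if min_confirm_contrast > 0 and mask.any():
        mask = _confirmed_against_original(mask, raw, min_confirm_contrast)
    count, table = count_particles(
        mask,
        min_area=min_area,
        max_area=max_area,
        min_circ=min_circ,
        max_circ=max_circ,
        intensity_image=raw,
    )
    return count, with_provenance(
        table,
        stage="count_adhesions",
        params={
            "rolling_radius_px": rolling_radius_px,
            "clahe_blocksize": clahe_blocksize,
            "clahe_max_slope": clahe_max_slope,
            "log_sigma": log_sigma,
            "min_area": min_area,
            "max_area": max_area,
        },
    )


def total_adhesion_area(
    image: ImageStack | np.ndarray,
    lower: float = 5500.0,
    upper: float = 65535.0,
    pixel_size_um: float | None = None,
) -> float:
    """Total area of pixels inside the fixed 16-bit threshold window.

    Returns pixels^2, or um^2 when a pixel size is supplied (either as the
    argument or on the :class:`ImageStack`).
    """
    if lower > upper:
        raise ParameterError("lower threshold exceeds upper threshold")
    arr = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if pixel_size_um is None and isinstance(image, ImageStack):
        pixel_size_um = image.pixel_size_um
    n = int(np.count_nonzero((arr >= lower) & (arr <= upper)))
    if pixel_size_um is None or pixel_size_um == 1.0:
        return float(n)
    return n * pixel_size_um**2


def adhesion_partition_coefficient(
    image: ImageStack | np.ndarray,
    background: float = 0.0,
    halo_px: int = 2,
) -> float:
    """Adhesion / cytoplasm partition coefficient for one cell.

    The manual two-step thresholding (Otsu for adhesions, an adjusted
    threshold for the cytoplasm) is automated with a three-class Otsu:
    background | cytoplasm | adhesions.  A ``halo_px``-wide band around
    each adhesion — blur-contaminated pixels a human would exclude when
    adjusting the threshold by eye — is dropped from the cytoplasm class.
    PC = (mean_adhesion - background) / (mean_cytoplasm - background),
    with ``background`` measured off-cell by the caller.
    """
    arr = _pixels2d(image)
    if arr.max() <= arr.min():
        raise SegmentationError("constant image: nothing to segment")
    t_cell, t_adh = threshold_multiotsu(arr, classes=3)
    adhesion = arr > t_adh
    excluded = (
        ndimage.binary_dilation(adhesion, iterations=halo_px)
        if halo_px > 0
        else adhesion
    )
    cytoplasm = (arr > t_cell) & ~excluded
    if not cytoplasm.any():
        raise SegmentationError("cytoplasm mask empty")
    if not adhesion.any():
        raise SegmentationError("adhesion mask empty")
    mean_adh = float(arr[adhesion].mean())
    mean_cyto = float(arr[cytoplasm].mean())
    denom = mean_cyto - background
    if denom <= 0:
        raise SegmentationError("cytoplasm at or below background")
    return (mean_adh - background) / denom


def gate_cells_by_gfp(
    cells: pd.DataFrame, low: float = 1000.0, high: float = 5000.0
) -> tuple[pd.DataFrame, float]:
    """Retain cells whose background-subtracted GFP mean is in [low, high].

    Bounds are inclusive.  Returns the filtered table and the retention
    fraction.
    """
    if "gfp_mean" not in cells.columns:
        raise ParameterError("cells table lacks a 'gfp_mean' column")
    gated = cells["gfp_mean"].between(low, high, inclusive="both")
    out = cells.loc[gated].copy()
    out["gated_in"] = True
    retention = float(gated.mean()) if len(cells) else 0.0
    return out, retention
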