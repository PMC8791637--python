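"""Droplet segmentation, illumination correction, partition coefficients,
TIRF cluster densities, and in-cluster enrichment.

The partition coefficient (PC) of a droplet is the mean fluorescence
intensity inside the segmented droplet divided by the mean intensity of the
surrounding bulk solution; PC = 1 means no enrichment.  Segmentation uses a
global Otsu threshold on a designated reference channel, the bulk is the
region outside the dilated union of all droplets, and droplets with a
measured diameter below 12 px are discarded because their intensity cannot
be measured or corrected reliably.  Measured means of the remaining
droplets may be corrected for PSF blur with a per-channel
:class:`~phaseq.psf.CorrectionCurve`.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk

from .core_io import ImageStack, with_provenance
from .errors import (
    BulkRegionError,
    CalibrationError,
    ConfigurationError,
    DimensionError,
    ParameterError,
)
from .psf import CorrectionCurve

logger = logging.getLogger("phaseq")

__all__ = [
    "flatfield_from_dye",
    "correct_illumination",
    "segment_droplets",
    "droplet_regions",
    "bulk_mean",
    "partition_coefficients",
    "summarize_partition",
    "cluster_density",
    "enrichment_in_clusters",
]

#: Droplets below this measured equivalent diameter are discarded.
MIN_DIAMETER_PX = 12.0


def _pixels(image: ImageStack | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError("expected a single 2D field")
    return arr.astype(np.float64)


def flatfield_from_dye(
    dye_image: ImageStack | np.ndarray,
    dark_image: ImageStack | np.ndarray,
    floor: float = 1e-3,
) -> np.ndarray:
    """Pixel-by-pixel illumination correction factors in (0, 1].

    ``field = (dye - dark) / max(dye - dark)``.  Noise can push isolated
    pixels to or below zero; those are clipped up to ``floor`` so later
    division is safe (and logged).
    """
    dye = _pixels(dye_image)
    dark = _pixels(dark_image)
    if dye.shape != dark.shape:
        raise DimensionError("dye and dark frames differ in shape")
    diff = dye - dark
    peak = diff.max()
    if peak <= 0:
        raise CalibrationError("dye frame not above dark frame: no signal")
    field = diff / peak
    n_low = int((field < floor).sum())
    if n_low:
        logger.warning("flat field: %d pixels clipped up to %.3g", n_low, floor)
        field = np.clip(field, floor, 1.0)
    return field


def correct_illumination(
    image: ImageStack, field: np.ndarray
) -> ImageStack:
    """Divide a (background-subtracted) image by the correction field.

    Not idempotent: the field must be applied exactly once per image.
    """
    field = np.asarray(field, dtype=np.float64)
    if image.pixels.shape[-2:] != field.shape:
        raise DimensionError("correction field shape does not match image")
    if np.any(field <= 0):
        raise ParameterError("correction field must be strictly positive")
    from dataclasses import replace

    return replace(image, pixels=image.pixels.astype(np.float64) / field)


def segment_droplets(reference_channel: ImageStack | np.ndarray) -> np.ndarray:
    """Label droplets in the reference channel by global Otsu thresholding.

    Returns an integer label image.  Labels are assigned in (y, x) centroid
    order so they are stable across runs.  A blank (zero-variance) image
    yields an empty mask (logged, not an error).
    """
    pixels = _pixels(reference_channel)
    if pixels.max() <= pixels.min():
        logger.info("segment_droplets: blank image, empty mask")
        return np.zeros(pixels.shape, dtype=np.int32)
    mask = pixels > threshold_otsu(pixels)
    labels = sk_label(mask, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    # relabel by centroid (y, x) for a documented, stable ordering
    props = regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, prop in enumerate(order, start=1):
        out[labels == prop.label] = new_id
    return out


def droplet_regions(labels: np.ndarray) -> pd.DataFrame:
    """Per-component geometry: area, equivalent diameter, centroid."""
    rows = []
    for prop in regionprops(labels):
        rows.append(
            {
                "droplet_id": int(prop.label),
                "area_px2": float(prop.area),
                "diameter_px": 2.0 * math.sqrt(prop.area / math.pi),
                "centroid_y": float(prop.centroid[0]),
                "centroid_x": float(prop.centroid[1]),
            }
        )
    return pd.DataFrame(
        rows, columns=["droplet_id", "area_px2", "diameter_px", "centroid_y", "centroid_x"]
    )


def bulk_mean(
    labels: np.ndarray,
    image: ImageStack | np.ndarray,
    dilation_radius_px: int = 5,
) -> float:
    """Mean intensity outside the dilated union of all droplets.

    Dilation clears the blur halo around each droplet so the bulk estimate
    is not contaminated by out-of-focus droplet light.
    """
    pixels = _pixels(image)
    if labels.shape != pixels.shape:
        raise DimensionError("labels and image shapes differ")
    union = labels > 0
    if union.any() and dilation_radius_px > 0:
        union = ndimage.binary_dilation(union, structure=disk(dilation_radius_px))
    outside = ~union
    if not outside.any():
        raise BulkRegionError("dilated droplet mask covers the entire field")
    return float(pixels[outside].mean())


def _trend_says_correct(
    diameters: np.ndarray, means: np.ndarray, alpha: float
) -> bool:
    """Spearman pre-test: does measured mean increase with diameter?"""
    if len(diameters) < 5:
        return False
    rho, p = stats.spearmanr(diameters, means)
    return bool(rho > 0 and p < alpha)


def partition_coefficients(
    labels: np.ndarray,
    channels: Mapping[str, ImageStack | np.ndarray],
    bulk: Mapping[str, float],
    curves: Mapping[str, CorrectionCurve] | None = None,
    min_diameter_px: float = MIN_DIAMETER_PX,
    apply_correction: bool = True,
    trend_pretest: bool = True,
    trend_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-droplet, per-channel partition coefficients.

    For each labelled droplet and channel the raw mean inside the mask is
    measured; when PSF correction is enabled *and* the channel's measured
    mean increases with diameter (positive Spearman trend at
    ``trend_alpha`` — the signature of blur dilution), the per-channel
    correction curve rescales the mean before dividing by the bulk.  The
    pre-test matters: a channel with no enrichment (PC = 1) shows no blur
    bias, and multiplying its mean by the zero-background calibration
    factor would *over*-correct it.  Set ``trend_pretest=False`` to always
    correct.  Droplets with measured diameter below ``min_diameter_px`` are
    kept in the table with ``discarded = True`` but must be excluded from
    any summary.
    """
    for ch, b in bulk.items():
        if not b > 0:
            raise ParameterError(f"bulk mean for channel {ch!r} must be > 0")
    geometry = droplet_regions(labels)
    records = geometry.copy()
    records["discarded"] = records["diameter_px"] < min_diameter_px
    records["discard_reason"] = np.where(
        records["discarded"], f"diameter < {min_diameter_px:g} px", ""
    )

    channel_names = list(channels)
    raw_means: dict[str, np.ndarray] = {}
    for ch in channel_names:
        pixels = _pixels(channels[ch])
        if pixels.shape != labels.shape:
            raise DimensionError(f"channel {ch!r} shape differs from mask")
        sums = np.bincount(
            labels.ravel(), weights=pixels.ravel(), minlength=labels.max() + 1
        )
        counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
        ids = records["droplet_id"].to_numpy()
        raw_means[ch] = sums[ids] / counts[ids]
        records[f"raw_mean_{ch}"] = raw_means[ch]

    for ch in channel_names:
        correct_this = apply_correction
        if correct_this and trend_pretest:
            keep = ~records["discarded"].to_numpy()
            correct_this = _trend_says_correct(
                records.loc[keep, "diameter_px"].to_numpy(),
                records.loc[keep, f"raw_mean_{ch}"].to_numpy(),
                trend_alpha,
            )
        if correct_this:
            if curves is None or ch not in curves:
                raise ConfigurationError(
                    f"PSF correction requested but no curve for channel {ch!r}"
                )
            from .psf import apply_intensity_correction

            records = apply_intensity_correction(records, curves[ch], ch)
        else:
            records[f"corrected_mean_{ch}"] = records[f"raw_mean_{ch}"]
        records[f"pc_{ch}"] = records[f"corrected_mean_{ch}"] / bulk[ch]
        records[f"pc_raw_{ch}"] = records[f"raw_mean_{ch}"] / bulk[ch]

    return with_provenance(
        records,
        stage="partition_coefficients",
        params={
            "min_diameter_px": min_diameter_px,
            "apply_correction": apply_correction,
            "trend_pretest": trend_pretest,
            "bulk": dict(bulk),
        },
    )


def summarize_partition(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM, and n of the PC per channel over non-discarded droplets."""
    kept = records.loc[~records["discarded"]]
    rows = []
    for col in records.columns:
        if col.startswith("pc_") and not col.startswith("pc_raw_"):
            ch = col[len("pc_") :]
            vals = kept[col].to_numpy(dtype=np.float64)
            n = len(vals)
            rows.append(
                {
                    "channel": ch,
                    "pc_mean": float(vals.mean()) if n else np.nan,
                    "pc_sem": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def cluster_density(
    field_images: Sequence[ImageStack],
    surface: str,
    timepoints_min: Sequence[float] | None = None,
    min_diameter_px: float = MIN_DIAMETER_PX,
) -> pd.DataFrame:
    """Clusters per mm^2 in TIRF fields of a supported bilayer.

    Each field is segmented exactly like a droplet field (Otsu + connected
    components, same minimum-diameter floor unless overridden) and the
    count is converted to a density via the physical field area
    ``(ny * pixel_size_um) * (nx * pixel_size_um)`` in mm^2.
    """
    rows = []
    timepoints = (
        list(timepoints_min)
        if timepoints_min is not None
        else [np.nan] * len(field_images)
    )
    if len(timepoints) != len(field_images):
        raise ParameterError("timepoints length must match field count")
    for img, tp in zip(field_images, timepoints):
        if img.ndim != 2:
            raise ParameterError("cluster fields must be 2D")
        ny, nx = img.shape
        area_mm2 = (ny * img.pixel_size_um) * (nx * img.pixel_size_um) / 1e6
        if area_mm2 <= 0:
            raise ParameterError("field area must be > 0")
        labels = segment_droplets(img)
        geometry = droplet_regions(labels)
        count = int((geometry["diameter_px"] >= min_diameter_px).sum())
        rows.append(
            {
                "surface": surface,
                "timepoint_min": tp,
                "field_area_mm2": area_mm2,
                "cluster_count": count,
                "density_per_mm2": count / area_mm2,
            }
        )
    return with_provenance(
        pd.DataFrame(rows),
        stage="cluster_density",
        params={"surface": surface, "min_diameter_px": min_diameter_px},
    )


def enrichment_in_clusters(
    image: ImageStack | np.ndarray,
    cluster_mask: np.ndarray,
    dilation_radius_px: int = 5,
) -> pd.DataFrame:
    """Per-cluster fold enrichment over the unclustered membrane.

    ``fold_enrichment = mean inside cluster / mean outside the dilated
    union of all clusters``.
    """
    pixels = _pixels(image)
    if cluster_mask.shape != pixels.shape:
        raise DimensionError("cluster mask shape differs from image")
    unclustered_mean = bulk_mean(cluster_mask, pixels, dilation_radius_px)
    rows = []
    for prop in regionprops(cluster_mask, intensity_image=pixels):
        in_mean = float(prop.intensity_mean)
        rows.append(
            {
                "cluster_id": int(prop.label),
                "in_cluster_mean": in_mean,
                "unclustered_mean": unclustered_mean,
                "fold_enrichment": in_mean / unclustered_mean,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "in_cluster_mean", "unclustered_mean", "fold_enrichment"],
    )
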