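"""Synthetic microscopy images and traces with attached ground truth.

Every generator here emulates one class of input the quantification
pipeline consumes:

* sub-resolution bead fields (PSF calibration),
* diffraction-blurred droplet fields of known interior/bulk ratio
  (partition coefficients),
* fluorescence-recovery time series with known fractions and rates
  (FRAP fitting),
* cells with punctate adhesions on a cytoplasmic plateau
  (adhesion counting / area / partitioning),
* dye + dark flat-field pairs (illumination correction).

All generators are deterministic given ``(parameters, seed)`` and return a
:class:`GroundTruth` record sufficient to compute, without the image, the
value each downstream stage should report.  Blur is a truncated (+/- 4 sigma)
unit-sum Gaussian; discs are anti-aliased by fractional pixel coverage at
the rim so that "diameter" stays well defined at small sizes.  Poisson shot
noise, when requested, is applied to the pre-offset signal and Gaussian read
noise after, mimicking camera physics while keeping the ground truth
analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ImageStack
from .errors import DimensionError, ParameterError, PlacementError

__all__ = [
    "GroundTruth",
    "DropletSpec",
    "FWHM_TO_SIGMA",
    "gaussian_kernel_1d",
    "gaussian_kernel_2d",
    "blur_gaussian",
    "render_disc",
    "make_bead_field",
    "make_droplet_image",
    "make_frap_series",
    "make_adhesion_image",
    "make_flatfield_pair",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian profile.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class GroundTruth:
    """The generator's own record of what it drew.

    ``kind`` is one of ``beads, droplets, frap, adhesions, clusters,
    flatfield``; ``parameters`` holds everything needed to predict every
    downstream measurement (centres, levels, rates, densities, ...).
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# kernels and rasterization shared with the calibration stage
# ---------------------------------------------------------------------------

def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Unit-sum 1D Gaussian sampled on +/- ``truncate * sigma`` (>= 1 px)."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    radius = max(1, int(math.ceil(truncate * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_kernel_2d(fwhm_px: float, truncate: float = 4.0) -> np.ndarray:
    """Unit-sum isotropic 2D Gaussian of the given FWHM (outer product of
    the 1D kernel, so separable convolution is exact)."""
    sigma = fwhm_px / FWHM_TO_SIGMA
    k1 = gaussian_kernel_1d(sigma, truncate)
    return np.outer(k1, k1)


def blur_gaussian(image: np.ndarray, fwhm_px: float) -> np.ndarray:
    """Convolve with the truncated unit-sum Gaussian (reflect boundary).

    ``fwhm_px == 0`` is the identity (delta kernel).  Implemented as two
    separable 1D passes, numerically identical to convolving with the
    outer-product 2D kernel.
    """
    if fwhm_px < 0:
        raise ParameterError("fwhm_px must be >= 0")
    if fwhm_px == 0:
        return image.astype(np.float64, copy=True)
    k1 = gaussian_kernel_1d(fwhm_px / FWHM_TO_SIGMA)
    out = ndimage.convolve1d(image.astype(np.float64), k1, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k1, axis=1, mode="reflect")


def render_disc(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_px: float,
    supersample: int = 8,
) -> np.ndarray:
    """Fractional pixel coverage of a disc (anti-aliased rim).

    Pixels fully inside get 1, fully outside 0; rim pixels get the fraction
    of their area covered, estimated on a ``supersample x supersample``
    sub-grid.  Pixel (i, j) spans [i - 0.5, i + 0.5] x [j - 0.5, j + 0.5].
    """
    if diameter_px < 1:
        raise ParameterError("disc diameter must be >= 1 px")
    cy, cx = center
    r = diameter_px / 2.0
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dist = np.hypot(yy - cy, xx - cx)
    cov = (dist <= r - 0.75).astype(np.float64)
    rim = (dist > r - 0.75) & (dist < r + 0.75)
    if rim.any():
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        oy, ox = np.meshgrid(offs, offs, indexing="ij")
        ry, rx = np.nonzero(rim)
        sub_y = ry[:, None] + oy.ravel()[None, :]
        sub_x = rx[:, None] + ox.ravel()[None, :]
        inside = np.hypot(sub_y - cy, sub_x - cx) <= r
        cov[ry, rx] = inside.mean(axis=1)
    return cov


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_separation: float,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Rejection-sample n (y, x) points with a minimum pairwise distance."""
    pts: list[tuple[float, float]] = []
    lo_y, hi_y = margin, shape[0] - margin
    lo_x, hi_x = margin, shape[1] - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise PlacementError("margin exceeds field size")
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} objects with separation "
                f"{min_separation:.1f} px in field {shape}"
            )
        tries += 1
        cand = (rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x))
        if all(
            math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation
            for p in pts
        ):
            pts.append(cand)
    return np.array(pts)


# ---------------------------------------------------------------------------
# bead fields for PSF calibration
# ---------------------------------------------------------------------------

def make_bead_field(
    n_beads: int,
    sigma_true: float,
    z_planes: int = 11,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    sigma_z: float | None = None,
    focus_plane: int | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """A z-stack of sub-resolution point emitters rendered as 3D Gaussians.

    Emulates 0.1 um multi-spectral beads imaged through the objective:
    lateral sigma ``sigma_true``, axial sigma ``sigma_z`` (default
    ``2 * sigma_true``), brightest at ``focus_plane`` (default: central
    plane).  Beads are placed without overlap; additive Gaussian read noise
    on a constant baseline.
    """
    if n_beads < 1:
        raise ParameterError("n_beads must be >= 1")
    if sigma_true <= 0:
        raise ParameterError("sigma_true must be > 0")
    if z_planes < 3:
        raise ParameterError("z_planes must be >= 3")
    rng = np.random.default_rng(seed)
    sigma_z = 2.0 * sigma_true if sigma_z is None else sigma_z
    focus = z_planes // 2 if focus_plane is None else focus_plane
    if not 0 <= focus < z_planes:
        raise ParameterError("focus_plane outside stack")
    # separation: linescan windows (±10 px) must never mix two beads
    margin = 6.0 * sigma_true + 12.0
    centres = _place_points(rng, n_beads, shape, margin, 2 * margin)

    stack = np.full((z_planes, *shape), baseline, dtype=np.float64)
    win = int(math.ceil(5 * sigma_true))
    for cy, cx in centres:
        iy, ix = int(round(cy)), int(round(cx))
        ys = slice(max(0, iy - win), min(shape[0], iy + win + 1))
        xs = slice(max(0, ix - win), min(shape[1], ix + win + 1))
        yy, xx = np.mgrid[ys, xs].astype(np.float64)
        lateral = np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_true**2)
        )
        for z in range(z_planes):
            az = math.exp(-((z - focus) ** 2) / (2 * sigma_z**2))
            stack[z, ys, xs] += amplitude * az * lateral
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
        stack = np.clip(stack, 0.0, None)

    truth = GroundTruth(
        kind="beads",
        parameters={
            "centres_yx": centres.tolist(),
            "sigma_true": sigma_true,
            "fwhm_true": FWHM_TO_SIGMA * sigma_true,
            "sigma_z": sigma_z,
            "focus_plane": focus,
            "amplitude": amplitude,
            "baseline": baseline,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return ImageStack(stack, channel_name="beads"), truth


# ---------------------------------------------------------------------------
# droplet / cluster fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropletSpec:
    """One synthetic droplet: centre, diameter, per-channel interior level."""

    center_yx: tuple[float, float]
    diameter_px: float
    interior: Mapping[str, float]


def make_droplet_image(
    droplets: Sequence[DropletSpec],
    bulk_level: Mapping[str, float],
    psf_fwhm: float = 0.0,
    illumination_field: np.ndarray | str = "uniform",
    background_offset: float = 0.0,
    noise_sd: float = 0.0,
    poisson: bool = False,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.25,
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Multi-channel field of bright discs ("droplets") on a uniform bulk.

    Per channel: ideal image = ``bulk_level`` everywhere with discs set to
    their interior level, convolved with a unit-sum Gaussian of FWHM
    ``psf_fwhm``, multiplied by the illumination field, plus
    ``background_offset`` and noise.  The ground truth stores each droplet's
    true partition ratio interior / bulk per channel.
    """
    channels = list(bulk_level)
    for spec in droplets:
        if spec.diameter_px < 1:
            raise ParameterError("droplet diameters must be >= 1 px")
        for ch in channels:
            if not spec.interior.get(ch, 0.0) >= bulk_level[ch] >= 0:
                raise ParameterError(
                    f"need interior >= bulk >= 0 for channel {ch!r}"
                )
    # overlap check including one-FWHM blur margin
    for i in range(len(droplets)):
        for j in range(i + 1, len(droplets)):
            a, b = droplets[i], droplets[j]
            dist = math.hypot(
                a.center_yx[0] - b.center_yx[0], a.center_yx[1] - b.center_yx[1]
            )
            if dist < (a.diameter_px + b.diameter_px) / 2 + 2 * psf_fwhm:
                raise PlacementError(
                    f"droplets {i} and {j} overlap (separation {dist:.1f} px)"
                )

    if isinstance(illumination_field, str):
        if illumination_field != "uniform":
            raise ParameterError("illumination_field must be an array or 'uniform'")
        illum = np.ones(shape)
    else:
        illum = np.asarray(illumination_field, dtype=np.float64)
        if illum.shape != shape:
            raise DimensionError(
                f"illumination field shape {illum.shape} != image shape {shape}"
            )
        if illum.min() <= 0 or illum.max() > 1:
            raise ParameterError("illumination field values must lie in (0, 1]")

    coverages = [
        render_disc(shape, spec.center_yx, spec.diameter_px) for spec in droplets
    ]
    rng = np.random.default_rng(seed)
    out: dict[str, ImageStack] = {}
    ideal_images: dict[str, np.ndarray] = {}
    for ch in channels:
        ideal = np.full(shape, float(bulk_level[ch]))
        for spec, cov in zip(droplets, coverages):
            ideal += cov * (spec.interior[ch] - bulk_level[ch])
        ideal_images[ch] = ideal
        signal = blur_gaussian(ideal, psf_fwhm) * illum
        if poisson:
            signal = rng.poisson(np.clip(signal, 0, None)).astype(np.float64)
        signal = signal + background_offset
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=shape)
        out[ch] = ImageStack(
            np.clip(signal, 0.0, None),
            channel_name=ch,
            pixel_size_um=pixel_size_um,
        )

    truth = GroundTruth(
        kind="droplets",
        parameters={
            "droplets": [
                {
                    "center_yx": spec.center_yx,
                    "diameter_px": spec.diameter_px,
                    "interior": dict(spec.interior),
                    "true_pc": {
                        ch: (spec.interior[ch] / bulk_level[ch])
                        if bulk_level[ch] > 0
                        else math.inf
                        for ch in channels
                    },
                }
                for spec in droplets
            ],
            "bulk_level": dict(bulk_level),
            "psf_fwhm": psf_fwhm,
            "background_offset": background_offset,
            "illumination_field": illum,
            "ideal_images": ideal_images,
            "noise_sd": noise_sd,
            "poisson": poisson,
            "pixel_size_um": pixel_size_um,
        },
        seed=seed,
    )
    return out, truth


# ---------------------------------------------------------------------------
# FRAP time series
# ---------------------------------------------------------------------------

def make_frap_series(
    mobile_fractions: Sequence[float],
    rate_constants: Sequence[float],
    bleach_depth: float = 0.1,
    acquisition_bleach_rate: float = 0.0,
    n_prebleach: int = 3,
    interval_s: float = 1.0,
    duration_s: float = 90.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    roi_prebleach: float = 1000.0,
    reference_level: float = 1000.0,
    background_level: float = 100.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential fluorescence-recovery trace with acquisition bleaching.

    ``mobile_fractions`` (one or two components) are fractions of the
    prebleach signal recovering with the paired ``rate_constants`` (1/s,
    fast first); the remainder is immobile.  ``bleach_depth`` is the
    fraction of the prebleach ROI intensity remaining immediately after the
    bleach pulse.  The entire field decays as
    ``exp(-acquisition_bleach_rate * t)`` from the first acquired frame, so
    the reference (bulk) region decays only by acquisition bleaching.

    Returns a tidy table (t, roi_intensity, reference_intensity,
    background_intensity) with ``t = 0`` at the first post-bleach frame and
    prebleach frames at negative times.
    """
    fracs = tuple(float(f) for f in mobile_fractions)
    rates = tuple(float(k) for k in rate_constants)
    if len(fracs) != len(rates) or len(fracs) not in (1, 2):
        raise ParameterError("need 1 or 2 (fraction, rate) component pairs")
    if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ParameterError("fractions must lie in [0, 1] and sum to <= 1")
    if any(k <= 0 for k in rates):
        raise ParameterError("rate constants must be > 0")
    if len(rates) == 2 and not rates[0] > rates[1]:
        raise ParameterError("biexponential requires k1 > k2 (fast first)")
    if not 0 <= bleach_depth < 1:
        raise ParameterError("bleach_depth must lie in [0, 1)")
    if n_prebleach < 3:
        raise ParameterError("n_prebleach must be >= 3")

    rng = np.random.default_rng(seed)
    t_pre = -interval_s * np.arange(n_prebleach, 0, -1)
    t_post = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    t = np.concatenate([t_pre, t_post])
    t_global = t - t[0]  # bleach clock starts at the first acquired frame

    i_post = bleach_depth * roi_prebleach
    recovery = np.zeros_like(t_post)
    for f, k in zip(fracs, rates):
        recovery += f * (1.0 - np.exp(-k * t_post))
    roi_signal = np.concatenate(
        [
            np.full(n_prebleach, roi_prebleach),
            i_post + (roi_prebleach - i_post) * recovery,
        ]
    )
    decay = np.exp(-acquisition_bleach_rate * t_global)
    roi = background_level + roi_signal * decay
    reference = background_level + reference_level * decay
    background = np.full_like(t, background_level)
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd, size=t.shape)
        reference = reference + rng.normal(0.0, noise_sd, size=t.shape)
        background = background + rng.normal(0.0, noise_sd, size=t.shape)

    table = pd.DataFrame(
        {
            "t": t,
            "roi_intensity": roi,
            "reference_intensity": reference,
            "background_intensity": background,
        }
    )
    truth = GroundTruth(
        kind="frap",
        parameters={
            "mobile_fractions": fracs,
            "rate_constants": rates,
            "t_half": tuple(math.log(2) / k for k in rates),
            "immobile_fraction": 1.0 - sum(fracs),
            "bleach_depth": bleach_depth,
            "acquisition_bleach_rate": acquisition_bleach_rate,
            "n_prebleach": n_prebleach,
            "interval_s": interval_s,
            "duration_s": duration_s,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# cells with punctate adhesions
# ---------------------------------------------------------------------------

def default_cell_mask(shape: tuple[int, int] = (360, 360)) -> np.ndarray:
    """Elliptical cell footprint filling most of the field."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    ry, rx = shape[0] * 0.42, shape[1] * 0.42
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_adhesion_image(
    n_adhesions: int,
    cell_mask: np.ndarray | None = None,
    area_range_px2: tuple[float, float] = (8.0, 60.0),
    adhesion_level: float = 9000.0,
    cytoplasm_level: float = 3000.0,
    background_level: float = 300.0,
    noise_sd: float = 0.0,
    blur_sigma: float = 1.0,
    seed: int = 0,
    pixel_size_um: float = 0.1,
) -> tuple[ImageStack, GroundTruth]:
    """A single-cell field with elliptical adhesion puncta.

    Intensity levels: ``background_level`` outside the cell,
    ``cytoplasm_level`` inside, ``adhesion_level`` within puncta; a mild
    Gaussian blur mimics the optics and Gaussian read noise is added last.
    Puncta areas are sampled uniformly in ``area_range_px2`` with aspect
    ratios in [1, 2]; puncta are placed disjointly, away from the cell edge.
    """
    if not adhesion_level > cytoplasm_level > background_level:
        raise ParameterError(
            "need adhesion_level > cytoplasm_level > background_level"
        )
    if n_adhesions < 0:
        raise ParameterError("n_adhesions must be >= 0")
    mask = default_cell_mask() if cell_mask is None else np.asarray(cell_mask, bool)
    shape = mask.shape
    rng = np.random.default_rng(seed)

    img = np.full(shape, float(background_level))
    img[mask] = cytoplasm_level

    records: list[dict] = []
    if n_adhesions > 0:
        max_r = math.sqrt(area_range_px2[1] / math.pi) * 1.5  # widest semi-axis
        sep = 2 * max_r + 6 + 4 * blur_sigma
        # restrict placement to the eroded cell so puncta stay inside
        eroded = ndimage.binary_erosion(
            mask, iterations=int(math.ceil(max_r + 3 + 2 * blur_sigma))
        )
        if not eroded.any():
            raise PlacementError("cell mask too small for requested puncta")
        ys, xs = np.nonzero(eroded)
        centres: list[tuple[float, float]] = []
        # greedy packing is shuffle-order dependent; retry a few orders
        for _attempt in range(8):
            order = rng.permutation(len(ys))
            centres = []
            for idx in order:
                if len(centres) == n_adhesions:
                    break
                cand = (float(ys[idx]), float(xs[idx]))
                if all(
                    math.hypot(cand[0] - c[0], cand[1] - c[1]) >= sep
                    for c in centres
                ):
                    centres.append(cand)
            if len(centres) == n_adhesions:
                break
        if len(centres) < n_adhesions:
            raise PlacementError(
                f"placed only {len(centres)}/{n_adhesions} disjoint puncta"
            )
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        for aid, (cy, cx) in enumerate(centres):
            area = rng.uniform(*area_range_px2)
            aspect = rng.uniform(1.0, 2.0)
            # area = pi * ra * rb with ra = aspect * rb
            rb = math.sqrt(area / (math.pi * aspect))
            ra = aspect * rb
            theta = rng.uniform(0, math.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * math.cos(theta) + dx * math.sin(theta)
            v = -dy * math.sin(theta) + dx * math.cos(theta)
            punctum = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
            img[punctum] = adhesion_level
            records.append(
                {
                    "adhesion_id": aid,
                    "centroid_yx": (cy, cx),
                    "area_px2_requested": area,
                    "area_px2_drawn": int(punctum.sum()),
                    "aspect": aspect,
                }
            )
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma, mode="nearest")
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=shape), 0.0, None)

    truth = GroundTruth(
        kind="adhesions",
        parameters={
            "n_adhesions": len(records),
            "adhesions": records,
            "adhesion_level": adhesion_level,
            "cytoplasm_level": cytoplasm_level,
            "background_level": background_level,
            "true_ratio": (adhesion_level - background_level)
            / (cytoplasm_level - background_level),
            "cell_mask": mask,
            "noise_sd": noise_sd,
            "blur_sigma": blur_sigma,
        },
        seed=seed,
    )
    return ImageStack(img, channel_name="paxillin", pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# flat-field calibration pairs
# ---------------------------------------------------------------------------

def make_flatfield_pair(
    gradient: np.ndarray | str = "uniform",
    shape: tuple[int, int] = (128, 128),
    dye_level: float = 2000.0,
    dark_level: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Dye (uniform fluorophore solution) and dark calibration frames.

    ``dye = dye_level * gradient + dark_level + noise``;
    ``dark = dark_level + noise``.  The multiplicative gradient must lie in
    (0, 1] — it is what the flat-field stage should recover.
    """
    if isinstance(gradient, str):
        if gradient != "uniform":
            raise ParameterError("gradient must be an array or 'uniform'")
        grad = np.ones(shape)
    else:
        grad = np.asarray(gradient, dtype=np.float64)
        shape = grad.shape
        if grad.min() <= 0 or grad.max() > 1:
            raise ParameterError("gradient values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    dye = dye_level * grad + dark_level
    dark = np.full(shape, float(dark_level))
    if noise_sd > 0:
        dye = dye + rng.normal(0.0, noise_sd, size=shape)
        dark = dark + rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruth(
        kind="flatfield",
        parameters={
            "gradient": grad,
            "dye_level": dye_level,
            "dark_level": dark_level,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return (
        ImageStack(np.clip(dye, 0, None), channel_name="dye"),
        ImageStack(np.clip(dark, 0, None), channel_name="dark"),
        truth,
    )
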