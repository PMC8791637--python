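"""PSF estimation from bead fields and the small-object intensity
correction.

Objects near the diffraction limit appear dimmer than they are: the PSF
spreads interior intensity over the rim, so the mean intensity inside a
segmented droplet underestimates the true interior level, and the bias
grows as the droplet shrinks.  The correction follows the bead-calibration
recipe:

1. estimate the per-channel Gaussian PSF FWHM from linescans through
   sub-resolution beads (focal plane = brightest z-plane per bead);
2. render discs of known diameter (1-50 px) and intensity 255, convolve
   with the measured PSF, segment each convolved disc by Otsu's threshold,
   and record measured mean intensity and measured (mask) diameter;
3. fit ``f(d) = plateau + (f0 - plateau) * exp(-k * d)`` — a one-phase
   exponential association over measured diameter ``d`` — to the factors
   ``255 / measured_mean``;
4. multiply measured droplet means by ``f(measured diameter)``.

Droplets below the 12 px diameter floor are discarded upstream rather than
corrected: at that size the mask mean is no longer a reliable statistic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .core_io import ImageStack
from .errors import CalibrationError, ParameterError
from .synthetic import FWHM_TO_SIGMA, gaussian_kernel_2d, render_disc

logger = logging.getLogger("phaseq")

__all__ = [
    "PsfModel",
    "CorrectionCurve",
    "select_focus_plane",
    "measure_fwhm",
    "gaussian_psf",
    "measure_masked_disc",
    "build_correction_curve",
    "apply_intensity_correction",
]


@dataclass
class PsfModel:
    """Per-channel Gaussian PSF summary: mean FWHM over measured beads."""

    channel_name: str
    fwhm_px: float
    sigma_px: float
    n_beads_used: int
    per_bead_fwhm: list[float] = dc_field(default_factory=list)

    @classmethod
    def from_per_bead(
        cls, per_bead_fwhm: Sequence[float], channel_name: str = ""
    ) -> "PsfModel":
        per_bead = [float(f) for f in per_bead_fwhm]
        fwhm = float(np.mean(per_bead))
        return cls(
            channel_name=channel_name,
            fwhm_px=fwhm,
            sigma_px=fwhm / FWHM_TO_SIGMA,
            n_beads_used=len(per_bead),
            per_bead_fwhm=per_bead,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "channel_name": self.channel_name,
                    "fwhm_px": self.fwhm_px,
                    "sigma_px": self.sigma_px,
                    "n_beads_used": self.n_beads_used,
                    "per_bead_fwhm": self.per_bead_fwhm,
                },
                indent=2,
            )
        )
        return path


@dataclass
class CorrectionCurve:
    """Fitted small-object intensity correction
    ``f(d) = plateau + (f0 - plateau) * exp(-k * d)``.

    ``support`` is the measured-diameter range covered by the calibration
    points; factors are >= 1 on a well-formed calibration (blur only dilutes
    a bright disc on a dark background) and decay to ``plateau ~ 1`` at
    large diameters.
    """

    channel_name: str
    plateau: float
    f0: float
    k: float
    support: tuple[float, float]
    sample_points: pd.DataFrame | None = None

    def factor(self, measured_diameter_px) -> np.ndarray | float:
        d = np.asarray(measured_diameter_px, dtype=np.float64)
        out = self.plateau + (self.f0 - self.plateau) * np.exp(-self.k * d)
        return float(out) if out.ndim == 0 else out

    def in_support(self, measured_diameter_px) -> np.ndarray | bool:
        d = np.asarray(measured_diameter_px, dtype=np.float64)
        ok = d >= self.support[0]  # above-support diameters extrapolate to plateau
        return bool(ok) if ok.ndim == 0 else ok

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "channel_name": self.channel_name,
            "plateau": self.plateau,
            "f0": self.f0,
            "k": self.k,
            "support": list(self.support),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            channel_name=payload["channel_name"],
            plateau=payload["plateau"],
            f0=payload["f0"],
            k=payload["k"],
            support=tuple(payload["support"]),
        )


def select_focus_plane(
    bead_stack: ImageStack, bead_centre: tuple[float, float], window: int = 2
) -> int:
    """Index of the z-plane with the highest intensity around a bead.

    Intensity is summed in a ``(2*window+1)^2`` box around the centre; ties
    break toward the lower plane index.
    """
    if bead_stack.ndim != 3:
        raise ParameterError("bead stack must be 3D (z, y, x)")
    nz, ny, nx = bead_stack.shape
    cy, cx = int(round(bead_centre[0])), int(round(bead_centre[1]))
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ParameterError(f"bead centre {bead_centre} outside image")
    ys = slice(max(0, cy - window), min(ny, cy + window + 1))
    xs = slice(max(0, cx - window), min(nx, cx + window + 1))
    sums = bead_stack.pixels[:, ys, xs].sum(axis=(1, 2))
    return int(np.argmax(sums))  # argmax returns the first (lowest) maximum


def _gaussian_line(x, amplitude, centre, sigma, baseline):
    return baseline + amplitude * np.exp(-((x - centre) ** 2) / (2 * sigma**2))


def _fit_linescan(profile: np.ndarray) -> float:
    """FWHM from a Gaussian fit (amplitude, centre, sigma, baseline free)."""
    x = np.arange(profile.size, dtype=np.float64)
    baseline0 = float(np.percentile(profile, 10))
    amp0 = float(profile.max() - baseline0)
    if amp0 <= 0:
        raise RuntimeError("no peak in linescan")
    centre0 = float(np.argmax(profile))
    sigma0 = max(1.0, profile.size / 10.0)
    popt, _ = optimize.curve_fit(
        _gaussian_line,
        x,
        profile.astype(np.float64),
        p0=(amp0, centre0, sigma0, baseline0),
        bounds=([0, 0, 0.1, -np.inf], [np.inf, profile.size, profile.size, np.inf]),
        maxfev=10_000,
    )
    return FWHM_TO_SIGMA * float(popt[2])


def measure_fwhm(
    image: ImageStack | np.ndarray,
    bead_centres: Sequence[tuple[float, float]],
    halfwidth_px: int = 10,
    average_axes: bool = False,
    channel_name: str = "",
) -> PsfModel:
    """Per-channel PSF FWHM from linescans through bead centres.

    For each bead a horizontal linescan through the detected centre is fit
    with a Gaussian; ``average_axes=True`` additionally fits the vertical
    scan and averages the two.  Beads whose fit fails are dropped with a
    warning; if every bead fails a :class:`CalibrationError` is raised.
    """
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if pixels.ndim != 2:
        raise ParameterError("measure_fwhm expects a 2D focal-plane image")
    if len(bead_centres) == 0:
        raise ParameterError("need at least one bead centre")
    ny, nx = pixels.shape
    per_bead: list[float] = []
    for cy, cx in bead_centres:
        iy, ix = int(round(cy)), int(round(cx))
        try:
            row = pixels[iy, max(0, ix - halfwidth_px) : min(nx, ix + halfwidth_px + 1)]
            fwhm = _fit_linescan(row)
            if average_axes:
                col = pixels[
                    max(0, iy - halfwidth_px) : min(ny, iy + halfwidth_px + 1), ix
                ]
                fwhm = 0.5 * (fwhm + _fit_linescan(col))
            per_bead.append(fwhm)
        except (RuntimeError, ValueError) as exc:
            logger.warning("bead at (%.1f, %.1f) dropped: %s", cy, cx, exc)
    if not per_bead:
        raise CalibrationError("every bead linescan fit failed")
    return PsfModel.from_per_bead(per_bead, channel_name=channel_name)


def gaussian_psf(fwhm_px: float, support: int | None = None) -> np.ndarray:
    """Centred, unit-sum, isotropic 2D Gaussian kernel.

    ``support`` (full width, odd) must hold at least +/- 4 sigma; by default
    it is exactly the +/- 4 sigma truncation used everywhere else in the
    package.
    """
    if fwhm_px <= 0:
        raise ParameterError("fwhm_px must be > 0")
    kernel = gaussian_kernel_2d(fwhm_px)
    if support is not None:
        needed = kernel.shape[0]
        if support < needed:
            raise ParameterError(
                f"support {support} too small: need >= {needed} px for +/-4 sigma"
            )
        pad = (support - needed) // 2
        kernel = np.pad(kernel, pad)
        kernel = kernel / kernel.sum()
    return kernel


def measure_masked_disc(convolved: np.ndarray) -> tuple[float, float]:
    """(measured diameter, measured mean) of a convolved disc.

    The convolved image is masked by Otsu's global threshold; the largest
    connected foreground component is measured.  Diameter is the
    equivalent-area diameter ``2 * sqrt(area / pi)``.

    Raises ``CalibrationError`` when the mask is empty.
    """
    if convolved.max() <= convolved.min():
        raise CalibrationError("blank image: Otsu mask undefined")
    mask = convolved > threshold_otsu(convolved)
    if not mask.any():
        raise CalibrationError("Otsu mask empty")
    labels = sk_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    region = labels == largest
    area = float(region.sum())
    diameter = 2.0 * math.sqrt(area / math.pi)
    mean = float(convolved[region].mean())
    return diameter, mean


def _one_phase_association(d, plateau, f0, k):
    return plateau + (f0 - plateau) * np.exp(-k * d)


def kernel_fwhm(psf: np.ndarray) -> float:
    """FWHM of a (near-Gaussian) kernel from its marginal standard deviation."""
    psf = np.asarray(psf, dtype=np.float64)
    marginal = psf.sum(axis=0)
    x = np.arange(marginal.size, dtype=np.float64)
    mu = float(np.dot(x, marginal))
    var = float(np.dot((x - mu) ** 2, marginal))
    return FWHM_TO_SIGMA * math.sqrt(max(var, 0.0))


def build_correction_curve(
    psf: np.ndarray,
    diameters: Sequence[float] = tuple(range(1, 51)),
    disc_intensity: float = 255.0,
    channel_name: str = "",
    fit_min_measured_diameter: float | None = None,
) -> CorrectionCurve:
    """Small-object correction curve from synthetic discs blurred by ``psf``.

    For each diameter a disc of ``disc_intensity`` on a zero background is
    convolved with the (normalized) kernel, masked by Otsu's threshold, and
    the correction factor ``disc_intensity / measured_mean`` is recorded
    against the measured mask diameter.  A one-phase exponential association
    with free plateau is then fit by least squares with relative-error
    weighting.

    Discs smaller than about twice the kernel FWHM are unresolved: their
    measured diameter is set by the PSF rather than the object, so the
    factor-vs-measured-diameter relation is not single-valued there.  Those
    points are recorded in ``sample_points`` but excluded from the fit
    (``fit_min_measured_diameter`` defaults to ``2 * kernel FWHM``); the
    curve's ``support`` starts at the first fitted diameter.  Diameters
    whose Otsu mask comes out empty are skipped with a warning; fewer than
    5 usable points is a calibration error.
    """
    psf = np.asarray(psf, dtype=np.float64)
    if not math.isclose(float(psf.sum()), 1.0, rel_tol=1e-6):
        raise ParameterError("psf kernel must be normalized to unit sum")
    if fit_min_measured_diameter is None:
        fit_min_measured_diameter = 2.0 * kernel_fwhm(psf)
    diameters = sorted(float(d) for d in diameters)
    if any(d < 1 for d in diameters):
        raise ParameterError("diameters must be >= 1 px")

    rows = []
    pad = psf.shape[0]  # keep the blurred disc away from the borders
    for d in diameters:
        size = int(math.ceil(d)) + 2 * pad + 8
        centre = ((size - 1) / 2.0, (size - 1) / 2.0)
        disc = disc_intensity * render_disc((size, size), centre, d)
        convolved = ndimage.convolve(disc, psf, mode="reflect")
        try:
            measured_d, measured_mean = measure_masked_disc(convolved)
        except CalibrationError as exc:
            logger.warning("diameter %.1f px skipped: %s", d, exc)
            continue
        rows.append(
            {
                "true_diameter_px": d,
                "measured_diameter_px": measured_d,
                "measured_mean": measured_mean,
                "correction_factor": disc_intensity / measured_mean,
            }
        )
    if len(rows) < 5:
        raise CalibrationError(
            f"only {len(rows)} usable calibration points (need >= 5)"
        )
    table = pd.DataFrame(rows)
    table["fitted"] = table["measured_diameter_px"] >= fit_min_measured_diameter

    fit_table = table.loc[table["fitted"]]
    if len(fit_table) < 5:
        raise CalibrationError(
            f"only {len(fit_table)} resolved calibration points (need >= 5)"
        )
    d_meas = fit_table["measured_diameter_px"].to_numpy()
    factors = fit_table["correction_factor"].to_numpy()
    p0 = (1.0, max(float(factors[0]), 1.01), 0.2)
    popt, _ = optimize.curve_fit(
        _one_phase_association,
        d_meas,
        factors,
        p0=p0,
        sigma=factors,  # relative-error weighting
        bounds=([0.9, 0.9, 1e-4], [1.1, 1e3, 5.0]),
        maxfev=20_000,
    )
    plateau, f0, k = (float(v) for v in popt)
    return CorrectionCurve(
        channel_name=channel_name,
        plateau=plateau,
        f0=f0,
        k=k,
        support=(float(d_meas.min()), float(d_meas.max())),
        sample_points=table,
    )


def apply_intensity_correction(
    records: pd.DataFrame,
    curve: CorrectionCurve,
    channel: str,
    diameter_column: str = "diameter_px",
) -> pd.DataFrame:
    """Multiply a channel's measured means by the correction factor.

    Expects the droplet table layout produced by the condensate stage:
    ``raw_mean_<channel>`` and ``corrected_mean_<channel>`` columns plus the
    measured ``diameter_px``.  Discarded (sub-12-px) records are never
    corrected.  Records whose diameter falls below the curve's support are
    flagged in ``correction_flagged`` and left uncorrected.
    """
    out = records.copy()
    raw_col = f"raw_mean_{channel}"
    corr_col = f"corrected_mean_{channel}"
    if raw_col not in out.columns:
        raise ParameterError(f"records lack column {raw_col!r}")
    if "correction_flagged" not in out.columns:
        out["correction_flagged"] = False
    d = out[diameter_column].to_numpy(dtype=np.float64)
    discarded = (
        out["discarded"].to_numpy(bool)
        if "discarded" in out.columns
        else np.zeros(len(out), bool)
    )
    in_support = curve.in_support(d)
    eligible = ~discarded & in_support
    factors = np.ones(len(out))
    factors[eligible] = curve.factor(d[eligible])
    out[corr_col] = out[raw_col].to_numpy(dtype=np.float64) * factors
    out.loc[~in_support & ~discarded, "correction_flagged"] = True
    return out
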