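"""Image containers, TIFF I/O, background subtraction, and fluorophore
labeling arithmetic.

The central container is :class:`ImageStack`, a thin wrapper around a numpy
array carrying the acquisition metadata the downstream stages need (pixel
size, bit depth, frame interval).  Raw acquisitions are integer-valued; any
correction stage promotes pixels to floating point and the ``[0, 2^bit-1]``
bound no longer applies.

Quantification stages emit plain :class:`pandas.DataFrame` tables whose
``attrs['provenance']`` records the source, stage name, and a digest of the
parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, FormatError, ParameterError

logger = logging.getLogger("phaseq")

__all__ = [
    "ImageStack",
    "DyeSpectralConstants",
    "ALEXA_488",
    "ALEXA_568",
    "ALEXA_647",
    "LabelingMetrics",
    "read_image_stack",
    "write_image_stack",
    "subtract_background_frame",
    "labeling_metrics",
    "with_provenance",
    "params_digest",
]


@dataclass
class ImageStack:
    """A single-channel 2D field or 3D (z or t, y, x) stack.

    Parameters
    ----------
    pixels
        Non-negative intensity array, ``(y, x)`` or ``(z|t, y, x)``.
    channel_name
        Free-text channel label (e.g. ``"488"``, ``"647"``).
    pixel_size_um
        Micrometres per pixel, strictly positive.
    bit_depth
        Acquisition bit depth (8 or 16).  Raw reads are validated against
        ``[0, 2**bit_depth - 1]``; corrected stacks are float and unbounded.
    frame_interval_s
        Seconds per frame for time series; ``None`` for single frames and
        z-stacks without timing.
    background_corrected
        Set by :func:`subtract_background_frame`.
    """

    pixels: np.ndarray
    channel_name: str = ""
    pixel_size_um: float = 1.0
    bit_depth: int = 16
    frame_interval_s: float | None = None
    background_corrected: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise DimensionError(
                f"ImageStack must be 2D or 3D, got ndim={self.pixels.ndim}"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0 when present")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if np.issubdtype(self.pixels.dtype, np.integer):
            lo, hi = self.pixels.min(initial=0), self.pixels.max(initial=0)
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise FormatError(
                    f"integer pixels outside [0, {2**self.bit_depth - 1}]"
                )
        elif np.any(self.pixels < 0):
            raise ParameterError("pixel values must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def ndim(self) -> int:
        return self.pixels.ndim

    @property
    def n_frames(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def frame(self, index: int) -> np.ndarray:
        """Return one (y, x) plane (the array itself for 2D stacks)."""
        return self.pixels if self.pixels.ndim == 2 else self.pixels[index]

    def astype_float(self) -> "ImageStack":
        return replace(self, pixels=self.pixels.astype(np.float64))


@dataclass(frozen=True)
class DyeSpectralConstants:
    """Spectral constants used for protein-concentration and
    degree-of-labeling arithmetic from a UV-Vis absorbance scan.

    ``a280_correction`` is the fraction of the dye's peak absorbance that
    bleeds into the 280 nm protein band; ``dye_extinction`` is the dye's
    molar extinction coefficient at its absorbance peak.
    """

    dye_name: str
    a280_correction: float
    dye_extinction: float
    dye_peak_wavelength_nm: float

    def __post_init__(self) -> None:
        if not 0 < self.a280_correction < 1:
            raise ParameterError("a280_correction must lie in (0, 1)")
        if self.dye_extinction <= 0:
            raise ParameterError("dye_extinction must be > 0")


ALEXA_488 = DyeSpectralConstants("Alexa488", 0.11, 71_000.0, 494.0)
ALEXA_568 = DyeSpectralConstants("Alexa568", 0.46, 91_300.0, 577.0)
ALEXA_647 = DyeSpectralConstants("Alexa647", 0.03, 239_000.0, 650.0)


class LabelingMetrics(NamedTuple):
    concentration_m: float
    degree_of_labeling: float


def read_image_stack(
    path: str | Path,
    pixel_size_um: float = 1.0,
    frame_interval_s: float | None = None,
    channel_name: str = "",
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Axes are normalized to ``(t/z, y, x)`` for multi-page files and
    ``(y, x)`` for single pages.  Bit depth is inferred from the sample
    format; only unsigned 8- and 16-bit grayscale TIFFs are accepted.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / unreadable TIFF
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported axis layout {arr.shape}")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"{path}: unsupported sample format {arr.dtype}")
    return ImageStack(
        pixels=arr,
        channel_name=channel_name,
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        frame_interval_s=frame_interval_s,
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as an 8/16-bit grayscale TIFF.

    Float-valued stacks are rounded and clipped to the stack's bit depth;
    integer stacks round-trip exactly.
    """
    path = Path(path)
    hi = 2**stack.bit_depth - 1
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    pixels = stack.pixels
    if not np.issubdtype(pixels.dtype, np.integer):
        pixels = np.clip(np.rint(pixels), 0, hi)
    tifffile.imwrite(path, pixels.astype(dtype), photometric="minisblack")
    return path


def subtract_background_frame(
    image: ImageStack, background: ImageStack
) -> ImageStack:
    """Subtract a dark/background calibration frame pixel-wise.

    Negative differences are clipped to zero so that downstream mean
    intensities stay non-negative.  The background frame must match the
    image's ``(y, x)`` shape; for 3D stacks it is broadcast across frames.
    """
    bg = background.frame(0) if background.ndim == 3 else background.pixels
    if image.pixels.shape[-2:] != bg.shape:
        raise DimensionError(
            f"background shape {bg.shape} does not match image "
            f"(y, x) shape {image.pixels.shape[-2:]}"
        )
    corrected = np.clip(
        image.pixels.astype(np.float64) - bg.astype(np.float64), 0.0, None
    )
    return replace(image, pixels=corrected, background_corrected=True)


def labeling_metrics(
    a280: float,
    a_dye: float,
    protein_ext_coef: float,
    constants: DyeSpectralConstants,
) -> LabelingMetrics:
    """Protein concentration and degree of labeling from absorbances.

    concentration (M) = (A280 - A_dye * a280_correction) / protein_ext_coef
    degree of labeling = A_dye / (dye_extinction * concentration)

    Raises :class:`ParameterError` when the dye bleed-through dominates the
    280 nm signal (non-positive concentration).
    """
    if a280 < 0 or a_dye < 0:
        raise ParameterError("absorbances must be >= 0")
    if protein_ext_coef <= 0:
        raise ParameterError("protein_ext_coef must be > 0")
    concentration = (a280 - a_dye * constants.a280_correction) / protein_ext_coef
    if concentration <= 0:
        raise ParameterError(
            "computed concentration <= 0: dye absorbance dominates A280"
        )
    dol = 0.0 if a_dye == 0 else a_dye / (constants.dye_extinction * concentration)
    return LabelingMetrics(concentration, dol)


def params_digest(params: dict) -> str:
    """Short stable digest of a parameter mapping (for provenance)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def with_provenance(
    df: pd.DataFrame,
    stage: str,
    params: dict | None = None,
    source: str | None = None,
) -> pd.DataFrame:
    """Attach provenance (stage name, parameter digest, source) to a table."""
    params = params or {}
    df.attrs["provenance"] = {
        "stage": stage,
        "source": source,
        "params": params,
        "params_digest": params_digest(params),
    }
    logger.info("stage=%s digest=%s source=%s", stage, df.attrs["provenance"]["params_digest"], source)
    return df
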