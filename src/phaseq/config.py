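"""Declarative pipeline configuration.

One YAML file holds every tunable of every stage; unknown keys are
rejected so typos fail loudly, and each output table embeds the digest of
the fully resolved configuration (see
:func:`phaseq.core_io.with_provenance`), making results reproducible from
config + inputs alone.  All randomness flows from the single top-level
``seed``; stages derive sub-seeds deterministically from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_io import params_digest
from .errors import ConfigurationError


@dataclass
class PsfConfig:
    linescan_halfwidth_px: int = 10
    average_axes: bool = False
    calibration_diameter_min_px: int = 1
    calibration_diameter_max_px: int = 50
    disc_intensity: float = 255.0


@dataclass
class DropletConfig:
    mask_channel: str = "647"
    dilation_radius_px: int = 5
    min_diameter_px: float = 12.0
    apply_psf_correction: bool = True
    trend_pretest: bool = True
    trend_alpha: float = 0.05


@dataclass
class FrapConfig:
    alpha: float = 0.05
    n_prebleach: int = 3
    plateau_low: float = 0.0
    plateau_high: float = 1.2
    k_low: float = 1e-4
    k_high: float = 10.0
    qc_threshold_s: float = 10.0


@dataclass
class AdhesionConfig:
    rolling_radius_px: int = 50
    clahe_blocksize: int = 19
    clahe_bins: int = 256
    clahe_max_slope: float = 6.0
    exp_curvature: float = 5.545177444479562  # 8 ln 2
    saturated_percent: float = 0.35
    log_sigma: float = 2.0
    min_area_px2: float = 5.0
    max_area_px2: float = 1000.0
    min_circularity: float = 0.0
    max_circularity: float = 1.0
    area_threshold_low: float = 5500.0
    area_threshold_high: float = 65535.0
    gfp_gate_low: float = 1000.0
    gfp_gate_high: float = 5000.0


@dataclass
class PipelineConfig:
    version: str = "1"
    seed: int = 0
    pixel_size_um: float = 0.25
    psf: PsfConfig = field(default_factory=PsfConfig)
    droplets: DropletConfig = field(default_factory=DropletConfig)
    frap: FrapConfig = field(default_factory=FrapConfig)
    adhesions: AdhesionConfig = field(default_factory=AdhesionConfig)

    def digest(self) -> str:
        return params_digest(dataclasses.asdict(self))

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed below 2**31."""
        import hashlib

        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _build(cls, payload: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'"
        )
    return cls(**payload)


_SECTIONS = {"psf": PsfConfig, "droplets": DropletConfig, "frap": FrapConfig, "adhesions": AdhesionConfig}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys; ``None`` gives defaults."""
    if path is None:
        return PipelineConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("config root must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for name, value in payload.items():
        if name in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build(_SECTIONS[name], value, name)
        else:
            kwargs[name] = value
    return PipelineConfig(**kwargs)
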