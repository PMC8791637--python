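"""FRAP trace normalization, exponential recovery fits, and nested-model
selection.

A bleached region recovers as mobile molecules exchange with the
surroundings.  After background subtraction and multiplicative correction
for acquisition photobleaching (ROI divided by the reference region
rescaled to its prebleach mean), traces are normalized as

    N(t) = (I(t) - I_post) / (I_pre - I_post)

with ``I_pre`` the mean of the prebleach frames and ``I_post`` the
corrected ROI intensity at the first post-bleach frame (t = 0), so that
N(0) = 0 and the prebleach level is 1.  Recovery is fit with

    single:  N(t) = P * (1 - exp(-k t))
    double:  N(t) = P * (phi * (1 - exp(-k1 t)) + (1 - phi) * (1 - exp(-k2 t)))

with plateau P in [0, 1.2] (immobile fraction = 1 - P) and the fast
component listed first.  The two nested models are compared with the extra
sum-of-squares F test; the biexponential is preferred iff p < alpha.

Supported-bilayer fluidity is gated on the single-exponential half-time:
experiments proceed only if t_1/2 < 10 s (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateBleachError,
    FitError,
    ModelSelectionError,
    ParameterError,
    PipelineError,
)

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FrapFit",
    "ModelSelection",
    "normalize_trace",
    "fit_recovery",
    "select_model",
    "fit_and_select",
    "qc_bilayer_fluidity",
]

LN2 = math.log(2.0)


@dataclass
class FrapTrace:
    """Raw per-frame intensities for one FRAP experiment.

    ``t`` is in seconds with ``t = 0`` at the first post-bleach frame and
    prebleach frames at negative times; ``background_intensity`` may be a
    per-frame series or a scalar.
    """

    t: np.ndarray
    roi_intensity: np.ndarray
    reference_intensity: np.ndarray
    background_intensity: np.ndarray | float
    n_prebleach: int = 3

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=np.float64)
        self.reference_intensity = np.asarray(
            self.reference_intensity, dtype=np.float64
        )
        if np.ndim(self.background_intensity) > 0:
            self.background_intensity = np.asarray(
                self.background_intensity, dtype=np.float64
            )
            if self.background_intensity.shape != self.t.shape:
                raise ParameterError("background series length mismatch")
        if not (
            self.t.shape == self.roi_intensity.shape == self.reference_intensity.shape
        ):
            raise ParameterError("t / roi / reference series must share length")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("t must be strictly increasing")
        if self.n_prebleach < 3:
            raise ParameterError("need >= 3 prebleach frames")
        if len(self.t) <= self.n_prebleach:
            raise ParameterError("no post-bleach frames")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_prebleach: int = 3) -> "FrapTrace":
        required = {"t", "roi_intensity", "reference_intensity", "background_intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"trace table missing columns: {sorted(missing)}")
        return cls(
            t=df["t"].to_numpy(),
            roi_intensity=df["roi_intensity"].to_numpy(),
            reference_intensity=df["reference_intensity"].to_numpy(),
            background_intensity=df["background_intensity"].to_numpy(),
            n_prebleach=n_prebleach,
        )


@dataclass
class NormalizedTrace:
    """Normalized recovery: post-bleach times (t[0] = 0) and N(t), plus the
    normalized prebleach samples (mean exactly 1 by construction)."""

    t: np.ndarray
    normalized: np.ndarray
    prebleach_normalized: np.ndarray


def normalize_trace(trace: FrapTrace) -> NormalizedTrace:
    """Background-subtract, photobleach-correct, and normalize a trace.

    The reference series (bulk region of identical size) tracks acquisition
    photobleaching; the ROI is divided frame-wise by the reference rescaled
    to its own prebleach mean.  Raises
    :class:`~phaseq.errors.DegenerateBleachError` when the corrected trace
    shows no bleach (I_pre <= I_post) and :class:`PipelineError` when the
    corrected reference decays to <= 0.
    """
    npre = trace.n_prebleach
    roi = trace.roi_intensity - trace.background_intensity
    ref = trace.reference_intensity - trace.background_intensity
    ref_pre = float(np.mean(ref[:npre]))
    if ref_pre <= 0:
        raise PipelineError("reference region at or below background")
    bleach = ref / ref_pre
    if np.any(bleach <= 0):
        raise PipelineError("reference decays to <= 0: correction impossible")
    corrected = roi / bleach
    i_pre = float(np.mean(corrected[:npre]))
    i_post = float(corrected[npre])
    if i_pre <= i_post:
        raise DegenerateBleachError(
            f"no bleach depth: I_pre={i_pre:.3g} <= I_post={i_post:.3g}"
        )
    normalized = (corrected - i_post) / (i_pre - i_post)
    return NormalizedTrace(
        t=trace.t[npre:].copy(),
        normalized=normalized[npre:],
        prebleach_normalized=normalized[:npre],
    )


@dataclass
class FrapFit:
    """One exponential-recovery fit.

    ``fractions`` are absolute recovering fractions of the prebleach signal
    (they sum to the plateau); ``t_half = ln 2 / k`` per component with the
    fast component first; ``plateau_resolved`` is False when the recovery
    has not plateaued within the observation window (reported as "nd" in
    tabular output).
    """

    model: str
    plateau: float
    fractions: tuple[float, ...]
    rate_constants: tuple[float, ...]
    t_half: tuple[float, ...]
    immobile_fraction: float
    sum_sq: float
    dof: int
    plateau_resolved: bool
    plateau_stderr: float = math.nan
    n_points: int = 0


def _model_single(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def _model_double(t, plateau, phi, k1, k2):
    return plateau * (
        phi * (1.0 - np.exp(-k1 * t)) + (1.0 - phi) * (1.0 - np.exp(-k2 * t))
    )


def _initial_rate_guess(t: np.ndarray, n: np.ndarray) -> float:
    """k from the time at which recovery first reaches half its final value."""
    final = float(np.mean(n[-max(3, len(n) // 10) :]))
    if final <= 0:
        return 0.1
    half_idx = np.argmax(n >= 0.5 * final)
    t_half_obs = float(t[half_idx]) if t[half_idx] > 0 else float(t[1])
    return LN2 / max(t_half_obs, 1e-6)


def _leastsq(model, t, n, p0, bounds):
    popt, pcov = optimize.curve_fit(
        model, t, n, p0=p0, bounds=bounds, maxfev=20_000
    )
    resid = n - model(t, *popt)
    return popt, pcov, float(np.sum(resid**2))


def fit_recovery(
    t: np.ndarray,
    normalized: np.ndarray,
    model: str = "single",
    plateau_bounds: tuple[float, float] = (0.0, 1.2),
    k_bounds: tuple[float, float] = (1e-4, 10.0),
) -> FrapFit:
    """Least-squares fit of the normalized recovery.

    Starts are deterministic: the rate guess comes from the time to half of
    the final observed recovery, expanded into a small multiplicative grid
    (for the biexponential, pairs bracketing the single-rate guess plus a
    nested start equivalent to the best single fit so the double model
    never fits worse than the single).
    """
    t = np.asarray(t, dtype=np.float64)
    n = np.asarray(normalized, dtype=np.float64)
    if len(t) < 10:
        raise ParameterError("need >= 10 post-bleach points")
    if abs(n[0]) > 0.05:
        raise ParameterError("normalized trace must start near N(0) = 0")
    k0 = float(np.clip(_initial_rate_guess(t, n), *k_bounds))
    p_hi = plateau_bounds[1]
    p0_plateau = float(np.clip(np.mean(n[-3:]), 0.05, p_hi))

    best = None
    errors = []
    if model == "single":
        bounds = ([plateau_bounds[0], k_bounds[0]], [p_hi, k_bounds[1]])
        starts = [
            (p0_plateau, float(np.clip(k0 * m, *k_bounds))) for m in (0.3, 1.0, 3.0)
        ]
        fitter = _model_single
    elif model == "double":
        bounds = (
            [plateau_bounds[0], 0.0, k_bounds[0], k_bounds[0]],
            [p_hi, 1.0, k_bounds[1], k_bounds[1]],
        )
        clip = lambda k: float(np.clip(k, *k_bounds))
        starts = [
            (p0_plateau, 0.5, clip(k0 * 5), clip(k0 / 5)),
            (p0_plateau, 0.5, clip(k0 * 20), clip(k0 / 2)),
            (p0_plateau, 0.3, clip(k0 * 2), clip(k0 / 20)),
            (p0_plateau, 1.0, clip(k0), clip(k0 / 10)),  # nested: single fit
        ]
        fitter = _model_double
    else:
        raise ParameterError("model must be 'single' or 'double'")

    for p0 in starts:
        try:
            popt, pcov, ss = _leastsq(fitter, t, n, p0, bounds)
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise FitError(f"{model} fit failed from every start: {errors}")
    popt, pcov, ss = best

    if model == "single":
        plateau, k = float(popt[0]), float(popt[1])
        fractions = (plateau,)
        rates = (k,)
        plateau_var = pcov[0, 0]
    else:
        plateau, phi, k1, k2 = (float(v) for v in popt)
        if k2 > k1:  # enforce fast-first ordering
            k1, k2 = k2, k1
            phi = 1.0 - phi
        fractions = (plateau * phi, plateau * (1.0 - phi))
        rates = (k1, k2)
        plateau_var = pcov[0, 0]
    t_half = tuple(LN2 / k for k in rates)
    dof = len(n) - len(popt)
    plateau_stderr = (
        math.sqrt(plateau_var) if np.isfinite(plateau_var) and plateau_var >= 0 else math.nan
    )
    window = float(t[-1] - t[0])
    ci_width = 2 * 1.96 * plateau_stderr if math.isfinite(plateau_stderr) else math.inf
    resolved = (max(t_half) <= window / 2) and (ci_width <= 0.3)
    return FrapFit(
        model=model,
        plateau=plateau,
        fractions=fractions,
        rate_constants=rates,
        t_half=t_half,
        immobile_fraction=1.0 - plateau,
        sum_sq=ss,
        dof=dof,
        plateau_resolved=resolved,
        plateau_stderr=plateau_stderr,
        n_points=len(n),
    )


@dataclass
class ModelSelection:
    """Extra sum-of-squares F test between nested recovery models."""

    f_statistic: float
    p_value: float
    alpha: float
    chosen: str


def select_model(
    fit_single: FrapFit, fit_double: FrapFit, alpha: float = 0.05
) -> ModelSelection:
    """Compare single vs double exponential fits on the same data.

    F = ((SS1 - SS2) / (dof1 - dof2)) / (SS2 / dof2), with p from the F
    distribution on (dof1 - dof2, dof2) degrees of freedom; the double
    model is chosen iff p < alpha.
    """
    if fit_single.n_points != fit_double.n_points:
        raise ParameterError("fits must be on identical data")
    ss1, ss2 = fit_single.sum_sq, fit_double.sum_sq
    dof1, dof2 = fit_single.dof, fit_double.dof
    if dof1 <= dof2:
        raise ParameterError("single model must have more residual dof")
    if ss2 > ss1 * (1 + 1e-9):
        raise ModelSelectionError(
            f"nested-model violation: SS_double={ss2:.4g} > SS_single={ss1:.4g}"
        )
    if ss2 <= 0:
        f_stat = math.inf
        p = 0.0
    else:
        f_stat = ((ss1 - ss2) / (dof1 - dof2)) / (ss2 / dof2)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, dof1 - dof2, dof2))
    chosen = "double" if p < alpha else "single"
    return ModelSelection(f_statistic=float(f_stat), p_value=p, alpha=alpha, chosen=chosen)


def fit_and_select(
    t: np.ndarray, normalized: np.ndarray, alpha: float = 0.05
) -> tuple[FrapFit, FrapFit, ModelSelection, FrapFit]:
    """Fit both models, run the F test, and return the preferred fit."""
    fit1 = fit_recovery(t, normalized, model="single")
    fit2 = fit_recovery(t, normalized, model="double")
    if fit2.sum_sq > fit1.sum_sq:
        # the single optimum lives inside the double parameter space;
        # refitting cannot be worse, so fall back to the nested solution
        fit2 = FrapFit(
            model="double",
            plateau=fit1.plateau,
            fractions=(fit1.fractions[0], 0.0),
            rate_constants=(fit1.rate_constants[0], fit1.rate_constants[0] / 10),
            t_half=(fit1.t_half[0], 10 * fit1.t_half[0]),
            immobile_fraction=fit1.immobile_fraction,
            sum_sq=fit1.sum_sq,
            dof=len(normalized) - 4,
            plateau_resolved=fit1.plateau_resolved,
            plateau_stderr=fit1.plateau_stderr,
            n_points=fit1.n_points,
        )
    selection = select_model(fit1, fit2, alpha)
    best = fit2 if selection.chosen == "double" else fit1
    return fit1, fit2, selection, best


def qc_bilayer_fluidity(fit: FrapFit, threshold_s: float = 10.0) -> bool:
    """Bilayer fluidity gate: pass iff the half-time is strictly < 10 s."""
    return fit.t_half[0] < threshold_s
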