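"""Template-mixture fits to relative-sensitivity spectra.

An anomalous action spectrum — e.g. a pigment whose retinal Schiff base is
only partially protonated — may be the superposition of two spectrally
distinct pigment pools.  This module fits a relative-sensitivity spectrum
with either a single A1 template or the weighted sum of two templates
(weights on the simplex, i.e. percentages summing to 100%), plus a free
amplitude scale absorbing the spectrum's max-equals-1 normalisation, and
compares the two models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .irc import SensitivitySpectrum
from .templates import GovardovskiiTemplate, TemplateMixture

__all__ = [
    "MixtureFitResult",
    "ModelComparison",
    "fit_single_template",
    "fit_dual_template",
    "compare_models",
]

_AMP_BOUNDS = (0.5, 2.0)


@dataclass(frozen=True)
class MixtureFitResult:
    """Fitted template mixture with goodness of fit.

    Components are sorted ascending by λmax.  ``effective_single`` marks a
    dual fit that collapsed to one component (boundary weight or coincident
    peaks).  ``aic`` is reported for transparency alongside R².
    """

    mixture: TemplateMixture
    amplitude: float
    r_squared: float
    residuals: tuple[float, ...]
    converged: bool
    n_starts: int
    aic: float
    effective_single: bool = False

    @property
    def n_components(self) -> int:
        return len(self.mixture.components)

    def predict(self, wavelength) -> np.ndarray:
        return self.amplitude * np.asarray(self.mixture.sensitivity(wavelength))

    def fitted_curve(self, start: float = 300.0, stop: float = 700.0) -> pd.DataFrame:
        grid = np.arange(start, stop + 0.5, 1.0)
        return pd.DataFrame(
            {"wavelength_nm": grid, "fitted_sensitivity": self.predict(grid)}
        )


def _goodness(y: np.ndarray, yhat: np.ndarray, k: int) -> tuple[float, float, float]:
    resid = y - yhat
    sse = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - sse / tss) if tss > 0 else 0.0
    n = len(y)
    aic = n * np.log(max(sse, 1e-300) / n) + 2 * k
    return sse, r2, float(aic)


def fit_single_template(
    spectrum: SensitivitySpectrum,
    search_range: tuple[float, float] = (330.0, 600.0),
) -> MixtureFitResult:
    """Least-squares single-template fit: parameters (λmax, amplitude).

    Seeded from a coarse λmax grid (amplitude solved in closed form per
    grid point), then refined with bounded least squares.  Deterministic.
    """
    wl = np.asarray(spectrum.wavelengths, dtype=float)
    y = np.asarray(spectrum.values, dtype=float)
    if len(wl) < 3:
        raise ValueError("need >= 3 wavelengths to fit a single template")
    lo, hi = search_range

    def model(params):
        lmax, amp = params
        return amp * np.asarray(GovardovskiiTemplate(float(lmax)).sensitivity(wl))

    best = None
    for lmax in np.arange(lo, hi + 1, 5.0):
        t = np.asarray(GovardovskiiTemplate(float(lmax)).sensitivity(wl))
        amp = float(np.clip(np.dot(t, y) / np.dot(t, t), *_AMP_BOUNDS))
        sse = float(np.sum((y - amp * t) ** 2))
        if best is None or sse < best[0]:
            best = (sse, lmax, amp)
    res = least_squares(
        lambda p: model(p) - y,
        x0=[best[1], best[2]],
        bounds=([lo, _AMP_BOUNDS[0]], [hi, _AMP_BOUNDS[1]]),
    )
    lmax, amp = float(res.x[0]), float(res.x[1])
    yhat = model(res.x)
    _, r2, aic = _goodness(y, yhat, k=2)
    return MixtureFitResult(
        mixture=TemplateMixture.single(lmax),
        amplitude=amp,
        r_squared=r2,
        residuals=tuple(float(v) for v in (y - yhat)),
        converged=bool(res.success),
        n_starts=1,
        aic=aic,
    )


def fit_dual_template(
    spectrum: SensitivitySpectrum,
    search_range: tuple[float, float] = (330.0, 600.0),
    coarse_step: float = 20.0,
) -> MixtureFitResult:
    """Least-squares two-template fit: parameters (λ₁, λ₂, w₁, amplitude).

    w₂ = 1 − w₁ and λ₁ < λ₂ are enforced by sorting; multi-start from a
    coarse λ-pair × weight grid keeps the non-convex problem deterministic.
    A solution at the weight boundary (w₁ ≈ 0 or 1) or with coincident
    peaks is reported as an effectively single-template fit.
    """
    wl = np.asarray(spectrum.wavelengths, dtype=float)
    y = np.asarray(spectrum.values, dtype=float)
    if len(wl) < 4:
        raise ValueError("need >= 4 wavelengths to fit two templates")
    lo, hi = search_range

    def model(params):
        l1, l2, w, amp = params
        s1 = np.asarray(GovardovskiiTemplate(float(l1)).sensitivity(wl))
        s2 = np.asarray(GovardovskiiTemplate(float(l2)).sensitivity(wl))
        return amp * (w * s1 + (1.0 - w) * s2)

    grid = np.arange(lo, hi + 1, coarse_step)
    starts = [
        (l1, l2, w, 1.0)
        for i, l1 in enumerate(grid)
        for l2 in grid[i + 1:]
        for w in (0.25, 0.5, 0.75)
    ]
    bounds = ([lo, lo, 0.0, _AMP_BOUNDS[0]], [hi, hi, 1.0, _AMP_BOUNDS[1]])
    best = None
    for start in starts:
        res = least_squares(lambda p: model(p) - y, x0=list(start), bounds=bounds)
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res)
    res = best[1]
    l1, l2, w, amp = (float(v) for v in res.x)
    if l1 > l2:  # sort components ascending by λmax
        l1, l2, w = l2, l1, 1.0 - w
    yhat = model([l1, l2, w, amp])
    _, r2, aic = _goodness(y, yhat, k=4)
    effective_single = w < 0.01 or w > 0.99 or abs(l2 - l1) < 2.0
    # clip away float dust so the mixture invariant (simplex weights) holds
    w = float(np.clip(w, 0.0, 1.0))
    return MixtureFitResult(
        mixture=TemplateMixture(((l1, w), (l2, 1.0 - w))),
        amplitude=amp,
        r_squared=r2,
        residuals=tuple(float(v) for v in (y - yhat)),
        converged=bool(res.success),
        n_starts=len(starts),
        aic=aic,
        effective_single=effective_single,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of the single-vs-dual template comparison."""

    choice: str  # "single" | "dual"
    single_r_squared: float
    dual_r_squared: float
    delta_r_squared: float
    min_weight: float
    reason: str

    def report(self) -> str:
        return (
            f"model choice: {self.choice} "
            f"(single R²={self.single_r_squared:.3f}, "
            f"dual R²={self.dual_r_squared:.3f}, ΔR²={self.delta_r_squared:.3f}; "
            f"{self.reason})"
        )


def compare_models(
    single: MixtureFitResult,
    dual: MixtureFitResult,
    delta_r2_threshold: float = 0.05,
    min_weight: float = 0.05,
) -> ModelComparison:
    """Prefer the dual fit only when it earns its extra parameters.

    The dual model is chosen when its R² improvement exceeds
    ``delta_r2_threshold`` AND both component weights are at least
    ``min_weight``; otherwise the single-template fit stands.
    """
    delta = dual.r_squared - single.r_squared
    wmin = min(w for _, w in dual.mixture.components)
    if wmin < min_weight:
        choice, reason = "single", f"minority weight {wmin:.3f} < {min_weight}"
    elif delta <= delta_r2_threshold:
        choice, reason = "single", f"ΔR² {delta:.3f} <= {delta_r2_threshold}"
    else:
        choice, reason = "dual", (
            f"ΔR² {delta:.3f} > {delta_r2_threshold} and both weights >= "
            f"{min_weight}"
        )
    return ModelComparison(
        choice=choice,
        single_r_squared=single.r_squared,
        dual_r_squared=dual.r_squared,
        delta_r_squared=delta,
        min_weight=wmin,
        reason=reason,
    )
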