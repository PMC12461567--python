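"""Irradiance-response curve (IRC) fitting and relative spectral sensitivity.

Each wavelength's peak responses over an intensity series are fit with a
four-parameter logistic (4PL) in log10 photon flux: floor, ceiling, log EC50
and Hill slope.  Relative sensitivity across wavelengths derives from the
fitted EC50s: the most sensitive wavelength (lowest EC50) is assigned 1 and
each other wavelength gets EC50_min / EC50 on the linear flux scale, so that
needing more photons for the same response means lower sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import ResponseDataset

__all__ = [
    "SigmoidFit",
    "SensitivitySpectrum",
    "four_param_logistic",
    "fit_irc",
    "fit_all_wavelengths",
    "relative_sensitivity",
]

_HILL_STARTS = (0.5, 1.0, 2.0)


def four_param_logistic(x, lower, upper, log_ec50, hill_slope):
    """4PL response at log10 intensity ``x`` (ascending, positive slope)."""
    return lower + (upper - lower) / (1.0 + 10.0 ** (hill_slope * (log_ec50 - x)))


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted 4PL parameters with goodness of fit.

    ``flag`` is ``None`` for a valid fit, else a diagnostic string
    (``"flat"``, ``"no_convergence"``, ``"non_identifiable"``).
    """

    lower: float
    upper: float
    log_ec50: float
    hill_slope: float
    r_squared: float
    n_points: int
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None

    def predict(self, x) -> np.ndarray:
        return four_param_logistic(
            np.asarray(x, dtype=float),
            self.lower, self.upper, self.log_ec50, self.hill_slope,
        )


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return max(0.0, 1.0 - float(np.sum((y - yhat) ** 2)) / tss)


def fit_irc(
    log_intensity,
    response,
    p0: tuple[float, float, float, float] | None = None,
) -> SigmoidFit:
    """Least-squares 4PL fit of responses against log10 intensity.

    Deterministic: initial values derive from data quantiles with a fixed
    set of Hill-slope starts (or a caller-supplied ``p0``); the best
    sum-of-squares solution wins.  Requires >= 5 distinct intensities.
    Degenerate data (flat responses) or failed optimisation yield a flagged
    fit rather than a silent value.
    """
    x = np.asarray(log_intensity, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log_intensity and response must be 1-D and aligned")
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct intensities for a 4PL fit")

    n = len(y)
    yspan = float(np.ptp(y))
    if yspan < 1e-12 * max(1.0, abs(float(y.mean()))):
        return SigmoidFit(float(y.mean()), float(y.mean()) + 1e-12, float(x.mean()),
                          1.0, 0.0, n, flag="flat")

    ymin, ymax = float(y.min()), float(y.max())
    # log EC50 start: intensity whose mean response is nearest the midpoint
    mid = (ymin + ymax) / 2.0
    order = np.argsort(x)
    x0 = float(x[order][np.argmin(np.abs(y[order] - mid))])
    lo_b = (0.0, ymin, x.min() - 3.0, 1e-3)
    hi_b = (ymax, 10.0 * ymax + 1.0, x.max() + 3.0, 20.0)

    starts = [p0] if p0 is not None else [
        (ymin, ymax, x0, h) for h in _HILL_STARTS
    ]
    best: tuple[float, np.ndarray] | None = None
    for start in starts:
        start = np.clip(np.asarray(start, dtype=float),
                        np.asarray(lo_b) + 1e-9, np.asarray(hi_b) - 1e-9)
        try:
            popt, _ = curve_fit(
                four_param_logistic, x, y, p0=start,
                bounds=(lo_b, hi_b), maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - four_param_logistic(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return SigmoidFit(ymin, ymax, x0, 1.0, 0.0, n, flag="no_convergence")

    lower, upper, log_ec50, hill = (float(v) for v in best[1])
    r2 = _r_squared(y, four_param_logistic(x, *best[1]))
    flag = None
    if upper - lower < 1e-6 * max(1.0, ymax):
        flag = "non_identifiable"
    elif not (x.min() - 2.5 < log_ec50 < x.max() + 2.5):
        flag = "non_identifiable"
    return SigmoidFit(lower, upper, log_ec50, hill, r2, n, flag=flag)


def fit_all_wavelengths(dataset: ResponseDataset) -> dict[float, SigmoidFit]:
    """Pooled-replicate 4PL fit per wavelength of a response dataset."""
    fits: dict[float, SigmoidFit] = {}
    for wl in dataset.wavelengths:
        sub = dataset.at_wavelength(wl)
        fits[float(wl)] = fit_irc(sub["log_intensity"], sub["response"])
    return fits


@dataclass(frozen=True)
class SensitivitySpectrum:
    """Relative sensitivity per wavelength, normalised to a maximum of 1."""

    wavelengths: tuple[float, ...]
    values: tuple[float, ...]
    log_ec50s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals <= 0) or np.any(vals > 1.0 + 1e-9):
            raise ValueError("sensitivities must lie in (0, 1]")
        if not np.isclose(vals.max(), 1.0):
            raise ValueError("exactly one wavelength must have sensitivity 1")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "sensitivity": self.values}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SensitivitySpectrum":
        if not {"wavelength_nm", "sensitivity"} <= set(frame.columns):
            raise ValueError("spectrum needs wavelength_nm and sensitivity columns")
        return cls(
            tuple(float(w) for w in frame["wavelength_nm"]),
            tuple(float(s) for s in frame["sensitivity"]),
        )


def relative_sensitivity(fits: dict[float, SigmoidFit]) -> SensitivitySpectrum:
    """EC50-ratio sensitivity spectrum from per-wavelength 4PL fits.

    sensitivity(λ) = EC50_min / EC50(λ) on the linear flux scale.  All input
    fits must be valid; flagged fits raise with the offending wavelengths.
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 wavelengths")
    bad = sorted(wl for wl, f in fits.items() if not f.ok)
    if bad:
        raise ValueError(f"flagged IRC fits at wavelengths: {bad}")
    wavelengths = tuple(sorted(fits))
    log_ec50s = np.array([fits[wl].log_ec50 for wl in wavelengths])
    values = 10.0 ** (log_ec50s.min() - log_ec50s)
    return SensitivitySpectrum(
        wavelengths=wavelengths,
        values=tuple(float(v) for v in values),
        log_ec50s=tuple(float(v) for v in log_ec50s),
    )
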