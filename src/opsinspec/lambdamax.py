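"""Peak spectral sensitivity (λmax) estimation via effective photon flux.

The estimator assumes the pigment follows an A1 template.  For a candidate
λmax, every stimulus is re-expressed as *effective* photon flux — stimulus
flux multiplied by the candidate template's sensitivity at the stimulus
wavelength (a sum on the log10 scale).  At the correct λmax, irradiance-
response curves from every wavelength collapse onto a single sigmoid in
effective flux; the estimator scans candidates, scores each by the residual
sum of squares of one shared four-parameter sigmoid fit to the pooled
records, and returns the candidate that best predicts response amplitude
across wavelengths and intensities.  Uncertainty comes from a stratified
bootstrap over replicate records, reported as "λmax ± SE".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .irc import SigmoidFit, fit_irc
from .simulate import ResponseDataset
from .templates import GovardovskiiTemplate

__all__ = [
    "NonIdentifiableError",
    "PooledObjective",
    "LambdaMaxEstimate",
    "effective_flux",
    "pooled_fit_objective",
    "estimate_lambda_max",
    "bootstrap_lambda_max",
    "default_search_range",
]


class NonIdentifiableError(ValueError):
    """Raised when the data cannot pin down a λmax (e.g. flat profile)."""


def effective_flux(log_intensity, wavelength, candidate_lambda_max: float):
    """log10 effective photon flux under a candidate template.

    ``log_intensity + log10(S_candidate(wavelength))``; since template
    sensitivity peaks near 1, effective flux never exceeds the stimulus flux
    by more than log10(peak) ≈ 0.0003.
    """
    template = GovardovskiiTemplate(candidate_lambda_max)
    logi = np.asarray(log_intensity, dtype=float)
    out = logi + np.log10(np.asarray(template.sensitivity(wavelength)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PooledObjective:
    """Goodness of fit of one shared sigmoid in effective-flux coordinates."""

    sse: float
    r_squared: float
    fit: SigmoidFit


def pooled_fit_objective(
    dataset: ResponseDataset,
    candidate_lambda_max: float,
    p0: tuple[float, float, float, float] | None = None,
) -> PooledObjective:
    """Score a candidate λmax by pooled single-sigmoid residuals.

    All records are transformed to effective flux under the candidate and fit
    with ONE shared 4PL; the SSE (and R²) of that fit is the objective.  A
    non-convergent shared fit yields an infinite (worst-case) SSE rather
    than an exception, so profile scans stay total.
    """
    df = dataset.records
    if df["wavelength_nm"].nunique() < 3:
        raise NonIdentifiableError("need >= 3 wavelengths to profile λmax")
    eff = effective_flux(
        df["log_intensity"].to_numpy(),
        df["wavelength_nm"].to_numpy(),
        candidate_lambda_max,
    )
    y = df["response"].to_numpy(dtype=float)
    fit = fit_irc(eff, y, p0=p0)
    if not fit.ok:
        return PooledObjective(sse=float("inf"), r_squared=0.0, fit=fit)
    sse = float(np.sum((y - fit.predict(eff)) ** 2))
    return PooledObjective(sse=sse, r_squared=fit.r_squared, fit=fit)


@dataclass(frozen=True)
class LambdaMaxEstimate:
    """λmax point estimate with optional bootstrap SE and objective profile."""

    lambda_max: float
    se: float
    n_boot: int
    objective_profile: pd.DataFrame  # columns: candidate_nm, sse, r_squared
    shared_fit: SigmoidFit
    search_range: tuple[float, float]
    bootstrap_values: tuple[float, ...] = ()
    n_failures: int = 0

    def report(self) -> str:
        """Human-readable "λmax ± SE" string, e.g. ``480.0 ± 1.1 nm``."""
        if self.n_boot > 0 and np.isfinite(self.se):
            return f"{self.lambda_max:.1f} ± {self.se:.1f} nm"
        return f"{self.lambda_max:.1f} nm"


def default_search_range(dataset: ResponseDataset) -> tuple[float, float]:
    """400-600 nm, widened to 330-550 nm when UV stimuli (<400 nm) exist."""
    if float(dataset.wavelengths.min()) < 400.0:
        return (330.0, 550.0)
    return (400.0, 600.0)


def _profile(
    dataset: ResponseDataset,
    candidates: np.ndarray,
    p0=None,
) -> pd.DataFrame:
    rows = []
    warm = p0
    for cand in candidates:
        obj = pooled_fit_objective(dataset, float(cand), p0=warm)
        if obj.fit.ok:
            warm = (obj.fit.lower, obj.fit.upper, obj.fit.log_ec50,
                    obj.fit.hill_slope)
        rows.append((float(cand), obj.sse, obj.r_squared))
    return pd.DataFrame(rows, columns=["candidate_nm", "sse", "r_squared"])


def estimate_lambda_max(
    dataset: ResponseDataset,
    search_range: tuple[float, float] | None = None,
    grid_step: float = 1.0,
    _fast_p0: tuple[float, float, float, float] | None = None,
) -> LambdaMaxEstimate:
    """Grid-then-refine λmax estimate (no bootstrap SE).

    Scans a 1-nm candidate grid over ``search_range`` (defaulting per
    :func:`default_search_range`), then refines around the grid minimum with
    a bounded scalar optimisation.  Grid ties break toward the lower λmax.
    Deterministic given the data.
    """
    if search_range is None:
        search_range = default_search_range(dataset)
    lo, hi = float(search_range[0]), float(search_range[1])
    if not lo < hi:
        raise ValueError("search_range must be an increasing interval")
    candidates = np.arange(lo, hi + grid_step / 2, grid_step)
    profile = _profile(dataset, candidates, p0=_fast_p0)

    sse = profile["sse"].to_numpy()
    finite = np.isfinite(sse)
    if not finite.any():
        raise NonIdentifiableError("shared fit failed at every candidate λmax")
    spread = np.nanmax(sse[finite]) - np.nanmin(sse[finite])
    if spread <= 1e-9 * max(1.0, np.nanmin(sse[finite])):
        raise NonIdentifiableError(
            "objective profile is flat over the search range; "
            "λmax is not identifiable from these data"
        )
    best_idx = int(np.argmin(np.where(finite, sse, np.inf)))
    best_grid = float(profile["candidate_nm"].iloc[best_idx])

    warm = None
    best_fit_obj = pooled_fit_objective(dataset, best_grid, p0=_fast_p0)
    if best_fit_obj.fit.ok:
        warm = (best_fit_obj.fit.lower, best_fit_obj.fit.upper,
                best_fit_obj.fit.log_ec50, best_fit_obj.fit.hill_slope)

    ref_lo = max(lo, best_grid - grid_step)
    ref_hi = min(hi, best_grid + grid_step)
    res = minimize_scalar(
        lambda lm: pooled_fit_objective(dataset, lm, p0=warm).sse,
        bounds=(ref_lo, ref_hi), method="bounded",
        options={"xatol": 1e-3},
    )
    best = float(res.x) if res.fun <= best_fit_obj.sse else best_grid
    final = pooled_fit_objective(dataset, best, p0=warm)
    return LambdaMaxEstimate(
        lambda_max=best,
        se=float("nan"),
        n_boot=0,
        objective_profile=profile,
        shared_fit=final.fit,
        search_range=(lo, hi),
    )


def bootstrap_lambda_max(
    dataset: ResponseDataset,
    n_boot: int = 200,
    seed: int = 0,
    search_range: tuple[float, float] | None = None,
    window: float = 20.0,
    max_failure_fraction: float = 0.1,
) -> LambdaMaxEstimate:
    """λmax estimate with bootstrap SE.

    Records are resampled with replacement *within* each (wavelength,
    intensity) stimulus cell, preserving the experimental design; each
    resample is re-estimated over a ±``window`` nm grid around the full-data
    point estimate (clipped to the search range).  The SE is the standard
    deviation of the bootstrap λmax distribution.  Resample failures are
    counted; more than ``max_failure_fraction`` of them raises.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = estimate_lambda_max(dataset, search_range=search_range)
    lo, hi = point.search_range
    blo = max(lo, point.lambda_max - window)
    bhi = min(hi, point.lambda_max + window)
    warm = None
    if point.shared_fit.ok:
        warm = (point.shared_fit.lower, point.shared_fit.upper,
                point.shared_fit.log_ec50, point.shared_fit.hill_slope)

    rng = np.random.default_rng(seed)
    df = dataset.records
    cells = [idx.to_numpy() for _, idx in
             df.groupby(["wavelength_nm", "log_intensity"]).groups.items()]
    values: list[float] = []
    failures = 0
    for _ in range(n_boot):
        take = np.concatenate([
            cell[rng.integers(0, len(cell), size=len(cell))] for cell in cells
        ])
        boot = ResponseDataset(records=df.loc[take].reset_index(drop=True),
                               metadata=dict(dataset.metadata))
        try:
            est = estimate_lambda_max(
                boot, search_range=(blo, bhi), _fast_p0=warm
            )
            values.append(est.lambda_max)
        except NonIdentifiableError:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise NonIdentifiableError(
            f"{failures}/{n_boot} bootstrap resamples failed to converge"
        )
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return LambdaMaxEstimate(
        lambda_max=point.lambda_max,
        se=se,
        n_boot=n_boot,
        objective_profile=point.objective_profile,
        shared_fit=point.shared_fit,
        search_range=point.search_range,
        bootstrap_values=tuple(values),
        n_failures=failures,
    )
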