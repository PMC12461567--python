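"""Govardovskii A1 visual-pigment spectral templates.

The spectral sensitivity of an opsin photopigment with an A1 (11-cis retinal)
chromophore is well described by an empirical template fully parameterised by
its wavelength of peak sensitivity, ``lambda_max``.  The template is the sum
of two bands:

* the **α-band**, the main absorbance peak, a function of the normalised
  wavenumber ``x = lambda_max / wavelength``;
* the **β-band**, a smaller Gaussian-shaped short-wavelength shoulder whose
  position and width scale linearly with ``lambda_max``.

Mixtures of up to two templates (convex weights) model pigments that exist as
a pool of spectrally distinct states, e.g. protonated vs. deprotonated
Schiff-base forms of the same opsin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemplateConstants",
    "GovardovskiiTemplate",
    "TemplateMixture",
    "A1_CONSTANTS",
    "tabulate_template",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class TemplateConstants:
    """Constants of the A1 pigment template.

    ``A``–``D`` parameterise the α-band; ``a_base``/``a_scale``/``a_denom``/
    ``a_offset`` define the λmax-dependent steepness term ``a``; the remaining
    fields define the β-band amplitude, peak position and width.
    """

    A: float = 69.7
    a_base: float = 0.8795
    a_scale: float = 0.0459
    a_denom: float = 11940.0  # nm^2
    a_offset: float = 300.0  # nm
    B: float = 28.0
    b_alpha: float = 0.922
    C: float = -14.9
    c: float = 1.104
    D: float = 0.674
    A_beta: float = 0.26
    lam_mbeta_intercept: float = 189.0  # nm
    lam_mbeta_slope: float = 0.315
    b_beta_intercept: float = -40.5  # nm
    b_beta_slope: float = 0.195


A1_CONSTANTS = TemplateConstants()


def _check_wavelength(wavelength) -> np.ndarray:
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0.0):
        raise ValueError("wavelength must be positive (nm)")
    return wl


@dataclass(frozen=True)
class GovardovskiiTemplate:
    """A1 pigment template at a given peak wavelength ``lambda_max`` (nm)."""

    lambda_max: float
    constants: TemplateConstants = field(default=A1_CONSTANTS)

    def __post_init__(self) -> None:
        if not (300.0 <= self.lambda_max <= 700.0):
            raise ValueError(
                f"lambda_max must lie in [300, 700] nm, got {self.lambda_max}"
            )

    # -- α-band -----------------------------------------------------------
    @property
    def alpha_a(self) -> float:
        """λmax-dependent steepness constant ``a`` of the α-band."""
        k = self.constants
        return k.a_base + k.a_scale * np.exp(
            -((self.lambda_max - k.a_offset) ** 2) / k.a_denom
        )

    def alpha_band(self, wavelength) -> np.ndarray | float:
        """α-band relative sensitivity at ``wavelength`` (nm)."""
        wl = _check_wavelength(wavelength)
        k = self.constants
        x = self.lambda_max / wl
        a = self.alpha_a
        denom = (
            np.exp(k.A * (a - x))
            + np.exp(k.B * (k.b_alpha - x))
            + np.exp(k.C * (k.c - x))
            + k.D
        )
        out = 1.0 / denom
        return out if out.ndim else float(out)

    # -- β-band -----------------------------------------------------------
    @property
    def beta_peak(self) -> float:
        """β-band peak wavelength λmβ (nm)."""
        k = self.constants
        return k.lam_mbeta_intercept + k.lam_mbeta_slope * self.lambda_max

    @property
    def beta_width(self) -> float:
        """β-band bandwidth parameter ``b`` (nm)."""
        k = self.constants
        return k.b_beta_intercept + k.b_beta_slope * self.lambda_max

    def beta_band(self, wavelength) -> np.ndarray | float:
        """β-band relative sensitivity at ``wavelength`` (nm)."""
        wl = _check_wavelength(wavelength)
        k = self.constants
        out = k.A_beta * np.exp(-(((wl - self.beta_peak) / self.beta_width) ** 2))
        return out if out.ndim else float(out)

    # -- total ------------------------------------------------------------
    def sensitivity(self, wavelength) -> np.ndarray | float:
        """Total relative sensitivity: α-band + β-band.

        The raw formula value is used (≈1.001 at the peak); the template is
        not renormalised to exactly 1.
        """
        wl = _check_wavelength(wavelength)
        out = np.asarray(self.alpha_band(wl)) + np.asarray(self.beta_band(wl))
        return out if out.ndim else float(out)

    def peak_wavelength(self, grid_start: float = 300.0, grid_stop: float = 750.0,
                        grid_step: float = 1.0) -> float:
        """Argmax of the template over a regular wavelength grid (nm)."""
        grid = np.arange(grid_start, grid_stop + grid_step / 2, grid_step)
        return float(grid[int(np.argmax(self.sensitivity(grid)))])


@dataclass(frozen=True)
class TemplateMixture:
    """Convex mixture of one or two A1 templates.

    ``components`` is a sequence of ``(lambda_max, weight)`` pairs; weights
    must be non-negative and sum to 1.
    """

    components: tuple[tuple[float, float], ...]
    constants: TemplateConstants = field(default=A1_CONSTANTS)

    def __post_init__(self) -> None:
        comps = tuple((float(l), float(w)) for l, w in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError("mixture must have 1 or 2 components")
        weights = np.array([w for _, w in comps])
        if np.any(weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"mixture weights must sum to 1, got {weights.sum():.12g}"
            )
        # constructing templates validates each lambda_max
        for l, _ in comps:
            GovardovskiiTemplate(l, self.constants)

    @classmethod
    def single(cls, lambda_max: float) -> "TemplateMixture":
        return cls(((float(lambda_max), 1.0),))

    @property
    def templates(self) -> tuple[GovardovskiiTemplate, ...]:
        return tuple(
            GovardovskiiTemplate(l, self.constants) for l, _ in self.components
        )

    def sensitivity(self, wavelength) -> np.ndarray | float:
        """Weighted sum of component template sensitivities."""
        wl = _check_wavelength(wavelength)
        out = sum(
            w * np.asarray(t.sensitivity(wl))
            for t, (_, w) in zip(self.templates, self.components)
        )
        out = np.asarray(out)
        return out if out.ndim else float(out)


def tabulate_template(
    template: GovardovskiiTemplate | TemplateMixture,
    wavelengths: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Tabulate a template (or mixture) as (wavelength_nm, sensitivity) rows."""
    if wavelengths is None:
        wavelengths = np.arange(300.0, 751.0, 1.0)
    wl = np.asarray(list(wavelengths), dtype=float)
    return pd.DataFrame(
        {"wavelength_nm": wl, "sensitivity": np.asarray(template.sensitivity(wl))}
    )
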