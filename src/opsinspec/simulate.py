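"""Synthetic photoresponse datasets for heterologous action spectroscopy.

Emulates the statistical structure of a bioluminescent calcium-reporter assay:
cells expressing an opsin are stimulated with 1-s monochromatic pulses over a
grid of wavelengths and intensities, and the peak fold-change response is
recorded per replicate well.  The generative model is a four-parameter
sigmoid in *effective* photon flux — stimulus flux scaled by the pigment's
template sensitivity at the stimulus wavelength — with multiplicative
log-normal noise on the positive, right-skewed fold-change responses.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .templates import TemplateMixture

__all__ = [
    "StimulusProtocol",
    "PhotoresponseModel",
    "ResponseDataset",
    "default_protocol",
    "simulate_responses",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = ("wavelength_nm", "log_intensity", "replicate", "response")


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus design: wavelengths (nm) and per-wavelength intensity grids.

    Intensities are log10 total photon flux (photons cm^-2 s^-1).
    """

    wavelengths: tuple[float, ...]
    intensity_grid: dict[float, tuple[float, ...]]
    pulse_duration_s: float = 1.0

    def __post_init__(self) -> None:
        wls = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wls)
        if len(set(wls)) != len(wls):
            raise ValueError("wavelengths must be distinct")
        if any(not (300.0 <= w <= 750.0) for w in wls):
            raise ValueError("wavelengths must lie within 300-750 nm")
        grid = {float(w): tuple(float(i) for i in g)
                for w, g in self.intensity_grid.items()}
        object.__setattr__(self, "intensity_grid", grid)
        for w in wls:
            g = grid.get(w, ())
            if not g:
                raise ValueError(f"empty intensity grid for {w} nm")
            if list(g) != sorted(g):
                raise ValueError(f"intensity grid for {w} nm must be ascending")


@dataclass(frozen=True)
class PhotoresponseModel:
    """Generative model of peak fold-change responses.

    ``truth`` is the pigment's template mixture; the response to a stimulus of
    log effective flux E follows a four-parameter sigmoid between
    ``response_floor`` and ``response_ceiling`` with midpoint
    ``log_ec50_eff`` and slope ``hill_slope``.  ``noise_sd`` is the standard
    deviation of Gaussian noise on log responses (``noise="lognormal"``) or of
    additive Gaussian noise (``noise="additive"``).
    """

    truth: TemplateMixture
    response_floor: float = 1.0
    response_ceiling: float = 9.0
    log_ec50_eff: float = 13.5
    hill_slope: float = 1.0
    noise_sd: float = 0.05
    n_replicates: int = 4
    noise: str = "lognormal"

    def __post_init__(self) -> None:
        if self.response_ceiling <= self.response_floor:
            raise ValueError("response_ceiling must exceed response_floor")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise not in ("lognormal", "additive"):
            raise ValueError("noise must be 'lognormal' or 'additive'")

    def mean_response(self, wavelength, log_intensity) -> np.ndarray:
        """Noise-free mean response at (wavelength nm, log10 photon flux)."""
        wl = np.asarray(wavelength, dtype=float)
        logi = np.asarray(log_intensity, dtype=float)
        eff = logi + np.log10(np.asarray(self.truth.sensitivity(wl)))
        span = self.response_ceiling - self.response_floor
        return self.response_floor + span / (
            1.0 + 10.0 ** (self.hill_slope * (self.log_ec50_eff - eff))
        )


@dataclass(frozen=True)
class ResponseDataset:
    """Peak-response records plus provenance metadata.

    ``records`` has columns wavelength_nm, log_intensity, replicate, response.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (df["response"] < 0).any():
            raise ValueError("responses must be non-negative")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @property
    def wavelengths(self) -> np.ndarray:
        return np.sort(self.records["wavelength_nm"].unique())

    def at_wavelength(self, wavelength: float) -> pd.DataFrame:
        return self.records[self.records["wavelength_nm"] == wavelength]

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, ResponseDataset):
            return NotImplemented
        return self.records.equals(other.records) and self.metadata == other.metadata


def default_protocol(kind: str = "standard") -> StimulusProtocol:
    """Stimulus protocols of the assay.

    ``standard``: 6 wavelengths (435/460/470/490/500/525 nm), 11-16 log
    photons cm^-2 s^-1 in 0.5-log steps.  ``uv_shifted``: 5 wavelengths
    (365/385/405/435/490 nm), 12-17 log in 0.5-log steps.  Pulses are 1 s.
    """
    if kind == "standard":
        wavelengths = (435.0, 460.0, 470.0, 490.0, 500.0, 525.0)
        lo, hi = 11.0, 16.0
    elif kind == "uv_shifted":
        wavelengths = (365.0, 385.0, 405.0, 435.0, 490.0)
        lo, hi = 12.0, 17.0
    else:
        raise ValueError(f"unknown protocol kind: {kind!r}")
    grid = tuple(np.arange(lo, hi + 0.25, 0.5))
    return StimulusProtocol(
        wavelengths=wavelengths,
        intensity_grid={w: grid for w in wavelengths},
        pulse_duration_s=1.0,
    )


def simulate_responses(
    protocol: StimulusProtocol,
    model: PhotoresponseModel,
    seed: int,
) -> ResponseDataset:
    """Simulate a full-factorial dataset under ``protocol`` and ``model``.

    Deterministic for a given seed: identical seeds give identical datasets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for wl in protocol.wavelengths:
        for logi in protocol.intensity_grid[wl]:
            mean = float(model.mean_response(wl, logi))
            for rep in range(model.n_replicates):
                if model.noise_sd == 0.0:
                    resp = mean
                elif model.noise == "lognormal":
                    resp = mean * float(np.exp(rng.normal(0.0, model.noise_sd)))
                else:
                    resp = max(0.0, mean + float(rng.normal(0.0, model.noise_sd)))
                rows.append((wl, logi, rep, resp))
    records = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    meta = {
        "protocol": {
            "wavelengths": list(protocol.wavelengths),
            "intensity_grid": {str(w): list(g)
                               for w, g in protocol.intensity_grid.items()},
            "pulse_duration_s": protocol.pulse_duration_s,
        },
        "model": {
            "truth": [list(c) for c in model.truth.components],
            "response_floor": model.response_floor,
            "response_ceiling": model.response_ceiling,
            "log_ec50_eff": model.log_ec50_eff,
            "hill_slope": model.hill_slope,
            "noise_sd": model.noise_sd,
            "n_replicates": model.n_replicates,
            "noise": model.noise,
        },
        "seed": int(seed),
    }
    return ResponseDataset(records=records, metadata=meta)


def write_dataset(dataset: ResponseDataset, path) -> None:
    """Write a dataset as CSV with '#'-prefixed JSON metadata lines."""
    with open(path, "w") as fh:
        for key, value in dataset.metadata.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        dataset.records.to_csv(fh, index=False)


def read_dataset(path) -> ResponseDataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Tolerates blank lines and extra whitespace; raises a parse error naming
    the offending line or missing column.
    """
    metadata: dict = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                payload = line.lstrip("#").strip()
                if "=" in payload:
                    key, _, value = payload.partition("=")
                    try:
                        metadata[key.strip()] = json.loads(value.strip())
                    except json.JSONDecodeError:
                        metadata[key.strip()] = value.strip()
                continue
            body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: no data rows found")
    try:
        records = pd.read_csv(io.StringIO("\n".join(body_lines)),
                              skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: malformed CSV body: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records = records[list(DATASET_COLUMNS)].astype(
        {"wavelength_nm": float, "log_intensity": float,
         "replicate": int, "response": float}
    )
    return ResponseDataset(records=records, metadata=metadata)
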