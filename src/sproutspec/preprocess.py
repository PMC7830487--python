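"""Spectral pretreatment: Savitzky-Golay smoothing and standard normal
variate, applied after wavelength-window truncation.

Order is fixed to truncate -> SG -> SNV. SG edge samples are obtained by
evaluating the local least-squares polynomial fitted on the one-sided
neighbourhood (scipy's ``mode="interp"``), which keeps the filter exact
on polynomials up to the fitted order at every point, edges included.
SNV uses the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DegenerateSpectrumError
from .spectra import SpectraSet, WavelengthWindow, truncate


@dataclass
class PreprocessConfig:
    sg_window: int = 15
    sg_polyorder: int = 2
    sg_derivative: int = 0
    apply_snv: bool = True
    window: WavelengthWindow | None = None

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                f"sg_window must be odd and > sg_polyorder "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        if self.sg_derivative > self.sg_polyorder:
            raise ConfigError("sg_derivative must be <= sg_polyorder")

    def to_dict(self) -> dict:
        d = {
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_derivative": self.sg_derivative,
            "snv": self.apply_snv,
        }
        if self.window is not None:
            d["window_lo_nm"] = self.window.lo_nm
            d["window_hi_nm"] = self.window.hi_nm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        window = None
        if "window_lo_nm" in d and "window_hi_nm" in d:
            window = WavelengthWindow(float(d["window_lo_nm"]), float(d["window_hi_nm"]))
        return cls(
            sg_window=int(d.get("sg_window", 15)),
            sg_polyorder=int(d.get("sg_polyorder", 2)),
            sg_derivative=int(d.get("sg_derivative", 0)),
            apply_snv=bool(d.get("snv", True)),
            window=window,
        )


def savgol_smooth(
    spectra: SpectraSet, window: int = 15, polyorder: int = 2, derivative: int = 0
) -> SpectraSet:
    """Savitzky-Golay filter each row along the wavelength axis.

    The grid is assumed uniform; non-uniform grids are filtered in index
    space (documented caveat).
    """
    if window >= spectra.n_wavelengths:
        raise ConfigError(
            f"SG window ({window} points) must be smaller than the spectrum "
            f"length ({spectra.n_wavelengths})"
        )
    step = float(np.median(np.diff(spectra.wavelengths))) if derivative else 1.0
    smoothed = savgol_filter(
        spectra.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=derivative,
        delta=step,
        axis=1,
        mode="interp",
    )
    return spectra.with_absorbance(smoothed, f"savgol[{window},{polyorder},d{derivative}]")


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row centring and scaling to unit
    sample standard deviation (divisor n-1)."""
    x = spectra.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        sid = spectra.meta["sample_id"].iloc[zero[0]] if "sample_id" in spectra.meta else zero[0]
        raise DegenerateSpectrumError(
            f"constant spectrum (zero variance) for sample {sid!r}; SNV undefined"
        )
    return spectra.with_absorbance((x - mu) / sd, "snv")


def preprocess_pipeline(
    spectra: SpectraSet, cfg: PreprocessConfig | None = None
) -> SpectraSet:
    """truncate -> SG -> SNV, returning a new set carrying a provenance
    record of the steps applied."""
    cfg = cfg or PreprocessConfig()
    out = spectra
    if cfg.window is not None:
        out = truncate(out, cfg.window)
    out = savgol_smooth(out, cfg.sg_window, cfg.sg_polyorder, cfg.sg_derivative)
    if cfg.apply_snv:
        out = snv(out)
    return out
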