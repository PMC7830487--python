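"""Seeded synthetic-data generators.

The generators emulate the statistical structure of the sprouting study
design: 21 germination-time classes (0-120 h, 6 h steps) scanned in
triplicate with five consecutive scans each; a six-point ascorbic acid
standard series (0-500 mg/L) in triplicate with three scans; and raw
quality triplicates drawn around the published summary anchors.

Spectra are sums of Gaussian water bands whose amplitudes drift linearly
with germination time (free water fading, strongly bound water growing),
plus Beer-Lambert analyte bands, a per-spectrum multiplicative scatter
factor, a random baseline offset and iid noise. Band shapes, widths and
slopes are simulation tuning constants, not measured facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigError
from .spectra import SpectraSet

#: mg/100 g of bean -> mg/L of extract under the nominal 100 g : 200 mL recipe
_MG100G_TO_MGL = 5.0


@dataclass
class GaussianBand:
    center_nm: float
    width_nm: float
    base_amplitude: float = 1.0
    slope_per_h: float = 0.0

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2)

    def amplitude(self, t_h: float) -> float:
        return self.base_amplitude + self.slope_per_h * t_h


DEFAULT_WATER_BANDS = (
    GaussianBand(1412.0, 18.0, 0.60, -0.0012),  # free water, fading
    GaussianBand(1452.0, 14.0, 0.45, +0.0004),  # solvation shell
    GaussianBand(1512.0, 16.0, 0.30, +0.0018),  # strongly bound, growing
    GaussianBand(1380.0, 12.0, 0.25, -0.0004),  # overtone shoulder
)

DEFAULT_ANALYTE_BANDS = (
    GaussianBand(1414.0, 10.0),
    GaussianBand(1477.0, 10.0),
    GaussianBand(1503.0, 10.0),
)


@dataclass
class SpectraSimConfig:
    grid_lo_nm: float = 900.0
    grid_hi_nm: float = 1700.0
    grid_step_nm: float = 2.0
    classes_h: tuple = tuple(range(0, 121, 6))
    n_replicates: int = 3
    n_scans: int = 5
    water_bands: tuple = DEFAULT_WATER_BANDS
    analyte_bands: tuple = DEFAULT_ANALYTE_BANDS
    analyte_response_per_mg_l: float = 4e-4  # AU at band peak per mg/L
    scatter_cv: float = 0.01  # lognormal multiplicative scatter
    baseline_sd: float = 0.005  # AU, per-spectrum offset
    noise_sd: float = 0.002  # AU, iid per point
    water_noise_sd: float = 0.2  # % water content, per replicate
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_hi_nm - self.grid_lo_nm) / self.grid_step_nm)) + 1
        return self.grid_lo_nm + self.grid_step_nm * np.arange(n)

    def validate(self) -> None:
        wl = self.wavelengths()
        for b in self.water_bands + self.analyte_bands:
            if not (wl[0] <= b.center_nm <= wl[-1]):
                raise ConfigError(f"band center {b.center_nm} nm outside the grid")
        for b in self.water_bands:
            for t in (min(self.classes_h), max(self.classes_h)):
                if b.amplitude(t) < 0:
                    raise ConfigError(
                        f"band at {b.center_nm} nm has negative amplitude at t={t} h"
                    )


@dataclass
class QualitySimConfig:
    n_per_time: int = 3
    seed: int = 0
    sd_override: float | None = None  # set 0 to emit exact anchor means


def _water_matrix(cfg: SpectraSimConfig, wl: np.ndarray, t_h: float) -> np.ndarray:
    out = np.zeros_like(wl)
    for b in cfg.water_bands:
        out += b.amplitude(t_h) * b.profile(wl)
    return out


def _analyte_profile(cfg: SpectraSimConfig, wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl)
    for b in cfg.analyte_bands:
        out += b.profile(wl)
    return out


def _noisy_spectrum(
    clean: np.ndarray, rng: np.random.Generator, cfg: SpectraSimConfig
) -> np.ndarray:
    scatter = float(np.exp(rng.normal(0.0, cfg.scatter_cv)))
    baseline = rng.normal(0.0, cfg.baseline_sd)
    noise = rng.normal(0.0, cfg.noise_sd, size=clean.size)
    return clean * scatter + baseline + noise


def simulate_extract_spectra(
    cfg: SpectraSimConfig | None = None,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Synthetic bean-extract spectra across germination times.

    Returns the SpectraSet (one row per scan, 21 x 3 x 5 = 315 at the
    defaults) and a per-row ground-truth frame with the true water
    content (%, per replicate, anchored to the published trajectory) and
    the true ascorbic acid level (mg/100 g, interpolated through the
    published titration means).
    """
    cfg = cfg or SpectraSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths()
    analyte_profile = _analyte_profile(cfg, wl)
    times = np.asarray(cfg.classes_h, dtype=float)
    asc_mg100g = reference.ascorbic_trajectory_mg_per_100g(times)
    water_mean = reference.water_pct_trajectory(times)

    rows, meta, truth = [], [], []
    for i, t in enumerate(times):
        conc_mg_l = asc_mg100g[i] * _MG100G_TO_MGL
        clean = (
            _water_matrix(cfg, wl, t)
            + cfg.analyte_response_per_mg_l * conc_mg_l * analyte_profile
        )
        sid = f"extract_{int(t):03d}h"
        for rep in range(1, cfg.n_replicates + 1):
            water_rep = water_mean[i] + rng.normal(0.0, cfg.water_noise_sd)
            for scan in range(1, cfg.n_scans + 1):
                rows.append(_noisy_spectrum(clean, rng, cfg))
                meta.append(
                    {
                        "sample_id": sid,
                        "germination_h": int(t),
                        "replicate": rep,
                        "scan": scan,
                        "mode": "transmission",
                    }
                )
                truth.append(
                    {
                        "sample_id": sid,
                        "germination_h": int(t),
                        "replicate": rep,
                        "scan": scan,
                        "water_pct": water_rep,
                        "ascorbic_mg_per_100g": asc_mg100g[i],
                        "ascorbic_mg_per_l": conc_mg_l,
                    }
                )
    spectra = SpectraSet(wl, np.vstack(rows), pd.DataFrame(meta), ["simulate[extract]"])
    return spectra, pd.DataFrame(truth)


def simulate_standard_curve(
    cfg: SpectraSimConfig | None = None,
    concentrations_mg_l: tuple = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0),
    n_replicates: int = 3,
    n_scans: int = 3,
) -> SpectraSet:
    """Synthetic ascorbic standard-solution spectra.

    Water bands are held at their base amplitudes (no time drift); the
    analyte response is linear in concentration. 6 levels x 3 replicates
    x 3 scans = 54 rows at the defaults.
    """
    cfg = cfg or SpectraSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths()
    water = _water_matrix(cfg, wl, 0.0)
    analyte_profile = _analyte_profile(cfg, wl)
    rows, meta = [], []
    for conc in concentrations_mg_l:
        clean = water + cfg.analyte_response_per_mg_l * conc * analyte_profile
        sid = f"standard_{int(conc):03d}mgL"
        for rep in range(1, n_replicates + 1):
            for scan in range(1, n_scans + 1):
                rows.append(_noisy_spectrum(clean, rng, cfg))
                meta.append(
                    {
                        "sample_id": sid,
                        "germination_h": np.nan,
                        "replicate": rep,
                        "scan": scan,
                        "mode": "transmission",
                        "analyte_conc": float(conc),
                    }
                )
    return SpectraSet(wl, np.vstack(rows), pd.DataFrame(meta), ["simulate[standard]"])


def simulate_quality_table(cfg: QualitySimConfig | None = None) -> pd.DataFrame:
    """Raw triplicates per germination time for the quality variables.

    Each cell draws n values from Normal(anchor mean, anchor sd).
    Ascorbic values exist only at the 24 h anchor times; other rows carry
    NaN there.
    """
    cfg = cfg or QualitySimConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    asc = reference.ASCORBIC_TITRATION_SUMMARY
    for t in sorted(reference.QUALITY_SUMMARY):
        (wm, ws), (pm, ps), (cm, cs) = reference.QUALITY_SUMMARY[t]
        if cfg.sd_override is not None:
            ws = ps = cs = cfg.sd_override
        water = rng.normal(wm, ws, cfg.n_per_time)
        ph = rng.normal(pm, ps, cfg.n_per_time)
        cond = rng.normal(cm, cs, cfg.n_per_time)
        if t in asc:
            am, asd = asc[t]
            if cfg.sd_override is not None:
                asd = cfg.sd_override
            ascv = rng.normal(am, asd, cfg.n_per_time)
        else:
            ascv = [np.nan] * cfg.n_per_time
        for r in range(cfg.n_per_time):
            rows.append(
                {
                    "germination_h": t,
                    "replicate": r + 1,
                    "water_pct": water[r],
                    "ph": ph[r],
                    "conductivity": cond[r],
                    "ascorbic_mg_per_100g": ascv[r],
                }
            )
    return pd.DataFrame(rows)
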