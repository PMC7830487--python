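"""Water-band bookkeeping and aquagram computation.

The first overtone of the O-H stretch (1300-1600 nm) is partitioned into
12 characteristic coordinates (C1-C12), each describing a water species
from free to strongly hydrogen-bonded. An aquagram reports, per group,
the mean of the per-sample standardized absorbance at each coordinate's
display wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateBandError
from .spectra import SpectraSet

# (id, lo_nm, hi_nm, display_nm, species) — ranges follow the classical
# first-overtone coordinate framework; fully configurable.
_DEFAULT_COORDS = [
    ("C1", 1336.0, 1348.0, 1344.0, "hydroxylated water / v3 asymmetric stretch"),
    ("C2", 1360.0, 1366.0, 1364.0, "water solvation shell"),
    ("C3", 1370.0, 1376.0, 1374.0, "trapped water / proton hydrates"),
    ("C4", 1380.0, 1388.0, 1384.0, "water solvation shell / superoxide hydrates"),
    ("C5", 1398.0, 1418.0, 1412.0, "free water / S0 no hydrogen bond"),
    ("C6", 1421.0, 1430.0, 1426.0, "water hydration / H-OH bend"),
    ("C7", 1432.0, 1444.0, 1440.0, "water with one hydrogen bond (S1)"),
    ("C8", 1448.0, 1454.0, 1452.0, "water with two hydrogen bonds (S2)"),
    ("C9", 1458.0, 1468.0, 1462.0, "water with three hydrogen bonds (S3)"),
    ("C10", 1472.0, 1482.0, 1476.0, "water with four hydrogen bonds (S4)"),
    ("C11", 1482.0, 1495.0, 1488.0, "strongly bound water / dimers"),
    ("C12", 1506.0, 1516.0, 1512.0, "strongly bound water / solvated ions"),
]


@dataclass(frozen=True)
class WamacCoordinate:
    id: str
    lo_nm: float
    hi_nm: float
    display_nm: float
    species: str

    def contains(self, nm: float) -> bool:
        return self.lo_nm <= nm <= self.hi_nm


@dataclass
class WamacTable:
    coordinates: list[WamacCoordinate]

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for c in self.coordinates:
            if not (1300.0 <= c.lo_nm < c.hi_nm <= 1600.0):
                raise ConfigError(f"{c.id}: range must lie within [1300, 1600] nm")
            if not (c.lo_nm <= c.display_nm <= c.hi_nm):
                raise ConfigError(f"{c.id}: display wavelength outside its range")
            if c.lo_nm < prev_hi:
                raise ConfigError(f"{c.id}: coordinate ranges overlap or are unordered")
            prev_hi = c.hi_nm

    @property
    def display_wavelengths(self) -> list[float]:
        return [c.display_nm for c in self.coordinates]

    def classify(self, nm: float) -> WamacCoordinate | None:
        """Coordinate whose range contains ``nm``, or None."""
        for c in self.coordinates:
            if c.contains(nm):
                return c
        return None

    def with_display_wavelengths(self, display: dict[str, float]) -> "WamacTable":
        """New table with some display wavelengths overridden by id."""
        coords = []
        for c in self.coordinates:
            nm = display.get(c.id, c.display_nm)
            # widen the range minimally if the override falls just outside
            lo, hi = min(c.lo_nm, nm), max(c.hi_nm, nm)
            coords.append(WamacCoordinate(c.id, lo, hi, nm, c.species))
        return WamacTable(coords)


def default_wamac_table() -> WamacTable:
    """The 12 default first-overtone coordinates."""
    return WamacTable([WamacCoordinate(*row) for row in _DEFAULT_COORDS])


@dataclass
class Aquagram:
    groups: list
    display_nm: list[float]
    values: np.ndarray  # (n_groups, n_bands)
    n_per_group: list[int]
    coordinate_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.groups, name="group"), columns=self.display_nm
        )
        df.insert(0, "n", self.n_per_group)
        return df

    def to_long_frame(self) -> pd.DataFrame:
        """Radar-chart-ready long format (group, nm, value)."""
        rows = [
            {"group": g, "nm": nm, "value": self.values[i, j]}
            for i, g in enumerate(self.groups)
            for j, nm in enumerate(self.display_nm)
        ]
        return pd.DataFrame(rows)


def compute_aquagram(
    spectra: SpectraSet, group_key: str, table: WamacTable | None = None
) -> Aquagram:
    """Per-group standardized absorbance at the coordinate display
    wavelengths.

    Each display wavelength is snapped to the nearest grid point; the
    absorbance there is z-scored across all samples (sample sd), and the
    group value is the mean z over the group's members. Groups are
    ordered by the natural order of ``group_key``.
    """
    table = table or default_wamac_table()
    if spectra.n_samples < 2:
        raise DataError("aquagram needs at least 2 samples")
    if group_key not in spectra.meta:
        raise ConfigError(f"metadata column {group_key!r} not present")
    lo, hi = spectra.wavelengths[0], spectra.wavelengths[-1]
    display = table.display_wavelengths
    half_step = float(np.max(np.diff(spectra.wavelengths))) / 2 if spectra.n_wavelengths > 1 else 0.0
    for nm in display:
        if nm < lo - half_step or nm > hi + half_step:
            raise DataError(f"display wavelength {nm} nm outside the spectral grid")
    cols = [spectra.nearest_index(nm) for nm in display]
    A = spectra.absorbance[:, cols]
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise DegenerateBandError(
            f"zero variance across samples at {display[zero[0]]} nm"
        )
    Z = (A - mu) / sd
    keys = spectra.meta[group_key]
    groups = sorted(keys.dropna().unique().tolist())
    values = np.vstack([Z[np.asarray(keys == g)].mean(axis=0) for g in groups])
    n_per_group = [int((keys == g).sum()) for g in groups]
    return Aquagram(
        groups=groups,
        display_nm=display,
        values=values,
        n_per_group=n_per_group,
        coordinate_ids=[c.id for c in table.coordinates],
    )
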