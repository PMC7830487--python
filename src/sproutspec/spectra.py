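"""Spectral data model and I/O.

A :class:`SpectraSet` is a rectangular absorbance matrix (samples x
wavelengths) on a strictly increasing nm grid, with per-sample metadata.
The CSV dialect is wide: metadata columns first, then one column per
wavelength named by its nm value.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DuplicateWavelengthError,
    EmptyWindowError,
    FormatError,
    MetadataConflictError,
    ParseError,
)

META_COLUMNS = ("sample_id", "germination_h", "replicate", "scan", "mode")
OPTIONAL_META = ("analyte_conc",)

#: tolerance used when comparing nm values
NM_TOL = 1e-9


@dataclass(frozen=True)
class WavelengthWindow:
    """Inclusive wavelength interval in nm."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise DataError(
                f"window lower bound {self.lo_nm} must be < upper bound {self.hi_nm}"
            )

    def contains(self, nm: np.ndarray) -> np.ndarray:
        return (nm >= self.lo_nm - NM_TOL) & (nm <= self.hi_nm + NM_TOL)


@dataclass
class SpectraSet:
    """Absorbance matrix with aligned per-sample metadata.

    Parameters
    ----------
    wavelengths : array of float, strictly increasing nm values.
    absorbance : 2-D array, shape (n_samples, n_wavelengths), finite.
    meta : DataFrame with at least ``sample_id``; recognised columns are
        ``germination_h``, ``replicate``, ``scan``, ``mode`` and
        ``analyte_conc``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise DataError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise DataError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise DataError(
                f"non-finite absorbance at row {bad[0]}, wavelength index {bad[1]}"
            )
        d = np.diff(self.wavelengths)
        if np.any(d <= NM_TOL):
            raise DuplicateWavelengthError(
                "wavelengths must be strictly increasing with no duplicates"
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != self.absorbance.shape[0]:
            raise DataError("metadata row count does not match absorbance rows")
        if "germination_h" in self.meta:
            g = self.meta["germination_h"].dropna()
            bad = g[(g % 6 != 0) | (g < 0) | (g > 120)]
            if len(bad):
                raise DataError(
                    f"germination_h must be a multiple of 6 in [0,120]; got {bad.iloc[0]}"
                )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(),
            self.absorbance.copy(),
            self.meta.copy(),
            list(self.provenance),
        )

    def with_absorbance(self, matrix: np.ndarray, step: str | None = None) -> "SpectraSet":
        """Return a new set with the same grid/metadata and new values."""
        prov = list(self.provenance) + ([step] if step else [])
        return SpectraSet(self.wavelengths.copy(), matrix, self.meta.copy(), prov)

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - nm)))


# ----------------------------------------------------------------------
# CSV I/O


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide-format spectra CSV.

    Header must start with ``sample_id, germination_h, replicate, scan,
    mode`` (``analyte_conc`` optional), followed by wavelength columns
    named by their nm value. Wavelength columns are sorted ascending.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    header = next(csv.reader(io.StringIO(text)), [])
    raw_wl = [c for c in header if c not in META_COLUMNS + OPTIONAL_META]
    seen: set[float] = set()
    for c in raw_wl:
        try:
            v = float(c)
        except ValueError:
            continue
        if v in seen:
            raise DuplicateWavelengthError(f"duplicate wavelength column {c!r}")
        seen.add(v)
    try:
        df = pd.read_csv(io.StringIO(text), dtype=str)
    except Exception as exc:  # pragma: no cover - pandas-specific failures
        raise FormatError(f"could not read CSV {path}: {exc}") from exc
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required header columns: {missing}")
    meta_cols = [c for c in META_COLUMNS + OPTIONAL_META if c in df.columns]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    if not wl_cols:
        raise FormatError("no wavelength columns found")
    try:
        nm = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"wavelength column name is not numeric: {exc}") from exc
    order = np.argsort(nm)
    nm_sorted = nm[order]
    if np.any(np.diff(nm_sorted) <= NM_TOL):
        raise DuplicateWavelengthError("duplicate wavelength columns in CSV")

    mat = np.empty((len(df), len(wl_cols)), dtype=float)
    for j, col in enumerate(np.array(wl_cols, dtype=object)[order]):
        try:
            mat[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            vals = pd.to_numeric(df[col], errors="coerce")
            row = int(vals[vals.isna()].index[0]) if vals.isna().any() else -1
            raise ParseError(
                f"non-numeric absorbance in column '{col}', row {row}"
            ) from exc

    meta = df[meta_cols].copy()
    meta["germination_h"] = pd.to_numeric(meta["germination_h"], errors="coerce")
    meta["replicate"] = pd.to_numeric(meta["replicate"], errors="coerce").astype("Int64")
    meta["scan"] = pd.to_numeric(meta["scan"], errors="coerce").astype("Int64")
    if "analyte_conc" in meta:
        meta["analyte_conc"] = pd.to_numeric(meta["analyte_conc"], errors="coerce")
    return SpectraSet(nm_sorted, mat, meta)


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write the wide CSV dialect: wavelengths to 2 decimals, absorbance
    to 9 significant digits."""
    meta = spectra.meta.copy()
    wl_names = [f"{w:.2f}" for w in spectra.wavelengths]
    out = pd.DataFrame(spectra.absorbance, columns=wl_names)
    df = pd.concat([meta, out], axis=1)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.9g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ----------------------------------------------------------------------
# Grid operations


def truncate(spectra: SpectraSet, window: WavelengthWindow) -> SpectraSet:
    """Keep exactly the wavelengths within the inclusive window."""
    mask = window.contains(spectra.wavelengths)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{window.lo_nm}, {window.hi_nm}] nm does not intersect "
            f"grid [{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}] nm"
        )
    prov = list(spectra.provenance) + [
        f"truncate[{window.lo_nm:g},{window.hi_nm:g}]"
    ]
    return SpectraSet(
        spectra.wavelengths[mask], spectra.absorbance[:, mask], spectra.meta.copy(), prov
    )


def aggregate_scans(spectra: SpectraSet, level: str = "scan") -> SpectraSet:
    """Average rows within a group.

    level="scan" averages the consecutive scans within each
    (sample_id, replicate) pair; level="replicate" averages everything
    sharing a sample_id. Metadata that must be constant within a group
    (germination_h, mode, analyte_conc) is checked and carried over.
    """
    if level == "scan":
        keys = ["sample_id", "replicate"]
    elif level == "replicate":
        keys = ["sample_id"]
    else:
        raise DataError(f"unknown aggregation level {level!r}")
    for k in keys:
        if k not in spectra.meta or spectra.meta[k].isna().all():
            raise DataError(f"metadata column {k!r} required for level {level!r}")

    meta = spectra.meta
    rows = []
    metas = []
    # sort=False keeps first-appearance order of groups
    for gkey, idx in meta.groupby(keys, sort=False, dropna=False).groups.items():
        idx = np.asarray(idx)
        sub = meta.loc[idx]
        rec = {}
        for col in ("germination_h", "mode", "analyte_conc"):
            if col in sub:
                vals = sub[col].dropna().unique()
                if len(vals) > 1:
                    raise MetadataConflictError(
                        f"group {gkey} has conflicting values for {col}: {vals}"
                    )
                rec[col] = vals[0] if len(vals) else np.nan
        rec["sample_id"] = sub["sample_id"].iloc[0]
        rec["replicate"] = sub["replicate"].iloc[0] if level == "scan" else 1
        rec["scan"] = 1
        metas.append(rec)
        rows.append(spectra.absorbance[idx].mean(axis=0))
    new_meta = pd.DataFrame(metas)
    cols = [c for c in META_COLUMNS + OPTIONAL_META if c in new_meta.columns]
    prov = list(spectra.provenance) + [f"aggregate[{level}]"]
    return SpectraSet(spectra.wavelengths.copy(), np.vstack(rows), new_meta[cols], prov)
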