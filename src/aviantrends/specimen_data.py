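"""Reading, validation and curation of museum-specimen data.

Specimen metadata arrive as one delimited-text row per specimen (species,
collection year, coordinates, altitude, sex, month, two wing-length
measurements, condition flags); reflectance spectra arrive as plain
two-column wavelength/reflectance text files, five replicate measurements
per plumage patch.  This module parses and validates both, derives the
season (two-month bins) and decade covariates used downstream, applies the
standard specimen exclusions (juvenile, molting, damaged, unsexed), and
quantifies measurement repeatability as the one-way ANOVA intraclass
correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenRecord",
    "ReflectanceSpectrum",
    "MeasurementPair",
    "SpecimenParseError",
    "read_specimen_table",
    "filter_specimens",
    "read_spectrum",
    "clean_and_resample",
    "repeatability",
    "records_to_frame",
    "season_from_month",
    "decade_from_year",
]

#: 1-nm wavelength grid over which all spectra are analysed (nm).
STANDARD_GRID = np.arange(300, 701, dtype=float)

REQUIRED_COLUMNS = (
    "specimen_id",
    "species",
    "year",
    "latitude",
    "longitude",
    "sex",
    "month",
)

FLAG_COLUMNS = ("juvenile", "molting", "damaged", "unsexed")


class SpecimenParseError(ValueError):
    """Raised when a specimen table or spectrum file cannot be parsed."""


def season_from_month(month: int) -> int:
    """Two-month collection season: months 1-2 -> 1, ..., 11-12 -> 6."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return math.ceil(month / 2)


def decade_from_year(year: int) -> int:
    return (year // 10) * 10


@dataclass
class SpecimenRecord:
    """One curated museum specimen.

    ``wing_length`` is the mean of the two raw measurements; the raw pair is
    kept on the record so repeatability can be computed later.  ``season``
    and ``decade`` are derived, never stored in the input table.
    """

    specimen_id: str
    species: str
    year: int
    latitude: float
    longitude: float
    sex: str
    month: int | None
    subspecies: str = ""
    altitude: float | None = None
    wing_first: float | None = None
    wing_second: float | None = None
    juvenile: bool = False
    molting: bool = False
    damaged: bool = False
    unsexed: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2008:
            raise ValueError(
                f"{self.specimen_id}: year {self.year} outside the 1900-2008 study span"
            )
        if self.wing_first is not None and self.wing_first <= 0:
            raise ValueError(f"{self.specimen_id}: non-positive wing measurement")
        if self.wing_second is not None and self.wing_second <= 0:
            raise ValueError(f"{self.specimen_id}: non-positive wing measurement")

    @property
    def season(self) -> int | None:
        """Two-month season of collection, 1..6; None when month is missing."""
        if self.month is None:
            return None
        return season_from_month(self.month)

    @property
    def decade(self) -> int:
        return decade_from_year(self.year)

    @property
    def wing_length(self) -> float | None:
        """Mean of the two wing measurements (mm)."""
        if self.wing_first is None or self.wing_second is None:
            return None
        return 0.5 * (self.wing_first + self.wing_second)


@dataclass(frozen=True)
class MeasurementPair:
    """The two repeated wing measurements of one specimen (mm)."""

    specimen_id: str
    first: float
    second: float

    def __post_init__(self) -> None:
        if self.first <= 0 or self.second <= 0:
            raise ValueError("wing measurements must be positive")


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Percent reflectance R(lambda) on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or wl.shape != rf.shape:
            raise ValueError("wavelengths and reflectance must be 1-d and aligned")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.reflectance)


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "t", "yes", "y"}
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(value)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    out = float(value)
    return None if math.isnan(out) else out


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a delimited specimen table (comma or tab, auto-detected).

    Required columns: ``specimen_id, species, year, latitude, longitude,
    sex, month``.  Optional: ``subspecies, altitude, wing_first,
    wing_second`` and the four condition flags.  Unknown columns are kept in
    ``record.extras``.  A missing required column is a hard error; rows with
    unparseable year or coordinates are collected and reported together.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    table.columns = [c.strip().lower() for c in table.columns]

    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SpecimenParseError(f"required column {col!r} missing from {path}")

    known = set(REQUIRED_COLUMNS) | set(FLAG_COLUMNS) | {
        "subspecies",
        "altitude",
        "wing_first",
        "wing_second",
    }
    extra_cols = [c for c in table.columns if c not in known]

    records: list[SpecimenRecord] = []
    row_errors: list[str] = []
    for idx, row in table.iterrows():
        try:
            month_raw = row["month"].strip()
            rec = SpecimenRecord(
                specimen_id=row["specimen_id"].strip(),
                species=row["species"].strip(),
                year=int(float(row["year"])),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                sex=row["sex"].strip().lower(),
                month=int(float(month_raw)) if month_raw else None,
                subspecies=row.get("subspecies", "").strip(),
                altitude=_opt_float(row["altitude"]) if "altitude" in table.columns else None,
                wing_first=_opt_float(row["wing_first"])
                if "wing_first" in table.columns
                else None,
                wing_second=_opt_float(row["wing_second"])
                if "wing_second" in table.columns
                else None,
                **{
                    flag: _parse_bool(row[flag])
                    for flag in FLAG_COLUMNS
                    if flag in table.columns
                },
                extras={c: row[c] for c in extra_cols},
            )
            if rec.month is None:
                warnings.warn(
                    f"{rec.specimen_id}: month missing; season unavailable",
                    stacklevel=2,
                )
            records.append(rec)
        except (ValueError, TypeError) as exc:
            row_errors.append(f"row {idx + 2}: {exc}")
    if row_errors:
        raise SpecimenParseError(
            f"{len(row_errors)} unparseable row(s) in {path}:\n" + "\n".join(row_errors)
        )
    _impute_missing_altitude(records)
    return records


def _impute_missing_altitude(records: Sequence[SpecimenRecord]) -> None:
    """Impute missing altitude as the species median, with a warning."""
    by_species: dict[str, list[float]] = {}
    for rec in records:
        if rec.altitude is not None:
            by_species.setdefault(rec.species, []).append(rec.altitude)
    n_imputed = 0
    for rec in records:
        if rec.altitude is None and rec.species in by_species:
            rec.altitude = float(np.median(by_species[rec.species]))
            n_imputed += 1
    if n_imputed:
        warnings.warn(
            f"imputed species-median altitude for {n_imputed} specimen(s)",
            stacklevel=3,
        )


def filter_specimens(
    records: Iterable[SpecimenRecord],
) -> tuple[list[SpecimenRecord], dict[str, int]]:
    """Drop juveniles, molting, highly damaged and unsexed specimens.

    Returns the retained records and a per-reason removal count (a record
    flagged for several reasons counts once per reason).
    """
    kept: list[SpecimenRecord] = []
    removed = {flag: 0 for flag in FLAG_COLUMNS}
    for rec in records:
        bad = False
        for flag in FLAG_COLUMNS:
            if getattr(rec, flag):
                removed[flag] += 1
                bad = True
        if not bad:
            kept.append(rec)
    return kept, removed


def read_spectrum(path: str | Path) -> ReflectanceSpectrum:
    """Read a two-column (nm, percent reflectance) text file.

    Rows are sorted by wavelength and exact duplicate wavelengths averaged.
    """
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise SpecimenParseError(f"non-numeric content in spectrum file {path}: {exc}")
    if data.ndim != 2 or data.shape[1] < 2:
        raise SpecimenParseError(f"spectrum file {path} needs two numeric columns")
    wl, rf = data[:, 0], data[:, 1]
    order = np.argsort(wl, kind="stable")
    wl, rf = wl[order], rf[order]
    uniq, inverse = np.unique(wl, return_inverse=True)
    if uniq.size != wl.size:
        rf = np.bincount(inverse, weights=rf) / np.bincount(inverse)
        wl = uniq
    return ReflectanceSpectrum(wl, rf)


def clean_and_resample(
    spectrum: ReflectanceSpectrum, grid: np.ndarray = STANDARD_GRID
) -> ReflectanceSpectrum:
    """Linear interpolation onto the 1-nm grid; negatives clamped to zero.

    Values above 100% are retained: specular glare can push bright patches
    over 100 and clamping both ends would bias them.
    """
    grid = np.asarray(grid, dtype=float)
    if spectrum.wavelengths[0] > grid[0] or spectrum.wavelengths[-1] < grid[-1]:
        raise ValueError(
            f"spectrum covers [{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm "
            f"but the analysis grid needs [{grid[0]}, {grid[-1]}]"
        )
    values = np.clip(spectrum.interp(grid), 0.0, None)
    return ReflectanceSpectrum(grid, values)


def repeatability(pairs: Sequence[MeasurementPair]) -> float:
    """Intraclass correlation of duplicated measurements (one-way ANOVA).

    r = (MS_A - MS_W) / (MS_A + (n0 - 1) MS_W) with n0 = 2 measurements per
    specimen; MS_A is the among-specimen and MS_W the within-specimen mean
    square.  Ranges over [-1, 1]; duplicate columns give exactly 1.
    """
    if len(pairs) < 2:
        raise ValueError("repeatability needs at least two specimens")
    data = np.array([[p.first, p.second] for p in pairs], dtype=float)
    k, n0 = data.shape
    grand = data.mean()
    group_means = data.mean(axis=1)
    ss_among = n0 * np.sum((group_means - grand) ** 2)
    ss_within = np.sum((data - group_means[:, None]) ** 2)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (k * (n0 - 1))
    denom = ms_among + (n0 - 1) * ms_within
    if denom == 0:
        raise ValueError("zero total variance: repeatability undefined")
    return float((ms_among - ms_within) / denom)


def records_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Flatten records to the analysis DataFrame used by temporal_models."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "species": [r.species for r in records],
            "subspecies": [r.subspecies for r in records],
            "year": [r.year for r in records],
            "decade": [r.decade for r in records],
            "month": [r.month for r in records],
            "season": [r.season for r in records],
            "latitude": [r.latitude for r in records],
            "longitude": [r.longitude for r in records],
            "altitude": [r.altitude for r in records],
            "sex": [r.sex for r in records],
            "wing_length": [r.wing_length for r in records],
        }
    )
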