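"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* A tree-ring year is the single calendar year label of the growth layer
  (no Schulman shift; the site is near-equatorial and rings are dated by
  single years).
* Ring widths are stored in millimetres, pith -> bark.  A width of 0.0
  marks a ring that is locally absent on that radius (kept in place so
  year alignment is preserved).
* Radiocarbon activity is expressed as fraction modern carbon (Fm), the
  sample activity normalized to the 1950 atmospheric standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class RingSeries:
    """One measured radius: innermost (pith-side) year plus ordered widths."""

    series_id: str
    first_year: int
    widths: np.ndarray  # mm, pith -> bark

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValueError("widths must be a non-empty 1-D array")
        if np.any(self.widths < 0):
            raise ValueError("ring widths must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class DetrendedSeries:
    """Ratio indices of one radius after growth-curve removal.

    ``ar_order`` / ``ar_coefs`` are filled once the series has been
    prewhitened; a freshly detrended series carries order ``None``.
    """

    series_id: str
    years: np.ndarray
    index: np.ndarray            # dimensionless ratio indices; NaN = missing
    curve: Optional[np.ndarray] = None   # fitted growth curve, mm
    ar_order: Optional[int] = None
    ar_coefs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        if self.years.shape != self.index.shape:
            raise ValueError("years and index must have the same length")


@dataclass
class Chronology:
    """Mean site chronology with quality statistics."""

    years: np.ndarray
    index: np.ndarray
    depth: np.ndarray            # number of radii contributing per year
    rbar: Optional[float] = None
    rbar_between_trees: Optional[float] = None
    eps: Optional[float] = None
    eps_windows: list = field(default_factory=list)  # [(window_start, eps)]
    lag1: Optional[float] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class ClimateSeries:
    """Monthly climate record: one row of 12 values per year."""

    name: str
    units: str
    years: np.ndarray
    monthly: np.ndarray          # shape (n_years, 12); NaN = missing
    station_id: str = ""
    lat: float = float("nan")
    lon: float = float("nan")

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.monthly = np.asarray(self.monthly, dtype=float)
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError(f"{self.name}: duplicated years")
        if self.monthly.shape != (len(self.years), 12):
            raise ValueError(f"{self.name}: monthly matrix must be (n_years, 12)")


@dataclass
class AnnualSeries:
    """A plain annual series (climate index, seasonal aggregate, ...)."""

    name: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")


@dataclass
class GriddedField:
    """Regular lat/lon grid of annual (or seasonal) values."""

    lat: np.ndarray
    lon: np.ndarray
    time: np.ndarray             # years
    values: np.ndarray           # shape (n_lat, n_lon, n_time)
    units: str = ""

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.time = np.asarray(self.time, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        for name, v in (("lat", self.lat), ("lon", self.lon)):
            d = np.diff(v)
            if len(v) > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} coordinates must be strictly monotone")
        if self.values.shape != (len(self.lat), len(self.lon), len(self.time)):
            raise ValueError("value cube dimensions must match coordinates")


@dataclass
class RadiocarbonSample:
    """One ring's Fm measurement with its dendrochronological date.

    ``ring_index`` (position from the pith, 0-based) and ``true_year`` are
    filled by the synthetic generator only; real data carry ``None``.
    """

    tree_id: str
    dendro_year: int
    fm: float
    fm_sd: float
    ring_index: Optional[int] = None
    true_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.fm > 0:
            raise ValueError("fm must be positive")
        if not self.fm_sd > 0:
            raise ValueError("fm_sd must be positive")


@dataclass
class BombCurve:
    """Atmospheric bomb-pulse Fm reference curve (decimal years)."""

    years: np.ndarray
    fm: np.ndarray
    fm_sd: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.fm = np.asarray(self.fm, dtype=float)
        self.fm_sd = np.asarray(self.fm_sd, dtype=float)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("curve time axis must be strictly increasing")
        if np.any(self.fm <= 0):
            raise ValueError("curve fm values must be positive")
        if self.years.shape != self.fm.shape or self.fm.shape != self.fm_sd.shape:
            raise ValueError("years, fm, fm_sd must have equal length")

    def fm_at(self, year) -> np.ndarray:
        """Fm linearly interpolated to ``year`` (scalar or array)."""
        return np.interp(year, self.years, self.fm)

    def sd_at(self, year) -> np.ndarray:
        return np.interp(year, self.years, self.fm_sd)

    @property
    def peak_year(self) -> float:
        return float(self.years[int(np.argmax(self.fm))])

    @property
    def peak_fm(self) -> float:
        return float(np.max(self.fm))

    def plateau_end(self, rel_tol: float = 1e-3) -> float:
        """Last year of the flat pre-bomb plateau.

        The plateau is the initial run of years whose Fm stays within
        ``rel_tol`` (relative) of the first value.
        """
        base = self.fm[0]
        off = np.nonzero(np.abs(self.fm - base) > rel_tol * base)[0]
        if len(off) == 0:
            return float(self.years[-1])
        return float(self.years[off[0] - 1]) if off[0] > 0 else float(self.years[0])
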