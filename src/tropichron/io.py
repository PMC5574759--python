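"""Readers and writers for the plain-text formats the pipeline touches.

Tucson RWL (decadal ring-width interchange format), and headered CSV
schemas for monthly climate (``year,m01..m12``), annual index
(``year,value``), chronology (``year,index,depth``), radiocarbon samples
(``tree_id,dendro_year,fm,fm_sd``) and the bomb-pulse curve
(``year,fm,fm_sd``).

All readers validate rather than coerce: malformed input raises
:class:`~tropichron.errors.FormatError` (or a subclass) whose message
names the offending line or column.  Round-trips are lossless at each
format's stated precision (0.01 mm for RWL).
"""

from __future__ import annotations

import csv
import io as _io
import math
import warnings
from typing import Dict, List, TextIO, Tuple, Union

import numpy as np
import pandas as pd

from .errors import FormatError, OrderError, OverflowError_, SchemaError
from .types import (
    AnnualSeries,
    BombCurve,
    Chronology,
    ClimateSeries,
    RadiocarbonSample,
    RingSeries,
)

#: Stop-marker values accepted on read (dominant Tucson dialects).
RWL_TERMINATORS = (999, -9999)
#: Stop marker emitted on write.
RWL_WRITE_TERMINATOR = 999
#: Largest width representable without colliding with a terminator (mm).
RWL_MAX_WIDTH_MM = 99.98


def _as_lines(stream: Union[str, TextIO]) -> List[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def read_rwl(stream: Union[str, TextIO]) -> List[RingSeries]:
    """Parse a Tucson decadal RWL file (text or stream).

    Values are integers in units of 0.01 mm; a terminator (999 or -9999)
    ends each series.  Width 0 encodes a locally absent ring and is kept
    in place as 0.0 mm.  Multiple series per file are supported; a
    duplicated series id is a format error.
    """
    lines = _as_lines(stream)
    out: List[RingSeries] = []
    seen = set()
    cur_id = None
    cur_first: int | None = None
    cur_vals: List[float] = []
    expect_year: int | None = None

    def flush(lineno):
        nonlocal cur_id, cur_first, cur_vals, expect_year
        if cur_id is None:
            return
        if cur_id in seen:
            raise FormatError(f"line {lineno}: duplicate series id '{cur_id}'")
        seen.add(cur_id)
        out.append(RingSeries(cur_id, cur_first, np.asarray(cur_vals)))
        cur_id, cur_first, cur_vals, expect_year = None, None, [], None

    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected 'id decade values...'")
        sid = parts[0]
        try:
            decade = int(parts[1])
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric decade year '{parts[1]}'")
        if cur_id is not None and sid != cur_id:
            raise FormatError(
                f"line {lineno}: series '{sid}' begins before '{cur_id}' "
                "was terminated")
        if cur_id is None:
            cur_id, cur_first = sid, decade
            expect_year = decade
        elif decade != expect_year:
            raise FormatError(
                f"line {lineno}: decade year {decade}, expected {expect_year}")
        terminated = False
        for f in parts[2:]:
            try:
                v = int(f)
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric width field '{f}'")
            if v in RWL_TERMINATORS:
                flush(lineno)
                terminated = True
                break
            if v < 0:
                raise FormatError(f"line {lineno}: negative width {v}")
            cur_vals.append(v / 100.0)
            expect_year += 1
        if not terminated and expect_year is not None and expect_year % 10 != 0:
            raise FormatError(
                f"line {lineno}: data line does not end at a decade boundary")
    if cur_id is not None:
        raise FormatError(f"series '{cur_id}' missing terminator")
    return out


def write_rwl(series: List[RingSeries]) -> str:
    """Serialize series to Tucson decadal RWL text.

    The first data line ends at the decade boundary; values are rounded
    half-up to integer hundredths of a millimetre; terminator 999.
    """
    buf = []
    for s in series:
        vals = []
        for w in s.widths:
            h = math.floor(w * 100 + 0.5)  # round half-up
            if h > 9998:
                raise OverflowError_(
                    f"{s.series_id}: width {w:.2f} mm exceeds RWL capacity "
                    f"({RWL_MAX_WIDTH_MM} mm)")
            if h == RWL_WRITE_TERMINATOR:
                # 9.99 mm would collide with the stop marker; nudge up one
                # hundredth (the format cannot represent 999 as data).
                warnings.warn(
                    f"{s.series_id}: width 9.99 mm collides with the "
                    "terminator; written as 10.00 mm", stacklevel=2)
                h = RWL_WRITE_TERMINATOR + 1
            vals.append(h)
        year = s.first_year
        i = 0
        n = len(vals)
        while i < n:
            decade_end = (year // 10) * 10 + 9
            take = min(n - i, decade_end - year + 1)
            fields = vals[i:i + take]
            i += take
            line = f"{s.series_id:<8s}{year:4d}" + "".join(f"{v:6d}" for v in fields)
            year += take
            if i == n:
                line += f"{RWL_WRITE_TERMINATOR:6d}"
            buf.append(line)
    return "\n".join(buf) + "\n"


# ---------------------------------------------------------------------------
# CSV schemas

_MONTH_COLS = [f"m{m:02d}" for m in range(1, 13)]


def _read_csv(stream: Union[str, TextIO], required: List[str], what: str) -> pd.DataFrame:
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing column '{col}'")
    return df


def _check_sorted_years(years: np.ndarray, what: str) -> None:
    if np.any(np.diff(years) <= 0):
        raise OrderError(f"{what}: years must be strictly increasing")


def read_climate_csv(stream, name: str = "climate", units: str = "") -> ClimateSeries:
    """Read a monthly climate CSV (``year,m01..m12``); empty cells are missing."""
    df = _read_csv(stream, ["year"] + _MONTH_COLS, "climate CSV")
    years = df["year"].to_numpy(dtype=int)
    _check_sorted_years(years, "climate CSV")
    return ClimateSeries(name, units, years, df[_MONTH_COLS].to_numpy(dtype=float))


def write_climate_csv(c: ClimateSeries) -> str:
    df = pd.DataFrame(c.monthly, columns=_MONTH_COLS)
    df.insert(0, "year", c.years)
    return df.to_csv(index=False)


def read_index_csv(stream, name: str = "index") -> AnnualSeries:
    df = _read_csv(stream, ["year", "value"], "index CSV")
    years = df["year"].to_numpy(dtype=int)
    _check_sorted_years(years, "index CSV")
    return AnnualSeries(name, years, df["value"].to_numpy(dtype=float))


def write_index_csv(s: AnnualSeries) -> str:
    return pd.DataFrame({"year": s.years, "value": s.values}).to_csv(index=False)


def read_chronology_csv(stream) -> Chronology:
    df = _read_csv(stream, ["year", "index", "depth"], "chronology CSV")
    years = df["year"].to_numpy(dtype=int)
    _check_sorted_years(years, "chronology CSV")
    return Chronology(years, df["index"].to_numpy(dtype=float),
                      df["depth"].to_numpy(dtype=int))


def write_chronology_csv(c: Chronology) -> str:
    return pd.DataFrame({"year": c.years, "index": c.index,
                         "depth": c.depth}).to_csv(index=False)


def read_c14_csv(stream) -> List[RadiocarbonSample]:
    """Read radiocarbon samples (``tree_id,dendro_year,fm,fm_sd``).

    Optional ``ring_index`` / ``true_year`` columns (synthetic ground
    truth) are carried through when present.
    """
    df = _read_csv(stream, ["tree_id", "dendro_year", "fm", "fm_sd"], "c14 CSV")
    out = []
    for _, row in df.iterrows():
        out.append(RadiocarbonSample(
            tree_id=str(row["tree_id"]),
            dendro_year=int(row["dendro_year"]),
            fm=float(row["fm"]),
            fm_sd=float(row["fm_sd"]),
            ring_index=(int(row["ring_index"]) if "ring_index" in df.columns
                        and not pd.isna(row["ring_index"]) else None),
            true_year=(int(row["true_year"]) if "true_year" in df.columns
                       and not pd.isna(row["true_year"]) else None),
        ))
    return out


def write_c14_csv(samples: List[RadiocarbonSample]) -> str:
    rows = [{"tree_id": s.tree_id, "dendro_year": s.dendro_year,
             "fm": s.fm, "fm_sd": s.fm_sd,
             "ring_index": s.ring_index, "true_year": s.true_year}
            for s in samples]
    return pd.DataFrame(rows).to_csv(index=False)


def read_curve_csv(stream) -> BombCurve:
    """Read a bomb-pulse calibration curve (``year,fm,fm_sd``)."""
    df = _read_csv(stream, ["year", "fm", "fm_sd"], "curve CSV")
    years = df["year"].to_numpy(dtype=float)
    if np.any(np.diff(years) <= 0):
        raise OrderError("curve CSV: years must be strictly increasing")
    return BombCurve(years, df["fm"].to_numpy(dtype=float),
                     df["fm_sd"].to_numpy(dtype=float))


def write_curve_csv(c: BombCurve) -> str:
    return pd.DataFrame({"year": c.years, "fm": c.fm,
                         "fm_sd": c.fm_sd}).to_csv(index=False)
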