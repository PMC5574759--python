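"""Chronology-climate response analysis.

Screening tests (normality, monotone trend, homogeneity), monthly /
seasonal / annual Pearson correlations with percentile-bootstrap
confidence intervals, and gridded-field correlation maps masked at
p < .10.  Missing data are handled by pairwise deletion, never
imputation; all correlations resample year pairs (case resampling) so
the bivariate pairing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedStatisticError
from .types import AnnualSeries, Chronology, ClimateSeries, GriddedField

MIN_OVERLAP = 15  # years of paired data required for a correlation

MONTH_NAMES = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]


# ---------------------------------------------------------------------------
# Series screening

def mann_kendall(x: np.ndarray) -> Tuple[float, float]:
    """Mann-Kendall trend test: returns (S statistic, two-sided p).

    Variance uses the tie correction; the normal approximation with
    continuity correction is standard for n >= 10.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = 0.0
    for i in range(n - 1):
        s += np.sum(np.sign(x[i + 1:] - x[i]))
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2 * (1 - stats.norm.cdf(abs(z)))
    return float(s), float(p)


def pettitt(x: np.ndarray) -> Tuple[float, float, int]:
    """Pettitt homogeneity (single change-point) test.

    Returns (K statistic, approximate p, change-point index).  The
    p-value uses the classical approximation 2·exp(−6K²/(n³+n²)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = stats.rankdata(x)
    u = 2 * np.cumsum(r)[:-1] - np.arange(1, n) * (n + 1)
    k_idx = int(np.argmax(np.abs(u)))
    K = float(np.abs(u[k_idx]))
    p = min(1.0, 2.0 * np.exp(-6.0 * K ** 2 / (n ** 3 + n ** 2)))
    return K, float(p), k_idx + 1


@dataclass
class ScreeningReport:
    name: str
    n: int
    shapiro_w: float
    shapiro_p: float
    mk_s: float
    mk_p: float
    pettitt_k: float
    pettitt_p: float
    alpha: float
    passed: bool


def screen_series(x: AnnualSeries, alpha: float = 0.05) -> ScreeningReport:
    """Normality (Shapiro-Wilk), trend (Mann-Kendall) and homogeneity
    (Pettitt) screening at level ``alpha``; pass = all three non-significant.
    """
    v = x.values[np.isfinite(x.values)]
    if len(v) < 20:
        raise UndefinedStatisticError(
            f"{x.name}: screening needs n >= 20, got {len(v)}")
    sw, sp_ = stats.shapiro(v)
    mks, mkp = mann_kendall(v)
    pk, pp, _ = pettitt(v)
    passed = (sp_ > alpha) and (mkp > alpha) and (pp > alpha)
    return ScreeningReport(x.name, len(v), float(sw), float(sp_),
                           mks, mkp, pk, pp, alpha, passed)


# ---------------------------------------------------------------------------
# Aggregation

def seasonalize(c: ClimateSeries, months: Sequence[int],
                stat: str = "mean") -> AnnualSeries:
    """Aggregate selected months (1-12) per year by mean or total.

    A year missing any selected month is reported missing.  Cross-year
    seasons are out of scope: all reported signals at this site fall
    within the ring's calendar year.
    """
    months = sorted(set(int(m) for m in months))
    if not months:
        raise DomainError("month set must be non-empty")
    if any(m < 1 or m > 12 for m in months):
        raise DomainError("months must lie in 1..12")
    block = c.monthly[:, [m - 1 for m in months]]
    if stat == "mean":
        vals = np.mean(block, axis=1)
    elif stat == "total":
        vals = np.sum(block, axis=1)
    else:
        raise DomainError(f"unknown stat '{stat}'")
    vals = np.where(np.any(~np.isfinite(block), axis=1), np.nan, vals)
    label = f"{c.name}_" + ("annual" if len(months) == 12 else
                            "".join(MONTH_NAMES[m - 1][0] for m in months))
    return AnnualSeries(label, c.years, vals)


# ---------------------------------------------------------------------------
# Bootstrapped correlation

@dataclass
class ResponseResult:
    predictor: str
    aggregation: str          # "month:oct", "season:ond", "annual"
    period: Tuple[int, int]
    n: int
    r: float
    ci_low: float
    ci_high: float
    significant: bool
    refused: bool = False
    reason: str = ""


def _aligned(ya, va, yb, vb, period=None):
    common, ia, ib = np.intersect1d(ya, yb, return_indices=True)
    a, b = va[ia], vb[ib]
    if period is not None:
        keep = (common >= period[0]) & (common <= period[1])
        common, a, b = common[keep], a[keep], b[keep]
    ok = np.isfinite(a) & np.isfinite(b)
    return common[ok], a[ok], b[ok]


def _bootstrap_r(a: np.ndarray, b: np.ndarray, n_boot: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Pearson r over ``n_boot`` case resamples, vectorized."""
    n = len(a)
    idx = rng.integers(0, n, size=(n_boot, n))
    xa, xb = a[idx], b[idx]
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    num = np.sum(xa * xb, axis=1)
    den = np.sqrt(np.sum(xa ** 2, axis=1) * np.sum(xb ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlate_bootstrap(chron: Chronology, y: AnnualSeries,
                        period: Optional[Tuple[int, int]] = None,
                        n_boot: int = 1000, seed: int = 0,
                        ci: float = 0.95,
                        aggregation: str = "annual") -> ResponseResult:
    """Pearson correlation with a percentile-bootstrap confidence interval.

    Years are resampled in pairs with replacement; significance means 0
    lies outside the CI.  Refuses (with the count in the message) when
    fewer than 15 paired years remain after alignment.
    """
    years, a, b = _aligned(chron.years, chron.index, y.years, y.values, period)
    n = len(years)
    if n < MIN_OVERLAP:
        return ResponseResult(y.name, aggregation,
                              period or (0, 0), n, np.nan, np.nan, np.nan,
                              False, refused=True,
                              reason=f"overlap {n} < {MIN_OVERLAP} years")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    boots = _bootstrap_r(a, b, n_boot, rng)
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    lo, hi = float(min(lo, r)), float(max(hi, r))
    sig = not (lo <= 0.0 <= hi)
    actual_period = (int(years.min()), int(years.max()))
    return ResponseResult(y.name, aggregation, actual_period, n, r, lo, hi, sig)


def monthly_response(chron: Chronology, c: ClimateSeries,
                     period: Optional[Tuple[int, int]] = None,
                     n_boot: int = 1000, seed: int = 0,
                     ci: float = 0.95) -> List[ResponseResult]:
    """One bootstrapped correlation per calendar month of the growth year.

    Months with insufficient overlap are reported refused; the others are
    computed.  Prior-year months are out of scope at this site (the
    growth season falls within the ring's calendar year).
    """
    out = []
    for m in range(1, 13):
        s = AnnualSeries(f"{c.name}", c.years, c.monthly[:, m - 1])
        res = correlate_bootstrap(chron, s, period=period, n_boot=n_boot,
                                  seed=seed + m, ci=ci,
                                  aggregation=f"month:{MONTH_NAMES[m - 1]}")
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Gridded fields

@dataclass
class FieldCorrelation:
    lat: np.ndarray
    lon: np.ndarray
    r: np.ndarray              # (n_lat, n_lon)
    p: np.ndarray
    mask: np.ndarray           # True where p < p_crit (plottable cells)
    p_crit: float
    undefined: np.ndarray      # True where a cell had zero variance


def field_correlate(x: AnnualSeries, g: GriddedField,
                    n_boot: int = 1000, seed: int = 0,
                    p_crit: float = 0.10) -> FieldCorrelation:
    """Per-cell Pearson r of a gridded field with an annual series.

    The bootstrap p per cell is the two-sided percentile inversion
    p = 2·min(frac of bootstrap r <= 0, >= 0), ties counted half; cells
    with zero variance are flagged undefined rather than fatal.  The mask
    marks cells significant at ``p_crit``.
    """
    common, ix, it = np.intersect1d(x.years, g.time, return_indices=True)
    if len(common) < MIN_OVERLAP:
        raise UndefinedStatisticError(
            f"field overlap {len(common)} < {MIN_OVERLAP} years")
    a = x.values[ix]
    cube = g.values[:, :, it]
    ok = np.isfinite(a)
    a = a[ok]
    cube = cube[:, :, ok]
    n_lat, n_lon, n = cube.shape

    am = a - a.mean()
    cm = cube - cube.mean(axis=2, keepdims=True)
    sa = np.sqrt(np.sum(am ** 2))
    sc = np.sqrt(np.sum(cm ** 2, axis=2))
    undefined = (sc == 0) | (sa == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ijt,t->ij", cm, am) / (sc * sa)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xa = a[idx]
    xa = xa - xa.mean(axis=1, keepdims=True)       # (B, n)
    xc = cube[:, :, idx]                           # (lat, lon, B, n)
    xc = xc - xc.mean(axis=3, keepdims=True)
    num = np.einsum("ijbt,bt->ijb", xc, xa)
    den = np.sqrt(np.einsum("ijbt,ijbt->ijb", xc, xc)
                  * np.sum(xa ** 2, axis=1)[None, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        br = num / den
    neg = np.sum(br < 0, axis=2) + 0.5 * np.sum(br == 0, axis=2)
    pos = np.sum(br > 0, axis=2) + 0.5 * np.sum(br == 0, axis=2)
    p = 2.0 * np.minimum(neg, pos) / n_boot
    p = np.minimum(p, 1.0)
    p = np.where(undefined, np.nan, p)
    r = np.where(undefined, np.nan, r)
    mask = np.where(undefined, False, p < p_crit)
    return FieldCorrelation(g.lat, g.lon, r, p, mask, p_crit, undefined)
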