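"""Synthetic floodplain-forest data with known ground truth.

Emulates a near-equatorial riverine site: ~15 trees measured on 31 radii
spanning 1830-2006, whose growth is driven by a shared October-December
(OND) streamflow signal modulated by an ENSO-like index.  Trees may form
intra-annual growth bands (an extra ring anatomically indistinguishable
from an annual boundary) and may fail to form a recognizable ring in some
years (the ring merges with its neighbour).  Both error types are drawn
at the population level — a shared climatic trigger — so the resulting
ring sequences still crossdate between trees while their calendar dates
drift away from the truth, which is exactly the failure mode bomb-pulse
radiocarbon dating is designed to expose.

Every output is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, SelectionError
from .types import (
    AnnualSeries,
    BombCurve,
    ClimateSeries,
    GriddedField,
    RadiocarbonSample,
    RingSeries,
)

# Flags a ring record can carry.
FLAG_ANNUAL = "annual"    # ordinary ring: one ring, one calendar year
FLAG_EXTRA = "extra"      # second ring of a split year (shares the year)
FLAG_MERGED = "merged"    # ring whose wood also contains the following year(s)


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults emulate the study conditions: 15 trees / 31 radii over
    1830-2006, lognormal ring noise around a negative-exponential age
    trend, a common OND-streamflow growth signal, shared intra-annual
    band years, and Fm measurement SD of 0.3%.
    """

    n_trees: int = 15
    radii_per_tree: int = 2
    extra_radii: int = 1          # this many trees (from the first) get +1 radius
    span: Tuple[int, int] = (1830, 2006)
    age_trend: Tuple[float, float, float] = (3.5, 0.02, 0.5)  # A mm, k 1/yr, c mm
    beta: float = 0.55            # climate sensitivity (per SD of OND flow)
    sigma_ring: float = 0.35      # lognormal SD of ring-width noise
    p_extra: float = 0.3          # per-year probability of an intra-annual band year
    p_merge: float = 0.02         # per-year probability of a tree-wide unrecognized ring
    p_missing: float = 0.02       # per-year probability a ring is locally absent on a radius
    participation: float = 1.0    # probability a tree expresses a population event year
    extra_era: Optional[Tuple[int, int]] = (1830, 1985)  # event years era; None = whole span
    recruit_span: int = 40        # tree births staggered over the first N years
    meas_sd_fm: float = 0.003     # Fm measurement SD (AMS precision ~0.3%)
    seed: int = 0

    def validate(self) -> None:
        A, k, c = self.age_trend
        if not (0 <= self.p_extra < 1 and 0 <= self.p_merge < 1
                and 0 <= self.p_missing < 1):
            raise ConfigError("probabilities must lie in [0, 1)")
        if self.p_extra + self.p_merge >= 1:
            raise ConfigError("p_extra + p_merge must be < 1")
        if not (A > 0 and k > 0 and c >= 0):
            raise ConfigError("age trend requires A > 0, k > 0, c >= 0")
        if not self.meas_sd_fm > 0:
            raise ConfigError("meas_sd_fm must be positive")
        if self.span[1] - self.span[0] + 1 < 40:
            raise ConfigError("span must cover at least 40 years")
        if not (0 <= self.participation <= 1):
            raise ConfigError("participation must lie in [0, 1]")
        if self.n_trees < 1 or self.radii_per_tree < 1:
            raise ConfigError("need at least one tree and one radius")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("span", "age_trend", "extra_era"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    """Per-tree stream derived by hashing (master seed, tree index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + tree_index]))


@dataclass
class RingRecord:
    """Ground truth for one observed ring of a tree."""

    position: int        # 0-based from the pith, tree-level ring count
    true_year: int       # calendar year the ring (started to) form
    flag: str            # FLAG_ANNUAL | FLAG_EXTRA | FLAG_MERGED
    n_years: int = 1     # calendar years of wood the ring contains (merged > 1)


@dataclass
class TruthTable:
    """Ground truth linking observed rings to calendar years.

    ``rings`` maps tree id -> ordered ring records (pith -> bark);
    ``absent`` maps series id -> 0-based positions locally absent on that
    radius; ``harvest_year`` anchors bark-side ring counting.
    """

    harvest_year: int
    rings: Dict[str, List[RingRecord]] = field(default_factory=dict)
    absent: Dict[str, List[int]] = field(default_factory=dict)
    event_years: Dict[str, List[int]] = field(default_factory=dict)

    def n_rings(self, tree_id: str) -> int:
        return len(self.rings[tree_id])

    def dendro_year(self, tree_id: str, position: int) -> int:
        """Calendar year ring counting assigns to a ring position.

        The bark-side ring is anchored to the harvest year and rings are
        counted inward, as a field dendrochronologist would; extra rings
        therefore push older dendro dates earlier and merged rings push
        them later.
        """
        n = self.n_rings(tree_id)
        if not 0 <= position < n:
            raise SelectionError(
                f"{tree_id}: position {position} beyond ring count {n}")
        return self.harvest_year - (n - 1 - position)

    def true_year(self, tree_id: str, position: int) -> int:
        n = self.n_rings(tree_id)
        if not 0 <= position < n:
            raise SelectionError(
                f"{tree_id}: position {position} beyond ring count {n}")
        return self.rings[tree_id][position].true_year

    def n_extra(self, tree_id: str) -> int:
        return sum(r.flag == FLAG_EXTRA for r in self.rings[tree_id])

    def offset_at(self, tree_id: str, position: int) -> int:
        """True minus dendro year at a position (positive = dated too old)."""
        return self.true_year(tree_id, position) - self.dendro_year(tree_id, position)

    def to_dict(self) -> dict:
        return {
            "harvest_year": self.harvest_year,
            "rings": {t: [asdict(r) for r in recs] for t, recs in self.rings.items()},
            "absent": self.absent,
            "event_years": self.event_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            harvest_year=d["harvest_year"],
            rings={t: [RingRecord(**r) for r in recs]
                   for t, recs in d["rings"].items()},
            absent={k: list(v) for k, v in d.get("absent", {}).items()},
            event_years={k: list(v) for k, v in d.get("event_years", {}).items()},
        )


# ---------------------------------------------------------------------------
# Climate

# Stylized seasonal cycles for a wet near-equatorial lowland site:
# precipitation (mm/month) with an OND-heavy wet season, temperature (degC)
# nearly flat, streamflow (m3/s) peaking in OND.
_PRECIP_CYCLE = np.array([300, 280, 320, 420, 500, 480, 470, 500, 540, 600, 580, 450.0])
_TEMP_CYCLE = np.array([26.8, 27.0, 27.1, 27.0, 26.9, 26.8, 26.8, 26.9, 26.8, 26.6, 26.5, 26.6])
_FLOW_CYCLE = np.array([2500, 2300, 2400, 2900, 3400, 3300, 3200, 3400, 3700, 4300, 4500, 3800.0])
_LEVEL_CYCLE = _FLOW_CYCLE / 600.0  # river stage, m


def gen_climate(config: SimConfig,
                couplings: Optional[dict] = None,
                noise_scale: float = 1.0,
                phi: float = 0.5,
                ) -> Tuple[Dict[str, ClimateSeries], Dict[str, AnnualSeries]]:
    """Generate monthly climate series and annual climate indices.

    The ENSO-like annual index ``z`` follows a stationary AR(1) with unit
    marginal variance; streamflow is coupled negatively to it (a warm
    event lowers flow), precipitation weakly negatively, temperature
    weakly positively.  ``couplings`` overrides the log-space (or, for
    temperature, additive) coupling coefficients per variable.

    Returns (monthly series by name, annual index series by name).
    """
    config.validate()
    y0, y1 = config.span
    n = y1 - y0 + 1
    if n < 2:
        raise ConfigError("span must cover at least 2 years")
    coup = {"precip": -0.3, "temp": 0.3, "streamflow": -0.6, "level": -0.6}
    if couplings:
        coup.update(couplings)
    for v in coup.values():
        if not np.isfinite(v):
            raise ConfigError("coupling coefficients must be finite")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    years = np.arange(y0, y1 + 1)

    # AR(1) ENSO-like index, unit marginal variance
    z = np.empty(n)
    z[0] = rng.normal(0, 1)
    innov = rng.normal(0, np.sqrt(1 - phi ** 2), n)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t]

    def lognormal_monthly(cycle, coupling, sd):
        eps = rng.normal(0, sd * noise_scale, (n, 12))
        return cycle[None, :] * np.exp(coupling * z[:, None] + eps)

    precip = lognormal_monthly(_PRECIP_CYCLE, coup["precip"], 0.30)
    flow = lognormal_monthly(_FLOW_CYCLE, coup["streamflow"], 0.25)
    level = lognormal_monthly(_LEVEL_CYCLE, coup["level"], 0.20)
    temp = (_TEMP_CYCLE[None, :] + coup["temp"] * z[:, None]
            + rng.normal(0, 0.3 * noise_scale, (n, 12)))

    series = {
        "precip": ClimateSeries("precip", "mm", years, precip, station_id="SYN-P1",
                                lat=7.0, lon=-77.0),
        "temp": ClimateSeries("temp", "degC", years, temp, station_id="SYN-T1",
                              lat=7.0, lon=-77.0),
        "streamflow": ClimateSeries("streamflow", "m3/s", years, flow,
                                    station_id="SYN-Q1", lat=7.1, lon=-77.0),
        "level": ClimateSeries("level", "m", years, level, station_id="SYN-H1",
                               lat=7.1, lon=-77.0),
    }

    pdo = np.empty(n)
    pdo[0] = rng.normal()
    pinnov = rng.normal(0, np.sqrt(1 - 0.8 ** 2), n)
    for t in range(1, n):
        pdo[t] = 0.8 * pdo[t - 1] + pinnov[t]
    indices = {
        "oni": AnnualSeries("oni", years, z.copy()),
        "soi": AnnualSeries("soi", years, -z + rng.normal(0, 0.5, n)),
        "pdo": AnnualSeries("pdo", years, pdo),
        "nao": AnnualSeries("nao", years, rng.normal(0, 1, n)),
    }
    return series, indices


def gen_gridded_field(config: SimConfig, signal: AnnualSeries,
                      n_lat: int = 8, n_lon: int = 10,
                      signal_box: Tuple[slice, slice] = (slice(2, 5), slice(3, 7)),
                      effect: float = 0.8, units: str = "mm",
                      ) -> GriddedField:
    """Gridded annual field sharing ``signal`` inside ``signal_box`` only.

    Cells in the box are ``effect * signal + noise``; all other cells are
    pure noise — a controlled stand-in for a gridded precipitation or SST
    product when testing field-correlation logic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    nt = len(signal.years)
    cube = rng.normal(0, 1, (n_lat, n_lon, nt))
    s = (signal.values - np.nanmean(signal.values)) / np.nanstd(signal.values)
    cube[signal_box[0], signal_box[1], :] = (
        effect * s[None, None, :]
        + rng.normal(0, 1, cube[signal_box[0], signal_box[1], :].shape))
    lat = np.linspace(-5, 15, n_lat)
    lon = np.linspace(-90, -60, n_lon)
    return GriddedField(lat, lon, signal.years, cube, units=units)


# ---------------------------------------------------------------------------
# Ring-width series

def ond_signal(streamflow: ClimateSeries) -> AnnualSeries:
    """Standardized log October-December mean streamflow (the growth driver).

    Growth responds to the relative (log) flow anomaly — a saturating
    response, so one extreme flood year does not produce a
    proportionally extreme ring.
    """
    ond = np.nanmean(streamflow.monthly[:, 9:12], axis=1)
    logq = np.log(ond)
    z = (logq - np.nanmean(logq)) / np.nanstd(logq)
    return AnnualSeries("ond_streamflow_std", streamflow.years, z)


def gen_ring_series(config: SimConfig, climate: ClimateSeries,
                    ) -> Tuple[List[RingSeries], TruthTable]:
    """Grow every tree and measure its radii.

    Width for true year t is ``(A*exp(-k*age) + c) * exp(beta * z_t) *
    exp(N(0, sigma_ring))`` where ``z_t`` is the standardized OND
    streamflow.  With probability ``p_extra`` a year is a population band
    year (its wood is split into two rings at a uniform [0.3, 0.7]
    proportion, conserving total wood); with probability ``p_merge`` a
    year's ring goes unrecognized tree-wide and its wood merges into the
    previous ring.  Each radius additionally loses rings locally with
    probability ``p_missing`` (kept as 0.0-width placeholders, as a
    crossdater who spotted the wedging ring would record them).
    """
    config.validate()
    y0, y1 = config.span
    cyears = climate.years
    if cyears[0] > y0 or cyears[-1] < y1:
        raise ConfigError(
            f"climate years {cyears[0]}-{cyears[-1]} do not cover span {y0}-{y1}")

    sig = ond_signal(climate)
    zmap = dict(zip(sig.years.tolist(), sig.values.tolist()))

    A, k, c = config.age_trend
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    # Population-level event years (shared climatic trigger).
    era0, era1 = config.extra_era if config.extra_era is not None else (y0, y1)
    extra_years, merge_years = [], []
    for year in range(y0, y1 + 1):
        if not era0 <= year <= era1:
            continue
        u = master.uniform()
        if u < config.p_extra:
            extra_years.append(year)
        elif u < config.p_extra + config.p_merge:
            merge_years.append(year)
    extra_set, merge_set = set(extra_years), set(merge_years)

    series: List[RingSeries] = []
    truth = TruthTable(harvest_year=y1,
                       event_years={"extra": extra_years, "merge": merge_years})

    for i in range(config.n_trees):
        tree_id = f"PG{i + 1:02d}"
        rng = _tree_rng(config.seed, i)
        birth = y0 + (0 if config.n_trees == 1 else
                      round(i * config.recruit_span / config.n_trees))
        records: List[RingRecord] = []
        widths: List[float] = []
        for year in range(birth, y1 + 1):
            age = year - birth
            z = zmap.get(year, 0.0)
            w = ((A * np.exp(-k * age) + c)
                 * np.exp(config.beta * z)
                 * np.exp(rng.normal(0, config.sigma_ring)))
            participates = (config.participation >= 1.0
                            or rng.uniform() < config.participation)
            if year in merge_set and participates and records:
                # ring unrecognized: wood merges into the previous ring
                widths[-1] += w
                records[-1].flag = FLAG_MERGED
                records[-1].n_years += 1
            elif year in extra_set and participates:
                q = rng.uniform(0.3, 0.7)
                records.append(RingRecord(len(records), year, FLAG_ANNUAL))
                widths.append(w * q)
                records.append(RingRecord(len(records), year, FLAG_EXTRA))
                widths.append(w * (1 - q))
            else:
                records.append(RingRecord(len(records), year, FLAG_ANNUAL))
                widths.append(w)
        truth.rings[tree_id] = records
        tree_widths = np.asarray(widths)
        n = len(tree_widths)
        first_dendro = y1 - n + 1

        n_radii = config.radii_per_tree + (1 if i < config.extra_radii else 0)
        radius_sd = 0.3 * config.sigma_ring  # within-tree measurement-path noise
        for r in range(n_radii):
            sid = f"{tree_id}{chr(65 + r)}"
            jitter = np.exp(rng.normal(0, radius_sd, n))
            w_r = tree_widths * jitter
            miss = np.nonzero(rng.uniform(size=n) < config.p_missing)[0]
            w_r[miss] = 0.0
            truth.absent[sid] = miss.tolist()
            series.append(RingSeries(sid, first_dendro, w_r))
    return series, truth


# ---------------------------------------------------------------------------
# Radiocarbon

# Stylized post-bomb atmospheric curve for the relevant northern band:
# flat pre-1955 plateau, strictly monotone rise to a single peak near
# 1964, monotone decay through 2006 (fast limb then a slow tail, as in
# the real atmospheric record).  Values are a stylized synthetic
# stand-in, not a published compilation; a real curve can be supplied as
# CSV through the I/O layer.  The fast-limb slope (0.026 Fm/yr) keeps
# single calendar years resolvable at the ~0.3% measurement SD the AMS
# protocol achieves: neighbouring years differ by > 4 measurement SDs.
_CURVE_PLATEAU = 0.980
_CURVE_PEAK = 1.830
_CURVE_PEAK_YEAR = 1964
_CURVE_KNEE = 1.050
_CURVE_KNEE_YEAR = 1994
_CURVE_END = 1.040
_CURVE_END_YEAR = 2006
_CURVE_SD = 0.006


def gen_bomb_curve(start: int = 1900, stop: int = 2008) -> BombCurve:
    """Built-in stylized bomb-pulse curve at annual resolution.

    Plateau 0.980 through 1954; strict rise to a single global maximum of
    1.830 at 1964; fast linear decay to 1.050 at 1994; slow strictly
    monotone tail to 1.040 at 2006 and beyond to ``stop``; constant
    curve SD 0.006.
    """
    years = np.arange(start, stop + 1, dtype=float)
    fm = np.full_like(years, _CURVE_PLATEAU)
    rise = (years > 1954) & (years <= _CURVE_PEAK_YEAR)
    frac = (years[rise] - 1954) / (_CURVE_PEAK_YEAR - 1954)
    fm[rise] = _CURVE_PLATEAU + (_CURVE_PEAK - _CURVE_PLATEAU) * frac
    fast = (years > _CURVE_PEAK_YEAR) & (years <= _CURVE_KNEE_YEAR)
    slope_fast = (_CURVE_KNEE - _CURVE_PEAK) / (_CURVE_KNEE_YEAR - _CURVE_PEAK_YEAR)
    fm[fast] = _CURVE_PEAK + slope_fast * (years[fast] - _CURVE_PEAK_YEAR)
    tail = years > _CURVE_KNEE_YEAR
    slope_tail = (_CURVE_END - _CURVE_KNEE) / (_CURVE_END_YEAR - _CURVE_KNEE_YEAR)
    fm[tail] = _CURVE_KNEE + slope_tail * (years[tail] - _CURVE_KNEE_YEAR)
    return BombCurve(years, fm, np.full_like(years, _CURVE_SD))


def default_sample_positions(truth: TruthTable, tree_id: str,
                             n_samples: int = 8, spacing: int = 10,
                             target_last_dendro: Optional[int] = None,
                             ) -> List[int]:
    """Ring positions for a bomb-spike sampling plan.

    Eight rings spaced ``spacing`` rings apart, the bark-most chosen so
    its dendro year sits near ``target_last_dendro`` (default: 11 rings
    in from the bark, bracketing a mid-1960s spike for a 2006 harvest).
    """
    n = truth.n_rings(tree_id)
    if target_last_dendro is None:
        last_pos = n - 1 - 11
    else:
        last_pos = n - 1 - (truth.harvest_year - target_last_dendro)
    positions = [last_pos - spacing * j for j in range(n_samples)][::-1]
    if positions[0] < 0 or positions[-1] >= n:
        raise SelectionError(
            f"{tree_id}: sampling plan positions {positions[0]}..{positions[-1]} "
            f"fall outside ring count {n}")
    return positions


def gen_14c_measurements(truth: TruthTable, curve: BombCurve, config: SimConfig,
                         tree_ids: Optional[Sequence[str]] = None,
                         positions: Optional[Dict[str, Sequence[int]]] = None,
                         n_samples: int = 8, spacing: int = 10,
                         ) -> List[RadiocarbonSample]:
    """Measure Fm on selected rings with Gaussian measurement error.

    Each measured ring yields ``Fm = curve(true year) + N(0, meas_sd_fm)``
    and records both its dendro year (ring counting with errors) and the
    hidden true year for test assertions.
    """
    config.validate()
    if tree_ids is None:
        tree_ids = sorted(truth.rings)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 14]))
    out: List[RadiocarbonSample] = []
    for tid in tree_ids:
        if positions is not None and tid in positions:
            pos_list = list(positions[tid])
        else:
            pos_list = default_sample_positions(truth, tid, n_samples, spacing)
        for pos in pos_list:
            ty = truth.true_year(tid, pos)            # raises SelectionError if bad
            fm = float(curve.fm_at(ty) + rng.normal(0, config.meas_sd_fm))
            out.append(RadiocarbonSample(
                tree_id=tid, dendro_year=truth.dendro_year(tid, pos),
                fm=fm, fm_sd=config.meas_sd_fm, ring_index=pos, true_year=ty))
    return out
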