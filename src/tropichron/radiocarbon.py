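"""Bomb-pulse validation of dendrochronological dates.

Each ring's measured fraction-modern value (Fm) is compared with the
atmospheric bomb-pulse reference curve: every calendar year whose curve
value lies within k·σ of the measurement (sample and curve SDs combined
in quadrature) is a candidate.  A dynamic program then picks one
candidate per sampled ring, minimizing the summed squared standardized
Fm residuals subject to strictly increasing calendar years along the
ring order (samples are ~10 rings apart, so true years are strictly
increasing even when individual rings are sub-annual); ties are broken
by the smallest total |offset| against the dendro dates.

Sign convention: offset = assigned − dendro year, so a positive offset
means ring counting dated the ring too old (too early) — the signature
of extra (intra-annual) rings, which accumulate going back in time.
Pre-bomb plateau matches are reported as open-ended bounds and excluded
from offset statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InfeasibleAssignmentError, UndefinedStatisticError
from .types import BombCurve, RadiocarbonSample

K_SIGMA_DEFAULT = 2.0


@dataclass
class CandidateRun:
    """A contiguous run of candidate calendar years for one sample."""

    start: int
    end: int
    open_start: bool = False    # run reaches the pre-bomb plateau

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.end - self.start)

    def years(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class CandidateResult:
    sample: RadiocarbonSample
    runs: List[CandidateRun]
    no_candidate: bool = False  # Fm above curve maximum + tolerance


def candidate_years(s: RadiocarbonSample, curve: BombCurve,
                    k_sigma: float = K_SIGMA_DEFAULT) -> CandidateResult:
    """All calendar years compatible with a sample's Fm value.

    A year y is a candidate when |fm − curve(y)| <= k·sqrt(fm_sd² +
    curve_sd²) with the curve interpolated to annual midpoints.
    Contiguous candidate years are collapsed into runs; a run touching
    the pre-bomb plateau is open-ended (any earlier year matches the flat
    plateau equally well).  An Fm above the curve maximum plus tolerance
    yields a flagged no-candidate result, not an error.
    """
    years = np.arange(int(np.ceil(curve.years[0])),
                      int(np.floor(curve.years[-1])) + 1)
    cfm = curve.fm_at(years)
    csd = curve.sd_at(years)
    tol = k_sigma * np.sqrt(s.fm_sd ** 2 + csd ** 2)
    hit = np.abs(s.fm - cfm) <= tol
    if not np.any(hit):
        return CandidateResult(s, [], no_candidate=True)
    runs: List[CandidateRun] = []
    plateau_end = curve.plateau_end()
    idx = np.nonzero(hit)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    for a, b in zip(starts, ends):
        y0, y1 = int(years[a]), int(years[b])
        open_start = y0 <= plateau_end
        runs.append(CandidateRun(y0, y1, open_start=open_start))
    return CandidateResult(s, runs)


@dataclass
class SampleAssignment:
    sample: RadiocarbonSample
    runs: List[CandidateRun]
    assigned_year: Optional[int]      # None when only the plateau matches
    plateau_bound: Optional[int]      # "<= this year" bound when on plateau
    offset: Optional[int]             # assigned − dendro; None on plateau
    coincident: bool                  # |offset| <= 1 year
    ambiguous: bool


@dataclass
class C14Assignment:
    tree_id: str
    samples: List[SampleAssignment] = field(default_factory=list)

    def offsets(self) -> List[Tuple[int, int]]:
        """(ring_position_order_index, offset) for datable samples."""
        return [(i, sa.offset) for i, sa in enumerate(self.samples)
                if sa.offset is not None]

    @property
    def mean_abs_offset(self) -> float:
        offs = [abs(sa.offset) for sa in self.samples if sa.offset is not None]
        if not offs:
            return float("nan")
        return float(np.mean(offs))


def _standardized_cost(s: RadiocarbonSample, curve: BombCurve, year: float) -> float:
    sd = float(np.sqrt(s.fm_sd ** 2 + curve.sd_at(year) ** 2))
    return float(((s.fm - curve.fm_at(year)) / sd) ** 2)


def assign_tree_dates(samples: Sequence[RadiocarbonSample], curve: BombCurve,
                      k_sigma: float = K_SIGMA_DEFAULT,
                      coincidence_margin: int = 1,
                      max_run_years: int = 5) -> C14Assignment:
    """Sequence-constrained calendar-year assignment for one tree.

    Samples are ordered pith -> bark (by ring position when available,
    else by dendro year).  The dynamic program minimizes the summed
    squared standardized Fm residuals, tie-broken by the total |offset|
    against the dendro dates, subject to strictly increasing assigned
    years.  Samples whose only candidates lie on the pre-bomb plateau are
    assigned an open bound and excluded from the monotone constraint and
    the offset statistics; likewise a candidate run wider than
    ``max_run_years`` post-plateau years (the curve is locally too flat
    to resolve a calendar year, e.g. the post-1994 tail) is treated as
    uninformative rather than pretending single-year precision.  A
    sample within ±``coincidence_margin`` years of its dendro date is
    marked coincident.  If no monotone selection exists an
    :class:`InfeasibleAssignmentError` names the violating pair.
    """
    samples = sorted(samples, key=lambda s: (
        s.ring_index if s.ring_index is not None else s.dendro_year))
    if not samples:
        return C14Assignment("", [])
    tree_id = samples[0].tree_id

    cands = [candidate_years(s, curve, k_sigma) for s in samples]
    plateau_end = int(curve.plateau_end())

    def _informative_years(c: CandidateResult) -> List[int]:
        """Candidate years usable for single-year dating.

        A run is informative when it lies past the plateau and spans at
        most ``max_run_years`` years.  A sample with ANY uninformative
        run (open plateau run, or a wide run on a flat curve stretch) is
        ambiguous as a whole: the flat stretch explains the measurement
        just as well as a narrow twin on a steep limb, so the sample
        must not be forced onto the twin.
        """
        ys: List[int] = []
        for run in c.runs:
            post = [y for y in run.years() if y > plateau_end]
            if run.open_start or len(post) > max_run_years:
                return []
            ys.extend(post)
        return sorted(set(ys))

    # Split plateau-only / ambiguous samples out of the DP.
    datable: List[int] = []
    plateau_only: List[int] = []
    for i, c in enumerate(cands):
        if _informative_years(c):
            datable.append(i)
        else:
            plateau_only.append(i)

    year_lists: List[List[int]] = []
    cost_lists: List[List[float]] = []
    for i in datable:
        ys = _informative_years(cands[i])
        year_lists.append(ys)
        cost_lists.append([_standardized_cost(samples[i], curve, y) for y in ys])

    m = len(datable)
    best_choice: List[Optional[int]] = [None] * len(samples)
    n_opt_paths = [1] * len(samples)
    if m > 0:
        INF = (float("inf"), float("inf"))
        # dp[j][k] = (cost, tie) best over samples j.. with choice k at j
        dp = [[INF] * len(year_lists[j]) for j in range(m)]
        cnt = [[0] * len(year_lists[j]) for j in range(m)]
        nxt = [[-1] * len(year_lists[j]) for j in range(m)]
        for k, y in enumerate(year_lists[m - 1]):
            off = abs(y - samples[datable[m - 1]].dendro_year)
            dp[m - 1][k] = (cost_lists[m - 1][k], off)
            cnt[m - 1][k] = 1
        for j in range(m - 2, -1, -1):
            for k, y in enumerate(year_lists[j]):
                off = abs(y - samples[datable[j]].dendro_year)
                base = (cost_lists[j][k], off)
                best = INF
                best_k2 = -1
                n_paths = 0
                for k2, y2 in enumerate(year_lists[j + 1]):
                    if y2 <= y:
                        continue
                    cand_val = (base[0] + dp[j + 1][k2][0],
                                base[1] + dp[j + 1][k2][1])
                    if cand_val < best:
                        best, best_k2, n_paths = cand_val, k2, cnt[j + 1][k2]
                    elif np.isfinite(cand_val[0]) and _close(cand_val, best):
                        n_paths += cnt[j + 1][k2]
                dp[j][k] = best
                nxt[j][k] = best_k2
                cnt[j][k] = n_paths
        # pick start
        start_best, start_k, start_paths = INF, -1, 0
        for k in range(len(year_lists[0])):
            if dp[0][k] < start_best:
                start_best, start_k, start_paths = dp[0][k], k, cnt[0][k]
            elif np.isfinite(dp[0][k][0]) and _close(dp[0][k], start_best):
                start_paths += cnt[0][k]
        if not np.isfinite(start_best[0]):
            # find a violating adjacent pair for the error message
            for j in range(m - 1):
                if max(year_lists[j]) >= max(year_lists[j + 1]):
                    a, b = samples[datable[j]], samples[datable[j + 1]]
                    raise InfeasibleAssignmentError(
                        f"{tree_id}: no increasing assignment between rings "
                        f"dated {a.dendro_year} and {b.dendro_year}")
            raise InfeasibleAssignmentError(
                f"{tree_id}: no monotone candidate selection exists")
        ambiguous_all = start_paths > 1
        j, k = 0, start_k
        while k != -1 and j < m:
            best_choice[datable[j]] = year_lists[j][k]
            n_opt_paths[datable[j]] = start_paths
            k = nxt[j][k]
            j += 1
    else:
        ambiguous_all = False

    out = C14Assignment(tree_id)
    for i, s in enumerate(samples):
        c = cands[i]
        if i in plateau_only:
            bound = plateau_end if any(r.open_start for r in c.runs) else None
            out.samples.append(SampleAssignment(
                s, c.runs, assigned_year=None, plateau_bound=bound,
                offset=None, coincident=False, ambiguous=True))
        else:
            y = best_choice[i]
            off = int(y - s.dendro_year)
            out.samples.append(SampleAssignment(
                s, c.runs, assigned_year=int(y), plateau_bound=None,
                offset=off, coincident=abs(off) <= coincidence_margin,
                ambiguous=bool(ambiguous_all)))
    return out


def _close(a: Tuple[float, float], b: Tuple[float, float],
           tol: float = 1e-9) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


# ---------------------------------------------------------------------------
# Offset statistics

@dataclass
class ExcessRate:
    """Excess rings per decade between consecutive sampled rings."""

    mean: float
    sd: float                   # population SD (divisor n)
    n_intervals: int
    rates: List[float]


def excess_per_decade(a: C14Assignment,
                      interval: Optional[Tuple[int, int]] = None) -> ExcessRate:
    """Mean ± SD of excess rings per decade of assigned time.

    For each consecutive pair of datable samples, the excess is (rings
    counted between them) − (calendar years elapsed), normalized per
    decade of assigned time.  The interval (on assigned years) may
    restrict which pairs count; SD is the population SD.
    """
    pts = [(sa.sample, sa.assigned_year) for sa in a.samples
           if sa.assigned_year is not None]
    if interval is not None:
        pts = [(s, y) for s, y in pts if interval[0] <= y <= interval[1]]
    if len(pts) < 2:
        raise UndefinedStatisticError(
            "excess rate needs >= 2 assigned samples in the interval")
    rates = []
    for (s0, y0), (s1, y1) in zip(pts[:-1], pts[1:]):
        d_rings = s1.dendro_year - s0.dendro_year
        d_years = y1 - y0
        if d_years == 0:
            continue
        rates.append((d_rings - d_years) / d_years * 10.0)
    if not rates:
        raise UndefinedStatisticError("no interval with nonzero assigned span")
    arr = np.asarray(rates, dtype=float)
    return ExcessRate(float(arr.mean()), float(arr.std(ddof=0)),
                      len(arr), rates)


def cumulative_mismatch(interval_mismatches: Sequence[float]) -> Tuple[float, List[float]]:
    """Running sum of |interval mismatches| along a bark -> pith sequence.

    Returns (total at the oldest boundary, running partial sums).
    """
    running = []
    total = 0.0
    for m in interval_mismatches:
        total += abs(m)
        running.append(total)
    return total, running


def interval_mismatches(a: C14Assignment) -> List[int]:
    """Signed ring-count mismatches between consecutive datable samples,
    ordered bark -> pith (positive = more rings counted than years elapsed).
    """
    pts = [(sa.sample, sa.assigned_year) for sa in a.samples
           if sa.assigned_year is not None]
    out = []
    for (s0, y0), (s1, y1) in zip(pts[:-1], pts[1:]):
        out.append((s1.dendro_year - s0.dendro_year) - (y1 - y0))
    return out[::-1]
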