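"""Stochastic response function: time-varying regression by Kalman filter.

Model (structural time-series form):

    I_t = mu_t + alpha_t * X_t + eps_t,        eps_t ~ N(0, s2_eps)
    mu_t = mu_{t-1} + delta_{t-1}              (integrated random walk)
    delta_t = delta_{t-1} + zeta_t,            zeta_t ~ N(0, s2_zeta)
    alpha_t = alpha_{t-1} + eta_t,             eta_t ~ N(0, s2_eta)

The trend mu_t bends slowly (its slope, not its level, is a random
walk); the response weight alpha_t is a random walk.  States are
estimated by the discrete Kalman filter with fixed-interval (RTS)
smoothing; the three noise variances are maximum-likelihood estimates
from the prediction-error decomposition, optimized on the log scale with
multiple data-scaled starts.  The explained variance of adding X is

    100 * (1 - var(I - mu_hat - alpha_hat * X) / var(I - mu_hat)).

Initialization is diffuse-by-proxy: a large-but-finite prior variance
(1e7 x the sample variance of I), adequate for the series lengths used
here (n >= 40).  When a walk variance is pinned to exactly zero its
state is constant; pinning the slope-walk variance also pins the initial
slope at zero, so the s2_zeta = s2_eta = 0 limit reduces exactly to the
ordinary regression I_t = mu + alpha * X_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, DomainError, SeriesTooShortError

DIFFUSE_SCALE = 1e7
Z95 = 1.96


@dataclass
class StateSpace:
    """State-space description of the stochastic response model."""

    I: np.ndarray              # observations (NaN = missing)
    X: np.ndarray              # regressor (must be present where I is)
    years: np.ndarray
    T: np.ndarray = field(init=False)    # transition matrix (unit determinant)
    a0: np.ndarray = field(init=False)
    P0_diag: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.years = np.asarray(self.years)
        if len(self.I) != len(self.X) or len(self.I) != len(self.years):
            raise DomainError("I, X, years must be aligned")
        if len(self.I) < 10:
            raise SeriesTooShortError("need at least 10 observations")
        obs = np.isfinite(self.I)
        if np.any(obs & ~np.isfinite(self.X)):
            raise DomainError("X must be present wherever I is observed")
        self.T = np.array([[1.0, 1.0, 0.0],
                           [0.0, 1.0, 0.0],
                           [0.0, 0.0, 1.0]])
        var_i = float(np.nanvar(self.I))
        if var_i == 0:
            var_i = 1.0
        self.a0 = np.array([float(np.nanmean(self.I)), 0.0, 0.0])
        self.P0_diag = np.full(3, DIFFUSE_SCALE * var_i)

    def obs_row(self, t: int) -> np.ndarray:
        return np.array([1.0, 0.0, self.X[t]])


def build_state_space(I, X, years=None) -> StateSpace:
    """Assemble the state-space model for aligned annual series I and X."""
    I = np.asarray(I, dtype=float)
    if years is None:
        years = np.arange(len(I))
    return StateSpace(I, np.asarray(X, dtype=float), np.asarray(years))


def _kalman(ss: StateSpace, s2_eps: float, s2_zeta: float, s2_eta: float,
            pin_zero_states: bool = True):
    """Kalman filter pass: returns loglik and stored moments.

    Missing observations trigger a prediction-only step.  With
    ``pin_zero_states``, an exactly-zero walk variance clamps the
    corresponding prior variance to zero (constant state).
    """
    n = len(ss.I)
    T = ss.T
    Q = np.diag([0.0, s2_zeta, s2_eta])
    a = ss.a0.copy()
    P = np.diag(ss.P0_diag.copy())
    if pin_zero_states:
        if s2_zeta == 0.0:
            P[1, 1] = 0.0
        if s2_eta == 0.0:
            P[2, 2] = max(P[2, 2], 0.0)  # alpha still diffuse: constant unknown
    a_pred = np.empty((n, 3))
    P_pred = np.empty((n, 3, 3))
    a_filt = np.empty((n, 3))
    P_filt = np.empty((n, 3, 3))
    loglik = 0.0
    LOG2PI = np.log(2.0 * np.pi)
    for t in range(n):
        if t == 0:
            ap, Pp = a, P
        else:
            ap = T @ a
            Pp = T @ P @ T.T + Q
        a_pred[t], P_pred[t] = ap, Pp
        if np.isfinite(ss.I[t]):
            Z = ss.obs_row(t)
            F = float(Z @ Pp @ Z) + s2_eps
            v = float(ss.I[t] - Z @ ap)
            if F <= 0:
                return -np.inf, None
            K = (Pp @ Z) / F
            a = ap + K * v
            P = Pp - np.outer(K, Z @ Pp)
            loglik += -0.5 * (LOG2PI + np.log(F) + v * v / F)
        else:
            a, P = ap, Pp.copy()
        a_filt[t], P_filt[t] = a, P
    return loglik, (a_pred, P_pred, a_filt, P_filt)


def _smooth(ss: StateSpace, store):
    """Fixed-interval (RTS) smoother from stored filter moments."""
    a_pred, P_pred, a_filt, P_filt = store
    n = len(ss.I)
    a_s = a_filt.copy()
    P_s = P_filt.copy()
    T = ss.T
    for t in range(n - 2, -1, -1):
        Pp = P_pred[t + 1]
        # guard: Pp may be numerically singular when variances are pinned
        J = P_filt[t] @ T.T @ np.linalg.pinv(Pp)
        a_s[t] = a_filt[t] + J @ (a_s[t + 1] - a_pred[t + 1])
        P_s[t] = P_filt[t] + J @ (P_s[t + 1] - Pp) @ J.T
    return a_s, P_s


def _loglik_loop(I, X, a0, P0_diag, s2_eps, s2_zeta, s2_eta, pin_zeta):
    """Likelihood-only filter pass (no moment storage)."""
    n = I.shape[0]
    a = a0.copy()
    P = np.diag(P0_diag)
    if pin_zeta:
        P[1, 1] = 0.0
    Q = np.zeros((3, 3))
    Q[1, 1] = s2_zeta
    Q[2, 2] = s2_eta
    T = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    loglik = 0.0
    LOG2PI = np.log(2.0 * np.pi)
    for t in range(n):
        if t > 0:
            a = T @ a
            P = T @ P @ T.T + Q
        if np.isfinite(I[t]):
            x = X[t]
            # F = Z P Z' + s2_eps with Z = (1, 0, x)
            pz0 = P[0, 0] + x * P[0, 2]
            pz1 = P[1, 0] + x * P[1, 2]
            pz2 = P[2, 0] + x * P[2, 2]
            F = pz0 + x * pz2 + s2_eps
            if F <= 0:
                return -np.inf
            v = I[t] - (a[0] + x * a[2])
            k0, k1, k2 = pz0 / F, pz1 / F, pz2 / F
            a = np.array([a[0] + k0 * v, a[1] + k1 * v, a[2] + k2 * v])
            PZ = np.array([pz0, pz1, pz2])
            K = np.array([k0, k1, k2])
            P = P - np.outer(K, PZ)
            P = 0.5 * (P + P.T)
            loglik += -0.5 * (LOG2PI + np.log(F) + v * v / F)
    return loglik


try:  # jit-compile the hot loop when numba is available
    from numba import njit as _njit

    _loglik_loop_fast = _njit(cache=False)(_loglik_loop)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _loglik_loop_fast = _loglik_loop


def loglikelihood(ss: StateSpace, s2_eps: float, s2_zeta: float,
                  s2_eta: float) -> float:
    return float(_loglik_loop_fast(ss.I, ss.X, ss.a0, ss.P0_diag,
                                   float(s2_eps), float(s2_zeta),
                                   float(s2_eta), s2_zeta == 0.0))


@dataclass
class STMFit:
    """Smoothed stochastic-response fit with 95% bands."""

    years: np.ndarray
    mu_hat: np.ndarray
    alpha_hat: np.ndarray
    mu_var: np.ndarray
    alpha_var: np.ndarray
    s2_eps: float
    s2_zeta: float
    s2_eta: float
    loglik: float
    var_explained: float            # from smoothed states, percent
    var_explained_filtered: float   # from filtered states, percent
    mu_filt: np.ndarray = None
    alpha_filt: np.ndarray = None
    mu_var_filt: np.ndarray = None
    alpha_var_filt: np.ndarray = None
    I: np.ndarray = None
    X: np.ndarray = None

    @property
    def alpha_lo(self) -> np.ndarray:
        return self.alpha_hat - Z95 * np.sqrt(self.alpha_var)

    @property
    def alpha_hi(self) -> np.ndarray:
        return self.alpha_hat + Z95 * np.sqrt(self.alpha_var)

    @property
    def mu_lo(self) -> np.ndarray:
        return self.mu_hat - Z95 * np.sqrt(self.mu_var)

    @property
    def mu_hi(self) -> np.ndarray:
        return self.mu_hat + Z95 * np.sqrt(self.mu_var)


def explained_variance(I, X, mu_hat, alpha_hat) -> float:
    """100 * (1 − var(I − mu − alpha·X) / var(I − mu)), sample variances."""
    I = np.asarray(I, float)
    X = np.asarray(X, float)
    mu_hat = np.asarray(mu_hat, float)
    alpha_hat = np.asarray(alpha_hat, float)
    ok = np.isfinite(I) & np.isfinite(X)
    base = I[ok] - mu_hat[ok]
    resid = base - alpha_hat[ok] * X[ok]
    vb = float(np.var(base, ddof=1))
    if vb == 0:
        raise DomainError("var(I - mu_hat) is zero; explained variance undefined")
    return 100.0 * (1.0 - float(np.var(resid, ddof=1)) / vb)


def _fit_given(ss: StateSpace, s2_eps, s2_zeta, s2_eta) -> STMFit:
    ll, store = _kalman(ss, s2_eps, s2_zeta, s2_eta)
    if store is None:
        raise ConvergenceError("degenerate filter", best_params=(s2_eps, s2_zeta, s2_eta))
    a_s, P_s = _smooth(ss, store)
    _, _, a_f, P_f = store
    ok = np.isfinite(ss.I)
    ve_s = explained_variance(ss.I, ss.X, a_s[:, 0], a_s[:, 2])
    ve_f = explained_variance(ss.I, ss.X, a_f[:, 0], a_f[:, 2])
    return STMFit(
        years=ss.years, mu_hat=a_s[:, 0], alpha_hat=a_s[:, 2],
        mu_var=np.maximum(P_s[:, 0, 0], 0.0),
        alpha_var=np.maximum(P_s[:, 2, 2], 0.0),
        s2_eps=float(s2_eps), s2_zeta=float(s2_zeta), s2_eta=float(s2_eta),
        loglik=float(ll), var_explained=ve_s, var_explained_filtered=ve_f,
        mu_filt=a_f[:, 0], alpha_filt=a_f[:, 2],
        mu_var_filt=np.maximum(P_f[:, 0, 0], 0.0),
        alpha_var_filt=np.maximum(P_f[:, 2, 2], 0.0),
        I=ss.I, X=ss.X)


def fit_stm(I, X, years=None, n_starts: int = 5, seed: int = 0,
            fixed: Optional[Tuple[Optional[float], Optional[float],
                                  Optional[float]]] = None,
            maxiter: int = 400) -> STMFit:
    """Maximum-likelihood stochastic-response fit.

    Noise variances are optimized on the log scale (Nelder-Mead) from
    ``n_starts`` data-scaled starting points; ties are broken by the
    highest likelihood then the smallest response-walk variance (the
    likelihood surface is often flat in s2_eta).  ``fixed`` pins any of
    (s2_eps, s2_zeta, s2_eta) to a given value (e.g. 0 for the
    OLS-limit); pass None entries for free parameters.
    """
    ss = build_state_space(I, X, years)
    fixed = fixed if fixed is not None else (None, None, None)
    free_idx = [i for i, f in enumerate(fixed) if f is None]

    var_i = max(float(np.nanvar(ss.I)), 1e-12)
    base = np.log([0.5 * var_i, 1e-4 * var_i, 1e-4 * var_i])
    rng = np.random.default_rng(seed)
    starts = [base]
    scales = [np.log([0.9, 1e-6, 1e-6]), np.log([0.3, 1e-2, 1e-2]),
              np.log([0.7, 1e-5, 1e-1]), np.log([0.7, 1e-1, 1e-5])]
    for s in scales[:max(0, n_starts - 1)]:
        starts.append(np.log(var_i) + s + rng.normal(0, 0.3, 3))

    def unpack(theta_free):
        full = np.empty(3)
        j = 0
        for i in range(3):
            if fixed[i] is None:
                full[i] = np.exp(theta_free[j])
                j += 1
            else:
                full[i] = fixed[i]
        return full

    def neg_ll(theta_free):
        s2 = unpack(theta_free)
        ll = loglikelihood(ss, *s2)
        return np.inf if not np.isfinite(ll) else -ll

    if not free_idx:
        return _fit_given(ss, *[f for f in fixed])

    results = []
    for x0 in starts:
        res = minimize(neg_ll, x0[free_idx], method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6,
                                "fatol": 1e-8})
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise ConvergenceError("no start converged to a finite likelihood")
    # best likelihood, tie-break smallest s2_eta
    def key(r):
        s2 = unpack(r.x)
        return (round(float(r.fun), 6), s2[2])
    best = min(results, key=key)
    if not best.success and best.fun == np.inf:
        g = np.nan
        raise ConvergenceError("optimizer failed", best_params=unpack(best.x),
                               grad_norm=g)
    s2 = unpack(best.x)
    return _fit_given(ss, *s2)


@dataclass
class StabilityTrace:
    years: np.ndarray
    significant: np.ndarray     # zero outside the 95% band of alpha_hat
    onset_year: Optional[int]   # first year after which significance persists


def stability_trace(fit: STMFit) -> StabilityTrace:
    """Per-year significance of alpha_hat and the stability onset.

    A year is significant when 0 lies strictly outside the 95% band
    (bands exactly touching zero count as non-significant).  The onset is
    the earliest year from which every later year is significant; None if
    never significant through the end.
    """
    lo, hi = fit.alpha_lo, fit.alpha_hi
    sig = (lo > 0.0) | (hi < 0.0)
    onset = None
    n = len(sig)
    for i in range(n):
        if np.all(sig[i:]):
            onset = int(fit.years[i])
            break
    return StabilityTrace(fit.years, sig, onset)
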