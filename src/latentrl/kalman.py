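"""Kalman filtering, fixed-interval smoothing, EM fitting and BIC.

The models in this package are linear-Gaussian state-space systems with a
scalar observation, diagonal process noise, a tiny fixed observation noise,
and a time-varying transition acting on the previous state plus a known
exogenous input:

    p_t = H x_t + g_t,            g_t ~ N(0, G)
    x_t = A_t x_{t-1} + d_t + q_t, q_t ~ N(0, diag(Q))

where ``d_t`` folds the input-vector contribution B_t u_t into a known
per-step offset. State dimensions are 2-3, so the per-step cost is tiny;
the loops are JIT-compiled with numba so that EM on tens of thousands of
renditions takes milliseconds per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "StateSpaceModel",
    "FilterResult",
    "SmoothResult",
    "FitResult",
    "kalman_filter",
    "rts_smooth",
    "em_fit",
    "bic",
]

_JITTER = 1e-10


@dataclass
class StateSpaceModel:
    """Concrete time-varying linear-Gaussian system.

    ``A[t]``/``d[t]`` govern the transition into step t (entries at t=0 are
    unused; the initial state is drawn from the prior). ``qdiag`` is the
    diagonal of the process covariance Q and ``G`` the scalar observation
    variance.
    """

    H: np.ndarray           # (n,)
    A: np.ndarray           # (T, n, n)
    d: np.ndarray           # (T, n)
    qdiag: np.ndarray       # (n,)
    G: float
    x1_mean: np.ndarray     # (n,)
    x1_cov: np.ndarray      # (n, n)
    labels: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.H = np.ascontiguousarray(self.H, dtype=float)
        self.A = np.ascontiguousarray(self.A, dtype=float)
        self.d = np.ascontiguousarray(self.d, dtype=float)
        self.qdiag = np.ascontiguousarray(self.qdiag, dtype=float)
        self.x1_mean = np.ascontiguousarray(self.x1_mean, dtype=float)
        self.x1_cov = np.ascontiguousarray(self.x1_cov, dtype=float)
        n = self.H.size
        T = self.A.shape[0]
        if self.A.shape != (T, n, n) or self.d.shape != (T, n):
            raise ValueError("inconsistent state-space dimensions")
        if self.qdiag.shape != (n,) or self.x1_mean.shape != (n,):
            raise ValueError("inconsistent state-space dimensions")
        if np.any(self.qdiag < 0) or not self.G > 0:
            raise ValueError("need qdiag >= 0 and G > 0")

    @property
    def nstates(self) -> int:
        return self.H.size

    @property
    def nobs(self) -> int:
        return self.A.shape[0]

    def simulate(self, rng: np.random.Generator):
        """Draw one sample path; returns (y, x, q) with q the state noises."""
        T, n = self.d.shape
        x = np.zeros((T, n))
        q = rng.normal(0.0, np.sqrt(self.qdiag), size=(T, n))
        x[0] = self.x1_mean + rng.multivariate_normal(np.zeros(n), self.x1_cov)
        for t in range(1, T):
            x[t] = self.A[t] @ x[t - 1] + self.d[t] + q[t]
        y = x @ self.H + rng.normal(0.0, np.sqrt(self.G), size=T)
        return y, x, q


@dataclass
class FilterResult:
    means_pred: np.ndarray
    covs_pred: np.ndarray
    means_filt: np.ndarray
    covs_filt: np.ndarray
    innovations: np.ndarray
    innovation_vars: np.ndarray
    loglik: float


@dataclass
class SmoothResult:
    means: np.ndarray        # (T, n) smoothed state means
    covs: np.ndarray         # (T, n, n)
    lag1_covs: np.ndarray    # (T, n, n); [t] = Cov(x_t, x_{t-1} | y_1..T)
    disturbances: np.ndarray  # (T, n) smoothed means of q_t (t=0: prior resid.)


@dataclass
class FitResult:
    params: dict
    free: tuple
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int
    seed: int | None = None

    @property
    def n_free_params(self) -> int:
        return sum(np.size(self.params[k]) for k in self.free)


@njit(cache=True)
def _filter_core(y, A, d, H, qd, g, x1m, x1P):  # pragma: no cover - jitted
    # explicit small-matrix loops: state dimensions here are 1-4, where
    # BLAS-call and allocation overhead would dominate
    T = y.shape[0]
    n = x1m.shape[0]
    xp = np.zeros((T, n))
    Pp = np.zeros((T, n, n))
    xf = np.zeros((T, n))
    Pf = np.zeros((T, n, n))
    innov = np.zeros(T)
    ivar = np.zeros(T)
    W = np.zeros((n, n))
    M = np.zeros((n, n))
    PH = np.zeros(n)
    K = np.zeros(n)
    ll = 0.0
    for t in range(T):
        if t == 0:
            for i in range(n):
                xp[0, i] = x1m[i]
                for j in range(n):
                    Pp[0, i, j] = 0.5 * (x1P[i, j] + x1P[j, i])
        else:
            for i in range(n):
                acc = d[t, i]
                for j in range(n):
                    acc += A[t, i, j] * xf[t - 1, j]
                xp[t, i] = acc
            # W = A_t @ Pf_{t-1}; Pp_t = W @ A_t' + diag(qd)
            for i in range(n):
                for j in range(n):
                    acc = 0.0
                    for k in range(n):
                        acc += A[t, i, k] * Pf[t - 1, k, j]
                    W[i, j] = acc
            for i in range(n):
                for j in range(i, n):
                    acc = 0.0
                    for k in range(n):
                        acc += W[i, k] * A[t, j, k]
                    if i == j:
                        acc += qd[i]
                    Pp[t, i, j] = acc
                    Pp[t, j, i] = acc
        v = y[t]
        for i in range(n):
            v -= H[i] * xp[t, i]
        s = g
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += Pp[t, i, j] * H[j]
            PH[i] = acc
            s += H[i] * acc
        for i in range(n):
            K[i] = PH[i] / s
            xf[t, i] = xp[t, i] + K[i] * v
        # Joseph form: Pf = (I-KH) Pp (I-KH)' + g K K'
        for i in range(n):
            for j in range(n):
                M[i, j] = (1.0 if i == j else 0.0) - K[i] * H[j]
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for k in range(n):
                    acc += M[i, k] * Pp[t, k, j]
                W[i, j] = acc
        for i in range(n):
            for j in range(i, n):
                acc = g * K[i] * K[j]
                for k in range(n):
                    acc += W[i, k] * M[j, k]
                Pf[t, i, j] = acc
                Pf[t, j, i] = acc
        innov[t] = v
        ivar[t] = s
        ll += -0.5 * (np.log(2.0 * np.pi * s) + v * v / s)
    return xp, Pp, xf, Pf, innov, ivar, ll


@njit(cache=True)
def _smooth_core(A, xf, Pf, xp, Pp, jitter):  # pragma: no cover - jitted
    T, n = xf.shape
    xs = xf.copy()
    Ps = Pf.copy()
    Ms = np.zeros((T, n, n))
    G = np.zeros((n, 2 * n))
    W = np.zeros((n, n))
    J = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        # J = Pf_t A_{t+1}' Pnext^{-1}; solve J Pnext = Pf A' by
        # Gauss-Jordan on the (symmetric, jittered) Pnext
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for k in range(n):
                    acc += Pf[t, i, k] * A[t + 1, j, k]
                W[i, j] = acc  # W = Pf_t A'
        # augmented system Pnext' X = W' -> X = Pnext^{-1} W' ; J = X'
        for i in range(n):
            for j in range(n):
                G[i, j] = Pp[t + 1, i, j]
                G[i, n + j] = W[j, i]
            G[i, i] += jitter
        for col in range(n):
            piv = col
            big = abs(G[col, col])
            for r in range(col + 1, n):
                if abs(G[r, col]) > big:
                    big = abs(G[r, col])
                    piv = r
            if piv != col:
                for cc in range(2 * n):
                    tmp = G[col, cc]
                    G[col, cc] = G[piv, cc]
                    G[piv, cc] = tmp
            pv = G[col, col]
            for cc in range(col, 2 * n):
                G[col, cc] /= pv
            for r in range(n):
                if r != col and G[r, col] != 0.0:
                    f = G[r, col]
                    for cc in range(col, 2 * n):
                        G[r, cc] -= f * G[col, cc]
        for i in range(n):
            for j in range(n):
                J[i, j] = G[j, n + i]
        for i in range(n):
            acc = xf[t, i]
            for j in range(n):
                acc += J[i, j] * (xs[t + 1, j] - xp[t + 1, j])
            xs[t, i] = acc
        # Ps_t = Pf_t + J (Ps_{t+1} - Pp_{t+1}) J'
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for k in range(n):
                    acc += J[i, k] * (Ps[t + 1, k, j] - Pp[t + 1, k, j])
                W[i, j] = acc
        for i in range(n):
            for j in range(i, n):
                acc = 0.0
                for k in range(n):
                    acc += W[i, k] * J[j, k]
                val = Pf[t, i, j] + acc
                Ps[t, i, j] = val
                Ps[t, j, i] = val
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for k in range(n):
                    acc += Ps[t + 1, i, k] * J[j, k]
                Ms[t + 1, i, j] = acc
    return xs, Ps, Ms


def kalman_filter(ssm: StateSpaceModel, y: np.ndarray) -> FilterResult:
    """Forward filter; returns per-step moments and the exact log-likelihood."""
    y = np.ascontiguousarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != ssm.nobs:
        raise ValueError("observation series length mismatch")
    if not np.all(np.isfinite(y)):
        raise ValueError("observations must be finite")
    xp, Pp, xf, Pf, innov, ivar, ll = _filter_core(
        y, ssm.A, ssm.d, ssm.H, ssm.qdiag, float(ssm.G), ssm.x1_mean, ssm.x1_cov
    )
    if not np.isfinite(ll):
        t_bad = int(np.flatnonzero(~np.isfinite(innov) | ~np.isfinite(ivar))[0]) if (
            np.any(~np.isfinite(innov)) or np.any(~np.isfinite(ivar))
        ) else -1
        raise FloatingPointError(f"non-finite filter quantity (t={t_bad})")
    return FilterResult(xp, Pp, xf, Pf, innov, ivar, float(ll))


def rts_smooth(filter_result: FilterResult, ssm: StateSpaceModel) -> SmoothResult:
    """Fixed-interval (RTS) smoother with lag-one covariances and smoothed
    disturbance means for every component of q_t.

    ``lag1_covs[t] = Cov(x_t, x_{t-1} | y)`` uses the exact identity
    ``P_{t,t-1|T} = P_{t|T} J_{t-1}'`` of the linear-Gaussian smoother.
    """
    f = filter_result
    xs, Ps, Ms = _smooth_core(ssm.A, f.means_filt, f.covs_filt, f.means_pred,
                              f.covs_pred, _JITTER)
    T, n = xs.shape
    dist = np.zeros((T, n))
    dist[0] = xs[0] - ssm.x1_mean
    dist[1:] = xs[1:] - np.einsum("tij,tj->ti", ssm.A[1:], xs[:-1]) - ssm.d[1:]
    return SmoothResult(xs, Ps, Ms, dist)


def bic(loglik: float, k_params: int, n_obs: int) -> float:
    """Bayesian information criterion, k ln(n) - 2 loglik (lower is better)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return k_params * np.log(n_obs) - 2.0 * loglik


def em_fit(
    design,
    y: np.ndarray,
    init: dict | None = None,
    free: tuple | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Expectation-maximization fit of a state-space design.

    ``design`` supplies the model family: ``design.init_params(y)``,
    ``design.build(params) -> StateSpaceModel``, and
    ``design.mstep(params, moments, free) -> params`` with closed-form
    expected-complete-data updates. The E-step is :func:`rts_smooth`.
    The log-likelihood trace is non-decreasing up to round-off; a decrease
    beyond 1e-8 (relative) raises, since for these designs the M-step is
    exact.

    With ``free=()`` no parameters move: a single filter pass returns the
    likelihood at ``init``.
    """
    y = np.asarray(y, dtype=float)
    params = dict(design.init_params(y)) if init is None else dict(init)
    if free is None:
        free = tuple(design.default_free)
    trace = []
    converged = False
    it = 0
    if len(free) == 0:
        ssm = design.build(params)
        ll = kalman_filter(ssm, y).loglik
        return FitResult(params, free, ll, np.array([ll]), True, 0, seed)

    for it in range(1, max_iter + 1):
        ssm = design.build(params)
        fr = kalman_filter(ssm, y)
        trace.append(fr.loglik)
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            rel = (cur - prev) / max(1.0, abs(prev))
            if rel < -1e-8:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev:.6f} -> {cur:.6f}"
                )
            if abs(rel) < tol:
                converged = True
                break
        sm = rts_smooth(fr, ssm)
        moments = _moments(sm)
        params = design.mstep(params, moments, free)
    if not converged:
        # max_iter exit: the last M-step moved the parameters past the
        # last recorded likelihood; record the final value so that
        # FitResult.loglik always matches FitResult.params
        trace.append(kalman_filter(design.build(params), y).loglik)
    ll = trace[-1]
    return FitResult(params, tuple(free), float(ll), np.asarray(trace),
                     converged, it, seed)


def _moments(sm: SmoothResult) -> dict:
    """Second-moment sufficient statistics for the M-step."""
    xs, Ps, Ms = sm.means, sm.covs, sm.lag1_covs
    Exx = Ps + np.einsum("ti,tj->tij", xs, xs)
    Exx1 = Ms.copy()
    Exx1[1:] += np.einsum("ti,tj->tij", xs[1:], xs[:-1])
    return {"xs": xs, "Exx": Exx, "Exx1": Exx1, "smooth": sm}
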