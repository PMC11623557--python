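"""Continuous piecewise-linear least squares with free breakpoints.

The compressed representation of a modulating profile is a continuous
n-segment piecewise-linear function

    f(t) = A_k * t + B_k   for  T_{k-1} < t <= T_k,   T_0 = 0,

whose intercepts follow the continuity recurrence
``B_{k+1} = (A_k - A_{k+1}) * T_k + B_k``.  By default the first segment
passes through the origin (``B_1 = 0``); an opt-in free intercept relaxes
this for profiles that do not vanish at t = 0.

Fitting minimizes the sum of squared errors over the full sample grid.
For fixed breakpoints the problem is linear: with hinge basis functions
``phi_k(t) = clip(t, T_{k-1}, T_k) - T_{k-1}`` the model is
``f = B_1 + sum_k A_k * phi_k`` and the slopes come from one least-squares
solve.  The breakpoints themselves are optimized by multi-start SLSQP with
an analytic (envelope-theorem) gradient, strict-ordering constraints, and
deterministic seeded restarts.

Goodness-of-fit metrics: SSE, RMSE = sqrt(SSE/K), the coefficient of
determination R^2, and — for periodic targets — total harmonic distortion
(THD), the ratio of the RMS harmonic content to the fundamental magnitude,
computed by discrete Fourier analysis over an integer-period window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "PiecewiseLinear",
    "FitMetrics",
    "evaluate_pwl",
    "fit_pwl",
    "fit_pwl_fixed_breakpoints",
    "fit_pwl_sequence",
    "compute_metrics",
    "compute_thd",
]

_CONTINUITY_TOL = 1e-10


@dataclass(frozen=True)
class PiecewiseLinear:
    """Continuous piecewise-linear function on [0, T[-1]].

    ``T`` holds the n segment end times (strictly increasing; the last is
    the domain end), ``A`` the n slopes, ``B1`` the first intercept.
    """

    T: np.ndarray
    A: np.ndarray
    B1: float = 0.0

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "A", A)
        if T.ndim != 1 or A.ndim != 1 or len(T) != len(A) or len(T) < 1:
            raise ValueError("T and A must be 1-D arrays of equal length >= 1")
        if np.any(np.diff(T) <= 0) or T[0] <= 0:
            raise ValueError("breakpoints must be strictly increasing and positive")

    @property
    def n(self) -> int:
        return len(self.T)

    @property
    def intercepts(self) -> np.ndarray:
        """All intercepts ``B_k`` via the continuity recurrence."""
        B = np.empty(self.n)
        B[0] = self.B1
        for k in range(1, self.n):
            B[k] = (self.A[k - 1] - self.A[k]) * self.T[k - 1] + B[k - 1]
        return B

    def __call__(self, t):
        return evaluate_pwl(self, t)


def evaluate_pwl(pwl: PiecewiseLinear, t) -> np.ndarray:
    """Evaluate on ``[0, T_n]``; segment k covers the half-open
    interval ``(T_{k-1}, T_k]`` and ``t = 0`` uses segment 1."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > pwl.T[-1] * (1 + 1e-12) + 1e-300):
        raise ValueError("t outside the function domain [0, T_n]")
    idx = np.searchsorted(pwl.T, t, side="left")
    idx = np.minimum(idx, pwl.n - 1)
    B = pwl.intercepts
    return pwl.A[idx] * t + B[idx]


@dataclass(frozen=True)
class FitMetrics:
    """SSE, RMSE, R^2 (None when the target has zero variance) and
    optionally THD."""

    sse: float
    rmse: float
    r2: float | None
    thd: float | None = None


def compute_metrics(y, y_hat) -> FitMetrics:
    """SSE, RMSE and R^2 between observed ``y`` and predicted ``y_hat``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    resid = y - y_hat
    sse = float(resid @ resid)
    rmse = float(np.sqrt(sse / len(y)))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        r2 = 1.0 if sse == 0.0 else None
    else:
        r2 = 1.0 - sse / tss
    return FitMetrics(sse=sse, rmse=rmse, r2=r2)


def compute_thd(y, dt_s: float, fundamental_omega: float,
                rel_tol: float = 1e-6) -> float:
    """Total harmonic distortion of a sampled signal.

    The window ``len(y) * dt_s`` must span an integer number of fundamental
    periods (2*pi/omega); otherwise spectral leakage would corrupt the
    harmonic magnitudes and a ``ValueError`` is raised.  THD is
    ``sqrt(sum_{k>=2} V_k^2) / V_1`` with ``V_k`` the magnitude at the
    k-th harmonic of the fundamental; all harmonics below Nyquist count.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cycles = n * dt_s * fundamental_omega / (2.0 * np.pi)
    m = round(cycles)
    if m < 1 or abs(cycles - m) > rel_tol * max(cycles, 1.0):
        raise ValueError(
            f"window covers {cycles:.6g} fundamental periods; need an integer")
    spec = np.abs(np.fft.rfft(y))
    v1 = spec[m]
    if v1 == 0.0:
        raise ValueError("fundamental component is zero")
    harmonics = spec[2 * m::m]
    return float(np.sqrt(np.sum(harmonics ** 2)) / v1)


# ---------------------------------------------------------------------------
# fitting


def _design_matrix(t, T_full, free_intercept):
    T_prev = np.concatenate(([0.0], T_full[:-1]))
    phi = np.clip(t[:, None], T_prev[None, :], T_full[None, :]) - T_prev[None, :]
    if free_intercept:
        phi = np.hstack([np.ones((len(t), 1)), phi])
    return phi


def fit_pwl_fixed_breakpoints(t, y, T, free_intercept=False):
    """Least-squares slopes for known breakpoints ``T`` (T[-1] = domain end).

    Returns ``(PiecewiseLinear, FitMetrics)``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    T = np.asarray(T, dtype=float)
    coef, y_hat = _solve_slopes(t, y, T, free_intercept)
    if free_intercept:
        B1, A = float(coef[0]), coef[1:]
    else:
        B1, A = 0.0, coef
    return PiecewiseLinear(T=T, A=A, B1=B1), compute_metrics(y, y_hat)


def _solve_slopes(t, y, T_full, free_intercept):
    phi = _design_matrix(t, T_full, free_intercept)
    coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
    return coef, phi @ coef


def _sse_and_grad(t, y, T_int, t_end, free_intercept):
    """SSE at optimal slopes, and its gradient w.r.t. interior breakpoints.

    With the slopes at their least-squares optimum the envelope theorem
    gives ``dSSE/dT_j = -2 (A_j - A_{j+1}) * sum_{t_i > T_j} r_i`` where
    ``r = y - f``.
    """
    T_full = np.concatenate([T_int, [t_end]])
    coef, y_hat = _solve_slopes(t, y, T_full, free_intercept)
    A = coef[1:] if free_intercept else coef
    resid = y - y_hat
    sse = float(resid @ resid)
    # sum of residuals to the right of each interior breakpoint
    rev_cum = np.concatenate([np.cumsum(resid[::-1])[::-1], [0.0]])
    pos = np.searchsorted(t, T_int, side="right")
    tail = rev_cum[pos]
    grad = -2.0 * (A[:-1] - A[1:]) * tail
    return sse, grad


def _initial_breakpoint_sets(t, y, n, rng, restarts):
    """Deterministic pool of interior-breakpoint initializations."""
    t_end = t[-1]
    inits = []
    equal = t_end * np.arange(1, n) / n
    inits.append(equal)
    # curvature-weighted: place knots at quantiles of |second difference|
    if len(y) > 4 and n > 1:
        curv = np.abs(np.diff(y, 2))
        w = curv + curv.mean() + 1e-30
        cdf = np.cumsum(w)
        cdf = cdf / cdf[-1]
        q = np.arange(1, n) / n
        pos = np.interp(q, cdf, t[1:-1])
        if np.all(np.diff(pos) > 0) and pos[0] > 0 and pos[-1] < t_end:
            inits.append(pos)
    while len(inits) < restarts:
        jitter = equal * (1.0 + 0.25 * rng.standard_normal(n - 1))
        jitter = np.sort(np.clip(jitter, t_end * 1e-4, t_end * (1 - 1e-4)))
        if np.all(np.diff(jitter) > t_end * 1e-6):
            inits.append(jitter)
    return inits[:restarts]


def _grid_seed(t, y, n, free_intercept, max_samples=150):
    """Exhaustive breakpoint search on the sample grid for small problems.

    Guarantees the local optimizer starts at (or below) the best
    grid-restricted solution.
    """
    if len(t) > max_samples or n > 3 or n < 2:
        return None
    interior = t[1:-1]
    best_sse, best_T = np.inf, None
    for combo in itertools.combinations(range(len(interior)), n - 1):
        T_int = interior[list(combo)]
        T_full = np.concatenate([T_int, [t[-1]]])
        _, y_hat = _solve_slopes(t, y, T_full, free_intercept)
        r = y - y_hat
        sse = float(r @ r)
        if sse < best_sse:
            best_sse, best_T = sse, T_int
    return best_T


def _split_init(pwl: PiecewiseLinear, t, y, n_target):
    """Refine an m-segment solution into n_target segments by repeatedly
    splitting the segment with the largest residual sum of squares."""
    T = list(pwl.T[:-1])
    bounds = np.concatenate([[0.0], pwl.T])
    y_hat = evaluate_pwl(pwl, t)
    resid2 = (y - y_hat) ** 2
    seg_sse = []
    for k in range(pwl.n):
        mask = (t > bounds[k]) & (t <= bounds[k + 1]) if k else (t <= bounds[1])
        seg_sse.append((resid2[mask].sum(), bounds[k], bounds[k + 1]))
    T_set = sorted(T)
    while len(T_set) < n_target - 1:
        seg_sse.sort(reverse=True)
        sse, lo, hi = seg_sse.pop(0)
        mid = 0.5 * (lo + hi)
        T_set.append(mid)
        seg_sse.append((sse / 2, lo, mid))
        seg_sse.append((sse / 2, mid, hi))
    return np.sort(np.asarray(T_set))


def fit_pwl(t, y, n_segments: int, seed: int = 0, restarts: int = 8,
            free_intercept: bool = False,
            warm_from: PiecewiseLinear | None = None):
    """Fit a continuous n-segment piecewise-linear function, free breakpoints.

    Parameters
    ----------
    t, y : arrays
        Uniformly gridded signal; the domain is ``[0, t[-1]]`` (``t`` is
        shifted so it starts at 0).
    n_segments : int
        Number of linear segments; requires ``len(y) > 2 * n_segments``.
    seed, restarts : int
        Multi-start control.  Restarts draw from equally spaced,
        curvature-weighted and seeded-jitter breakpoint initializations
        (plus an exhaustive grid seed for small problems and the optional
        ``warm_from`` split seed); ties in SSE within 1e-12 are broken by
        lexicographically smaller breakpoints.
    free_intercept : bool
        Allow ``B1 != 0`` (first segment not through the origin).
    warm_from : PiecewiseLinear, optional
        A coarser solution to refine; its largest-error segments are split
        to produce one additional initialization.

    Returns
    -------
    (PiecewiseLinear, FitMetrics)
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if t[0] < 0:
        raise ValueError("fit domain starts at 0; t must be non-negative")
    n = int(n_segments)
    if n < 1:
        raise ValueError("n_segments must be >= 1")
    if len(y) <= 2 * n:
        raise ValueError(f"too few samples ({len(y)}) for {n} segments")
    t_end = float(t[-1])

    if n == 1:
        return fit_pwl_fixed_breakpoints(t, y, np.array([t_end]),
                                         free_intercept)

    rng = np.random.default_rng(seed)
    inits = _initial_breakpoint_sets(t, y, n, rng, restarts)
    grid = _grid_seed(t, y, n, free_intercept)
    if grid is not None and len(grid) == n - 1 and np.all(np.diff(grid) > 0):
        inits.append(grid)
    if warm_from is not None:
        if warm_from.n > n:
            raise ValueError("warm_from must have at most n_segments segments")
        split = _split_init(warm_from, t, y, n)
        if len(split) == n - 1 and np.all(np.diff(split) > 0):
            inits.append(split)

    gap = t_end * 1e-5

    def objective(T_int):
        order = np.argsort(T_int)
        sse, g = _sse_and_grad(t, y, T_int[order], t_end, free_intercept)
        grad = np.empty_like(g)
        grad[order] = g
        return sse, grad

    constraints = [{"type": "ineq",
                    "fun": lambda x, i=i: x[i + 1] - x[i] - gap}
                   for i in range(n - 2)]
    bounds = [(gap, t_end - gap)] * (n - 1)

    best = None  # (sse, T_int)
    for T0 in inits:
        T0 = np.clip(np.sort(T0), gap, t_end - gap)
        res = minimize(objective, T0, jac=True, method="SLSQP",
                       bounds=bounds, constraints=constraints,
                       options={"maxiter": 300, "ftol": 1e-14})
        cand = np.sort(np.clip(res.x, gap, t_end - gap))
        sse, _ = _sse_and_grad(t, y, cand, t_end, free_intercept)
        # also score the raw initialization: SLSQP may wander on kinks
        sse0, _ = _sse_and_grad(t, y, T0, t_end, free_intercept)
        for s, c in ((sse, cand), (sse0, T0)):
            if best is None or s < best[0] - 1e-12 or (
                    abs(s - best[0]) <= 1e-12 and tuple(c) < tuple(best[1])):
                best = (s, c)

    T_full = np.concatenate([best[1], [t_end]])
    # collapse near-duplicate breakpoints, then re-solve
    keep = np.concatenate([[True], np.diff(T_full) > gap / 2])
    if not keep.all():
        T_full = T_full[keep]
    return fit_pwl_fixed_breakpoints(t, y, T_full, free_intercept)


def fit_pwl_sequence(t, y, n_list, seed: int = 0, restarts: int = 8,
                     free_intercept: bool = False):
    """Fit increasing segment counts, warm-starting each from the previous.

    Because each fit scores the split refinement of its predecessor as one
    of its candidate starts, the SSE along an increasing ``n_list`` is
    monotonically non-increasing.  Returns a list of
    ``(PiecewiseLinear, FitMetrics)``.
    """
    out = []
    prev = None
    for n in n_list:
        pwl, m = fit_pwl(t, y, n, seed=seed, restarts=restarts,
                         free_intercept=free_intercept, warm_from=prev)
        prev = pwl
        out.append((pwl, m))
    return out
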