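"""Independent brute-force oracles used to cross-check the optimizers.

These deliberately avoid the package's fitting code paths: the grid
search below enumerates breakpoint placements exhaustively and solves
each candidate by a plain normal-equations least squares on explicit
hinge regressors.
"""

import itertools

import numpy as np


def grid_pwl_sse(t, y, n_segments, free_intercept=False):
    """Exhaustive continuous-PWL least squares with breakpoints restricted
    to the sample locations; returns the best SSE."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    interior = t[1:-1]
    best = np.inf
    combos = (itertools.combinations(range(len(interior)), n_segments - 1)
              if n_segments > 1 else [()])
    for combo in combos:
        T_int = interior[list(combo)]
        T_full = np.concatenate([T_int, [t[-1]]])
        T_prev = np.concatenate([[0.0], T_full[:-1]])
        X = np.clip(t[:, None], T_prev, T_full) - T_prev
        if free_intercept:
            X = np.hstack([np.ones((len(t), 1)), X])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        best = min(best, float(r @ r))
    return best


def triangle_thd():
    """Closed-form THD of an ideal symmetric triangle wave.

    Fourier magnitudes fall off as 1/k^2 over odd harmonics, so
    THD = sqrt(sum_{odd k>=3} k^-4) = sqrt(pi^4/96 - 1).
    """
    return float(np.sqrt(np.pi ** 4 / 96.0 - 1.0))
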