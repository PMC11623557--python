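"""Ground-truth action-potential sources.

Two small excitable-cell ODE models are integrated with a fixed-step RK4
scheme so that every downstream stage of the package (phase extraction,
piecewise-linear compression, tissue coupling) has deterministic inputs:

* FitzHugh–Nagumo (FHN): a two-variable reduction of the Hodgkin–Huxley
  neuron with an excitation variable ``v`` and a recovery variable ``u``.
* Fenton–Karma (FK): a three-variable ventricular model with a
  dimensionless transmembrane potential ``u`` and two gates ``v`` and ``w``.

Externally produced traces (e.g. from detailed biophysical models) enter
through :func:`load_trace` as two-column delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "APTrace",
    "FHNParams",
    "FKParams",
    "IntegrationError",
    "simulate_fhn",
    "simulate_fk",
    "load_trace",
    "write_trace",
]

#: maximum relative jitter tolerated in a "uniform" time grid
_JITTER_TOL = 1e-9


class IntegrationError(RuntimeError):
    """The ODE state became non-finite during integration."""


@dataclass(frozen=True)
class APTrace:
    """A uniformly sampled voltage time series.

    Parameters
    ----------
    t : ndarray
        Sample times in milliseconds, strictly increasing with constant
        spacing (relative jitter below 1e-9).
    v : ndarray
        Voltage at each sample, in millivolts (or the model's native
        dimensionless units; the FM pipeline normalizes either way).
    meta : str
        Free-form provenance label.
    """

    t: np.ndarray
    v: np.ndarray
    meta: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v) or len(t) < 2:
            raise ValueError("trace needs matching 1-D t/v arrays of length >= 2")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if (dt.max() - dt.min()) > _JITTER_TOL * max(dt.mean(), 1e-300):
            raise ValueError("time axis is not uniformly sampled")

    @property
    def dt(self) -> float:
        """Sample spacing in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Total span ``t[-1] - t[0]`` in ms."""
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh–Nagumo constants (classic excitable regime by default).

    The dimensionless FHN time unit is read as one millisecond, which puts
    the stimulated pulse on a ~40 ms scale.  ``duration`` of 38.6 ms at
    ``dt`` = 0.01 ms yields a 3861-point trace.
    """

    a: float = 0.7
    b: float = 0.8
    eps: float = 0.08
    I_stim: float = 1.0
    stim_duration: float = 1.0
    dt: float = 0.01
    duration: float = 38.6

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")


@dataclass(frozen=True)
class FKParams:
    """Fenton–Karma rate/threshold constants.

    Defaults follow the widely used Beeler–Reuter-derived parameter set of
    the original three-variable model; the resulting action potential
    repolarizes within the default 300 ms window (30001 samples at
    dt = 0.01 ms).
    """

    tau_d: float = 0.25
    tau_r: float = 33.33
    tau_si: float = 29.0
    tau_0: float = 12.5
    tau_v_plus: float = 3.33
    tau_v1_minus: float = 1250.0
    tau_v2_minus: float = 19.6
    tau_w_plus: float = 870.0
    tau_w_minus: float = 41.0
    u_c: float = 0.13
    u_v: float = 0.04
    u_csi: float = 0.85
    k: float = 10.0
    I_stim: float = 0.3
    stim_duration: float = 2.0
    dt: float = 0.01
    duration: float = 300.0

    def __post_init__(self):
        for name in ("tau_d", "tau_r", "tau_si", "tau_0", "tau_v_plus",
                     "tau_v1_minus", "tau_v2_minus", "tau_w_plus",
                     "tau_w_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")


def _rk4(rhs, y0, t):
    """Fixed-step classical RK4 over the grid ``t``; raises on blow-up."""
    y = np.empty((len(t), len(y0)))
    y[0] = y0
    h = t[1] - t[0]
    cur = np.asarray(y0, dtype=float)
    for i in range(1, len(t)):
        ti = t[i - 1]
        k1 = rhs(ti, cur)
        k2 = rhs(ti + h / 2, cur + (h / 2) * k1)
        k3 = rhs(ti + h / 2, cur + (h / 2) * k2)
        k4 = rhs(ti + h, cur + h * k3)
        cur = cur + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(cur)):
            raise IntegrationError(
                f"state became non-finite at t = {t[i]:.6g} ms")
        y[i] = cur
    return y


def _time_grid(dt: float, duration: float) -> np.ndarray:
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def simulate_fhn(params: FHNParams = FHNParams(), stim_time: float = 0.0) -> APTrace:
    """Integrate the FitzHugh–Nagumo model under a single stimulus pulse.

    The stimulus current ``I_stim`` is applied for ``stim_duration`` ms
    starting at ``stim_time``; the system starts from its resting fixed
    point, so with ``I_stim = 0`` the trace is constant.
    """
    p = params
    # resting fixed point: v - v^3/3 - u = 0 with u = (v + a)/b
    coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / p.b, -p.a / p.b]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    v0 = float(real[np.argmin(real)])  # lower (resting) branch
    u0 = (v0 + p.a) / p.b

    def rhs(t, y):
        v, u = y
        I = p.I_stim if stim_time <= t < stim_time + p.stim_duration else 0.0
        return np.array([v - v ** 3 / 3.0 - u + I,
                         p.eps * (v + p.a - p.b * u)])

    t = _time_grid(p.dt, p.duration)
    y = _rk4(rhs, np.array([v0, u0]), t)
    return APTrace(t, y[:, 0], meta="fhn")


def _H(x: float) -> float:
    """Heaviside step (1 for x >= 0)."""
    return 1.0 if x >= 0.0 else 0.0


def simulate_fk(params: FKParams = FKParams(), stim_time: float = 0.0) -> APTrace:
    """Integrate the three-variable Fenton–Karma model under one stimulus.

    Returns the dimensionless transmembrane potential ``u`` (0 at rest,
    ~1 at the plateau).
    """
    p = params

    def rhs(t, y):
        u, v, w = y
        above = _H(u - p.u_c)
        below = 1.0 - above
        tau_v_minus = p.tau_v1_minus if u >= p.u_v else p.tau_v2_minus
        J_fi = -(v / p.tau_d) * above * (1.0 - u) * (u - p.u_c)
        J_so = (u / p.tau_0) * below + (1.0 / p.tau_r) * above
        J_si = -(w / (2.0 * p.tau_si)) * (1.0 + np.tanh(p.k * (u - p.u_csi)))
        J_stim = p.I_stim if stim_time <= t < stim_time + p.stim_duration else 0.0
        du = -(J_fi + J_so + J_si) + J_stim
        dv = below * (1.0 - v) / tau_v_minus - above * v / p.tau_v_plus
        dw = below * (1.0 - w) / p.tau_w_minus - above * w / p.tau_w_plus
        return np.array([du, dv, dw])

    t = _time_grid(p.dt, p.duration)
    y = _rk4(rhs, np.array([0.0, 1.0, 1.0]), t)
    return APTrace(t, y[:, 0], meta="fk")


def load_trace(path, time_unit: str = "ms", voltage_column: int = 1) -> APTrace:
    """Read a delimited two-or-more-column text file as an :class:`APTrace`.

    The first column is time (``time_unit`` either ``"ms"`` or ``"s"``),
    ``voltage_column`` selects the voltage column (0-based).  A header line
    is tolerated.  Time must be strictly increasing and uniform to within
    the package jitter tolerance; the grid is then rebuilt exactly uniform
    from the first sample and the mean spacing.
    """
    path = Path(path)
    text = path.read_text()
    rows = []
    for lineno, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if lineno == 0 and not rows:
                continue  # header
            raise ValueError(f"{path}: non-numeric value on line {lineno + 1}")
        rows.append(vals)
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need at least 2 columns")
    if voltage_column >= ncol:
        raise ValueError(f"{path}: voltage column {voltage_column} out of range")
    data = np.array([r[:ncol] for r in rows])
    t = data[:, 0]
    if time_unit == "s":
        t = t * 1000.0
    elif time_unit != "ms":
        raise ValueError("time_unit must be 'ms' or 's'")
    v = data[:, voltage_column]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time axis is not strictly increasing")
    if (dt.max() - dt.min()) > _JITTER_TOL * dt.mean():
        raise ValueError(f"{path}: time axis is not uniformly sampled")
    t_uniform = t[0] + np.arange(len(t)) * dt.mean()
    return APTrace(t_uniform, v, meta=str(path))


def write_trace(trace: APTrace, path) -> None:
    """Write a trace as full-precision two-column CSV (time ms, voltage)."""
    path = Path(path)
    with path.open("w") as fh:
        for ti, vi in zip(trace.t, trace.v):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")
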