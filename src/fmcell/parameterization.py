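"""Blockade parameterization of the modulating-profile coefficients.

A family of action potentials indexed by a blockade fraction
``b = Ifb`` in [0, 1] (e.g. fractional block of the sinoatrial "funny"
current) is compressed as follows: the modulating profile of the reference
level ``b = 0`` is fitted with n free-breakpoint linear segments; those
breakpoints are then *frozen* across the family and only the slopes (and
first intercept) are re-solved per level, so each coefficient traces a
single-valued trajectory A_i(b).  Each trajectory — together with the
carrier frequency omega(b) and intercept B1(b) — is then summarized by a
piecewise-linear fit-type function of b with 3, 4 or 5 pieces (PL3 / PL4 /
PL5) and free interior knots, reusing the same segmented-least-squares
engine with b as the abscissa.  Evaluating the fit-type model at an
arbitrary blockade reassembles the piecewise-linear profile and
reconstructs the action potential through the FM synthesis equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import fm_core
from .pwl_fit import (PiecewiseLinear, fit_pwl, fit_pwl_fixed_breakpoints,
                      fit_pwl_sequence)
from .reference_models import APTrace

__all__ = ["CoefficientFamily", "FitTypeModel", "FIT_KINDS",
           "fit_family", "fit_fittype", "predict_ap", "carrier_at"]

FIT_KINDS = {"PL3": 3, "PL4": 4, "PL5": 5}


@dataclass(frozen=True)
class CoefficientFamily:
    """Per-level piecewise-linear coefficients on a shared breakpoint grid.

    ``A_matrix[i, j]`` is slope ``A_{i+1}`` at blockade ``b_values[j]``;
    ``B1_values`` the per-level first intercepts; ``omega_values`` the
    per-level carrier frequencies (rad/s); carriers hold the per-level
    amplitude, offset (mV) and constant phase (rad); ``t_grid`` the common
    time grid (ms).
    """

    b_values: np.ndarray
    shared_T: np.ndarray          # seconds, domain of the dw(t) fit
    A_matrix: np.ndarray          # (n_segments, n_levels)
    B1_values: np.ndarray
    omega_values: np.ndarray
    carrier_C: np.ndarray
    carrier_offset: np.ndarray
    carrier_phi0: np.ndarray
    t_grid: np.ndarray            # ms

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", b)
        if np.any(np.diff(b) <= 0) or b[0] < 0 or b[-1] > 1:
            raise ValueError("b_values must be strictly increasing in [0, 1]")
        if self.A_matrix.shape != (len(self.shared_T), len(b)):
            raise ValueError("A_matrix shape mismatch")

    @property
    def n_segments(self) -> int:
        return len(self.shared_T)

    @property
    def targets(self) -> dict[str, np.ndarray]:
        """Every scalar series to be modelled against blockade."""
        out = {f"A_{i + 1}": self.A_matrix[i] for i in range(self.n_segments)}
        out["B1"] = self.B1_values
        out["omega"] = self.omega_values
        return out


@dataclass(frozen=True)
class FitTypeModel:
    """Piecewise-linear-in-blockade functions, one per coefficient."""

    kind: str
    models: dict[str, PiecewiseLinear]
    sse: float                     # total across targets

    def coefficient(self, name: str, b: float) -> float:
        return float(self.models[name](min(b, self.models[name].T[-1]))[0])

    def to_json(self) -> str:
        payload = {"kind": self.kind, "sse": self.sse, "targets": {
            name: {"T": list(map(float, m.T)), "A": list(map(float, m.A)),
                   "B1": float(m.B1)}
            for name, m in self.models.items()}}
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FitTypeModel":
        d = json.loads(text)
        models = {name: PiecewiseLinear(np.array(m["T"]), np.array(m["A"]),
                                        m["B1"])
                  for name, m in d["targets"].items()}
        return cls(kind=d["kind"], models=models, sse=d["sse"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "FitTypeModel":
        return cls.from_json(Path(path).read_text())


def _common_grid(traces: list[APTrace]) -> tuple[np.ndarray, list[APTrace]]:
    """Resample all traces onto the first trace's grid if needed."""
    ref = traces[0]
    out = []
    for tr in traces:
        if len(tr) == len(ref) and abs(tr.duration - ref.duration) < 1e-9:
            out.append(tr)
            continue
        if tr.duration < 0.5 * ref.duration or tr.duration > 2.0 * ref.duration:
            raise ValueError("trace durations too dissimilar to resample")
        v = np.interp(ref.t - ref.t[0], tr.t - tr.t[0], tr.v)
        out.append(APTrace(ref.t, v, meta=tr.meta))
    return ref.t, out


def fit_family(traces, n_segments: int, seed: int = 0, restarts: int = 8,
               ) -> CoefficientFamily:
    """Extract and jointly compress the modulating profiles of a family.

    ``traces`` is a list of ``(ifb, APTrace)`` pairs, at least three
    levels.  Breakpoints are optimized on the lowest-blockade level and
    frozen; per-level slopes and intercepts come from linear least squares
    on the frozen breakpoints (fast and uniquely defined).
    """
    if len(traces) < 3:
        raise ValueError("need at least 3 blockade levels")
    order = np.argsort([b for b, _ in traces])
    b_values = np.array([traces[i][0] for i in order], dtype=float)
    t_grid, resampled = _common_grid([traces[i][1] for i in order])

    profiles = [fm_core.extract_modulation(tr) for tr in resampled]
    t_s = fm_core.ms_to_s(t_grid - t_grid[0])

    ref_pwl, _ = fit_pwl(t_s, profiles[0].delta_w, n_segments, seed=seed,
                         restarts=restarts, free_intercept=True)
    shared_T = ref_pwl.T
    n_levels = len(profiles)
    A = np.empty((len(shared_T), n_levels))
    B1 = np.empty(n_levels)
    for j, prof in enumerate(profiles):
        pwl, _ = fit_pwl_fixed_breakpoints(t_s, prof.delta_w, shared_T,
                                           free_intercept=True)
        A[:, j] = pwl.A
        B1[j] = pwl.B1
    return CoefficientFamily(
        b_values=b_values, shared_T=shared_T, A_matrix=A, B1_values=B1,
        omega_values=np.array([p.omega for p in profiles]),
        carrier_C=np.array([p.C for p in profiles]),
        carrier_offset=np.array([p.offset for p in profiles]),
        carrier_phi0=np.array([p.phi0 for p in profiles]),
        t_grid=t_grid)


def fit_fittype(family: CoefficientFamily, kind: str = "PL3",
                seed: int = 0, restarts: int = 8) -> FitTypeModel:
    """Fit PL3/PL4/PL5 blockade laws to every coefficient trajectory.

    Each target series is fitted with a continuous piecewise-linear
    function of b with free interior knots and a free intercept; segment
    counts below the requested one warm-start the fit, so SSE is
    non-increasing from PL3 to PL5 on the same family.
    """
    if kind not in FIT_KINDS:
        raise ValueError(f"kind must be one of {sorted(FIT_KINDS)}")
    n_pieces = FIT_KINDS[kind]
    n_levels = len(family.b_values)
    if n_levels < n_pieces + 1:
        raise ValueError(f"{kind} needs at least {n_pieces + 1} levels")
    models = {}
    total_sse = 0.0
    for name, series in family.targets.items():
        if np.ptp(series) == 0.0:
            # degenerate (constant) target: exact zero-slope fit
            T = np.linspace(family.b_values[-1] / n_pieces,
                            family.b_values[-1], n_pieces)
            models[name] = PiecewiseLinear(T, np.zeros(n_pieces),
                                           B1=float(series[0]))
            continue
        fits = fit_pwl_sequence(family.b_values, series,
                                range(3, n_pieces + 1), seed=seed,
                                restarts=restarts, free_intercept=True)
        pwl, metrics = fits[-1]
        models[name] = pwl
        total_sse += metrics.sse
    return FitTypeModel(kind=kind, models=models, sse=total_sse)


def carrier_at(family: CoefficientFamily, ifb: float):
    """Interpolated carrier ``(C, offset, phi0)`` at a blockade level."""
    b = family.b_values
    return (float(np.interp(ifb, b, family.carrier_C)),
            float(np.interp(ifb, b, family.carrier_offset)),
            float(np.interp(ifb, b, family.carrier_phi0)))


def predict_ap(model: FitTypeModel, shared_T: np.ndarray, ifb: float,
               carrier: tuple[float, float, float], t_grid: np.ndarray):
    """Reconstruct the modulating profile and AP at an arbitrary blockade.

    ``carrier`` is ``(C, offset, phi0)``; ``t_grid`` is in ms.  Returns
    ``(ModulationProfile, APTrace)``.  Raises for ``ifb`` outside [0, 1].
    """
    if not 0.0 <= ifb <= 1.0:
        raise ValueError("ifb must lie in [0, 1]")
    n = len(shared_T)
    A = np.array([model.coefficient(f"A_{i + 1}", ifb) for i in range(n)])
    B1 = model.coefficient("B1", ifb)
    omega = model.coefficient("omega", ifb)
    dw_pwl = PiecewiseLinear(np.asarray(shared_T, dtype=float), A, B1=B1)
    t_s = fm_core.ms_to_s(np.asarray(t_grid) - t_grid[0])
    delta_w = dw_pwl(np.minimum(t_s, dw_pwl.T[-1]))
    C, offset, phi0 = carrier
    profile = fm_core.ModulationProfile(
        t=np.asarray(t_grid, dtype=float), delta_w=delta_w, omega=omega,
        C=C, offset=offset, phi0=phi0, source_meta=f"predicted ifb={ifb}")
    return profile, fm_core.reconstruct(profile)
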