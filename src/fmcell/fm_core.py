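"""The frequency-modulation (FM) transform.

An action potential ``V(t)`` is re-expressed as a single constant-amplitude
sine whose frequency is modulated in time:

    V(t) = C * sin((omega + dw(t)) * t + phi) + offset

The pipeline is

1. :func:`normalize_trace` — map the trace affinely onto [-1, 1], storing
   the amplitude ``C`` and midrange ``offset``;
2. :func:`extract_phase` — invert the sine per sample with a
   branch-corrected (unwrapped) arcsine so the total phase is continuous,
   and subtract the carrier ``omega * t + phi`` to obtain the varying phase
   ``phi_t(t)``;
3. :func:`phase_to_deltaw` — divide by time, ``dw(t) = phi_t(t) / t``, to
   obtain the frequency-modulating factor;
4. :func:`reconstruct` — evaluate the product-form synthesis equation above.

Before any fitting the chain is an exact re-parameterization: composing the
four steps reproduces the input to floating-point accuracy.  Note the
synthesis uses the *product* of instantaneous frequency and time, not the
integral of instantaneous frequency; steps 2–3 are constructed so that this
literal form is self-consistent.

Units: traces carry time in milliseconds; all trigonometric math uses
seconds and rad/s.  :func:`ms_to_s` is the single conversion point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reference_models import APTrace

__all__ = [
    "NormalizedTrace",
    "PhaseProfile",
    "ModulationProfile",
    "ms_to_s",
    "default_omega",
    "normalize_trace",
    "denormalize",
    "extract_phase",
    "phase_to_deltaw",
    "extract_modulation",
    "reconstruct",
    "save_profile",
    "load_profile",
]

MS_PER_S = 1000.0


def ms_to_s(t_ms):
    """Convert a millisecond time array/scalar to seconds."""
    return np.asarray(t_ms, dtype=float) / MS_PER_S


@dataclass(frozen=True)
class NormalizedTrace:
    """A trace mapped onto [-1, 1]: ``v = C * y + offset``."""

    t: np.ndarray          # ms
    y: np.ndarray          # dimensionless, |y| <= 1
    C: float               # mV
    offset: float          # mV
    source_meta: str = ""


@dataclass(frozen=True)
class PhaseProfile:
    """Varying phase ``phi_t(t)`` relative to carrier ``omega * t + phi0``."""

    t: np.ndarray          # ms
    phi_t: np.ndarray      # rad
    phi0: float            # rad
    omega: float           # rad/s
    source_meta: str = ""


@dataclass(frozen=True)
class ModulationProfile:
    """Frequency-modulating factor plus everything needed for synthesis."""

    t: np.ndarray          # ms
    delta_w: np.ndarray    # rad/s
    omega: float           # rad/s
    C: float               # mV
    offset: float          # mV
    phi0: float            # rad
    source_meta: str = ""

    @property
    def composite_frequency(self) -> np.ndarray:
        """Instantaneous frequency ``omega + dw(t)`` in rad/s."""
        return self.omega + self.delta_w


def default_omega(trace_duration_ms: float) -> float:
    """One carrier period per trace: ``omega = 2*pi / duration`` (rad/s)."""
    return 2.0 * np.pi / ms_to_s(trace_duration_ms)


def normalize_trace(trace: APTrace) -> NormalizedTrace:
    """Affinely map a trace onto [-1, 1].

    ``offset`` is the midrange, ``C`` the half-range, ``y = (v - offset)/C``.
    Raises ``ValueError`` for a constant trace (degenerate range).
    """
    vmax, vmin = float(trace.v.max()), float(trace.v.min())
    if vmax <= vmin:
        raise ValueError("constant trace: voltage range is degenerate")
    offset = (vmax + vmin) / 2.0
    C = (vmax - vmin) / 2.0
    y = (trace.v - offset) / C
    return NormalizedTrace(trace.t, y, C, offset, source_meta=trace.meta)


def denormalize(norm: NormalizedTrace) -> APTrace:
    """Invert :func:`normalize_trace`."""
    return APTrace(norm.t, norm.C * norm.y + norm.offset, meta=norm.source_meta)


def _unwrap_arcsin(y: np.ndarray, hysteresis: float = 0.02) -> np.ndarray:
    """Continuous total phase ``theta`` with ``sin(theta) = y`` per sample.

    Each sample's principal arcsine ``p`` admits the solution family
    ``{p + 2*pi*k, (pi - p) + 2*pi*k}``.  The branch is selected by
    tracking the signal's direction: on a rising stretch theta lives on
    the ascending branch (``p + 2*pi*k``), on a falling stretch on the
    descending branch (``pi - p + 2*pi*k``), with ``2*pi*k`` chosen
    nearest the previous sample.  The direction flips only once the
    signal has retreated by more than ``hysteresis`` (in normalized
    units) from its running extremum, so genuine turning points wind the
    phase through the extremum while sub-hysteresis ripple (noise,
    discretization) merely bounces on the current branch.  Near-extremum
    branch choices are otherwise numerically degenerate — both
    candidates almost coincide — and a greedy nearest-candidate rule
    would resolve them by floating-point accident, which breaks the
    sample-to-sample comparability of profiles extracted from families
    of similar traces.  Both branches satisfy the sine identity exactly,
    so the reconstruction round trip is exact regardless.
    """
    p = np.arcsin(np.clip(y, -1.0, 1.0))
    theta = np.empty_like(p)
    theta[0] = p[0]
    two_pi = 2.0 * np.pi

    def assign(i, rising):
        base = p[i] if rising else np.pi - p[i]
        k = np.round((theta[i - 1] - base) / two_pi)
        theta[i] = base + two_pi * k

    rising = True if len(y) < 2 or y[1] >= y[0] else False
    ext_val, ext_idx = y[0], 0
    for i in range(1, len(p)):
        yi = y[i]
        if rising:
            if yi > ext_val:
                ext_val, ext_idx = yi, i
            if yi < ext_val - hysteresis:
                # turning point confirmed: move the post-extremum lag
                # samples onto the descending branch retroactively
                rising = False
                for m in range(ext_idx + 1, i + 1):
                    assign(m, rising)
                ext_val, ext_idx = yi, i
                continue
        else:
            if yi < ext_val:
                ext_val, ext_idx = yi, i
            if yi > ext_val + hysteresis:
                rising = True
                for m in range(ext_idx + 1, i + 1):
                    assign(m, rising)
                ext_val, ext_idx = yi, i
                continue
        assign(i, rising)
    return theta


def extract_phase(norm: NormalizedTrace,
                  omega: float | None = None,
                  phi0: float | None = None) -> PhaseProfile:
    """Extract the varying phase ``phi_t(t)`` from a normalized trace.

    Parameters
    ----------
    omega : rad/s, optional
        Carrier frequency; defaults to one period per trace duration.
    phi0 : rad, optional
        Constant phase.  Defaults to ``arcsin(y[0])`` so that
        ``phi_t`` starts at zero and the synthesis equation reproduces the
        first sample exactly (at ``t = 0`` the modulating term ``dw * t``
        vanishes, so the carrier phase alone must account for ``y[0]``).
    """
    atol = 1e-9
    if np.any(np.abs(norm.y) > 1.0 + atol):
        raise ValueError("|y| > 1: normalization is broken")
    if omega is None:
        omega = default_omega(norm.t[-1] - norm.t[0])
    theta = _unwrap_arcsin(norm.y)
    if phi0 is None:
        phi0 = float(theta[0])
    t_s = ms_to_s(norm.t - norm.t[0])
    phi_t = theta - omega * t_s - phi0
    return PhaseProfile(norm.t, phi_t, float(phi0), float(omega),
                        source_meta=norm.source_meta)


def phase_to_deltaw(phase: PhaseProfile, C: float, offset: float) -> ModulationProfile:
    """Convert a phase profile to the frequency-modulating factor.

    ``dw[i] = phi_t[i] / t[i]`` with time in seconds measured from the
    first sample; the ``t = 0`` sample takes its one-sided limit
    (nearest-neighbor fill from sample 1).
    """
    t_s = ms_to_s(phase.t - phase.t[0])
    delta_w = np.empty_like(phase.phi_t)
    nz = t_s > 0
    delta_w[nz] = phase.phi_t[nz] / t_s[nz]
    if not nz[0]:
        delta_w[0] = delta_w[1] if len(delta_w) > 1 else 0.0
    return ModulationProfile(phase.t, delta_w, phase.omega, float(C),
                             float(offset), phase.phi0,
                             source_meta=phase.source_meta)


def extract_modulation(trace: APTrace,
                       omega: float | None = None,
                       phi0: float | None = None) -> ModulationProfile:
    """Full analysis chain: trace -> normalized -> phase -> dw profile."""
    norm = normalize_trace(trace)
    phase = extract_phase(norm, omega=omega, phi0=phi0)
    return phase_to_deltaw(phase, norm.C, norm.offset)


def reconstruct(profile: ModulationProfile) -> APTrace:
    """Synthesize the trace: ``C * sin((omega + dw) * t + phi0) + offset``.

    The instantaneous frequency multiplies elapsed time directly (product
    form), matching the analysis convention of :func:`phase_to_deltaw`.
    """
    t_s = ms_to_s(profile.t - profile.t[0])
    v = profile.C * np.sin((profile.omega + profile.delta_w) * t_s
                           + profile.phi0) + profile.offset
    return APTrace(profile.t, v, meta=profile.source_meta)


def save_profile(profile: ModulationProfile, path) -> None:
    """Write (t, dw) as CSV plus a JSON sidecar with the carrier header."""
    path = Path(path)
    with path.open("w") as fh:
        for ti, wi in zip(profile.t, profile.delta_w):
            fh.write(f"{float(ti)!r},{float(wi)!r}\n")
    header = {"omega": profile.omega, "C": profile.C,
              "offset": profile.offset, "phi0": profile.phi0,
              "source_meta": profile.source_meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def load_profile(path) -> ModulationProfile:
    """Inverse of :func:`save_profile`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",")
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ModulationProfile(data[:, 0], data[:, 1], header["omega"],
                             header["C"], header["offset"], header["phi0"],
                             source_meta=header.get("source_meta", ""))
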