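"""Shared fixtures: reference traces, reconstructed waveforms, tissue cells
and the blockade-law family.  Session-scoped so the ODE integrations and
segmented fits run once."""

import numpy as np
import pytest

from fmcell import fm_core, simulate_fhn, simulate_fk
from fmcell.dynamics import cell_config_from_trace
from fmcell.pwl_fit import PiecewiseLinear
from fmcell.reference_models import APTrace


@pytest.fixture(scope="session")
def fhn_trace():
    return simulate_fhn()


@pytest.fixture(scope="session")
def fk_trace():
    return simulate_fk()


@pytest.fixture(scope="session")
def fhn_waveform(fhn_trace):
    """FHN action potential passed through the full FM round trip."""
    return fm_core.reconstruct(fm_core.extract_modulation(fhn_trace))


@pytest.fixture(scope="session")
def tissue_cell(fhn_waveform):
    """FHN playback cell resampled to a 0.1 ms tissue step."""
    return cell_config_from_trace(fhn_waveform, dt=0.1)


def smooth_random_trace(rng, n=400, duration_ms=200.0):
    """A random smooth finite trace: band-limited noise via a random
    low-order Fourier sum, offset to an AP-like voltage range."""
    t = np.linspace(0.0, duration_ms, n)
    x = t / duration_ms
    y = np.zeros(n)
    for k in range(1, 6):
        y += rng.normal() * np.sin(np.pi * k * x) / k
        y += rng.normal() * np.cos(np.pi * k * x) / k
    y = 40.0 * y / max(np.abs(y).max(), 1e-12) - 30.0
    return APTrace(t, y, meta="random-smooth")


COEFF_LAW_KNOTS = (0.35, 0.65)
# (start value, slopes of the 3 pieces) per dw segment; chosen so the total
# phase stays monotone for every blockade level
COEFF_LAWS = [
    (0.8, (1.0, -0.6, 0.9)),
    (-1.3, (-1.2, 0.6, -0.9)),
    (0.4, (0.7, 1.4, 0.5)),
    (0.15, (-0.6, 0.4, -0.5)),
]
# single-slope (globally linear in b) variant of the same coefficients
LINEAR_LAWS = [(0.8, 0.6), (-1.3, -0.8), (0.4, 0.9), (0.15, -0.3)]
COEFF_LAW_T = np.array([0.2, 0.45, 0.7, 1.0])  # seconds
COEFF_LAW_B1 = -0.8
# per-sample trace noise (mV): the family stands in for numerically exact
# ODE solutions, so only solver-scale noise is appropriate
COEFF_LAW_NOISE = 0.001


def coeff_law_value(target_idx, b, kinked=True):
    """Evaluate the designed continuous blockade law for one segment."""
    if not kinked:
        start, slope = LINEAR_LAWS[target_idx]
        return start + slope * b
    start, slopes = COEFF_LAWS[target_idx]
    r1, r2 = COEFF_LAW_KNOTS
    if b < r1:
        return start + slopes[0] * b
    v1 = start + slopes[0] * r1
    if b < r2:
        return v1 + slopes[1] * (b - r1)
    return v1 + slopes[1] * (r2 - r1) + slopes[2] * (b - r2)


def make_coeff_law_family(n_levels=11, noise_sigma=COEFF_LAW_NOISE, seed=7,
                          kinked=True):
    """Family of traces whose modulating-profile slopes follow known
    piecewise-linear (or, with ``kinked=False``, linear) blockade laws —
    the recovery oracle.

    Built in canonical form — phi0 = 0 and monotone total phase below one
    full turn — so the analysis chain reproduces the designed profile.
    """
    rng = np.random.default_rng(seed)
    t_ms = np.arange(0.0, 1000.1, 1.0)
    t_s = fm_core.ms_to_s(t_ms)
    omega = 2.0 * np.pi
    out = []
    for b in np.linspace(0.0, 1.0, n_levels):
        A = np.array([coeff_law_value(i, b, kinked)
                      for i in range(len(COEFF_LAWS))])
        dw = PiecewiseLinear(COEFF_LAW_T, A, B1=COEFF_LAW_B1)(
            np.minimum(t_s, COEFF_LAW_T[-1]))
        theta = (omega + dw) * t_s
        assert np.all(np.diff(theta) > 0) and theta[-1] < 2.0 * np.pi
        prof = fm_core.ModulationProfile(t=t_ms, delta_w=dw, omega=omega,
                                         C=40.0, offset=-20.0, phi0=0.0)
        v = fm_core.reconstruct(prof).v
        if noise_sigma > 0:
            v = v + rng.normal(0.0, noise_sigma, len(v))
        out.append((float(b), APTrace(t_ms, v, meta=f"law family b={b:.2f}")))
    return out


@pytest.fixture(scope="session")
def coeff_law_family():
    return make_coeff_law_family()
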