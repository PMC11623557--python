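"""Two-state playback controller for a reconstructed FM cell.

A cell is either resting (S = 1), emitting its resting voltage, or playing
back its stored action-potential waveform (S = 2).  A sensed voltage at or
above the threshold ``V_th`` flips a resting cell into playback; the
waveform then runs for its full length of k samples, during which further
stimuli are ignored (absolute refractoriness by construction), after which
the cell rests again.

Every emitted sample is therefore either ``V_rest`` or a stored waveform
sample — the controller adds no dynamics of its own, which is what makes
wavefront timing in coupled tissue exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_models import APTrace

__all__ = ["CellConfig", "CellState", "step_cell", "run_cell",
           "cell_config_from_trace"]

REST, PLAYBACK = 1, 2


@dataclass(frozen=True)
class CellConfig:
    """Playback table and trigger constants for one FM cell.

    ``waveform`` is the reconstructed AP sampled at the simulation step
    ``dt`` (ms).  ``delta_rest`` records the resting value of the
    frequency-modulating factor for provenance; playback itself reads the
    precomputed table (reconstruction at simulation time would repeat the
    same deterministic arithmetic).
    """

    waveform: np.ndarray
    dt: float
    V_th: float
    V_rest: float
    delta_rest: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("waveform must be a non-empty 1-D array")
        if not np.all(np.isfinite(w)):
            raise ValueError("waveform contains non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.V_rest > self.V_th:
            raise ValueError("V_rest must not exceed V_th")

    @property
    def k(self) -> int:
        """Playback length in samples."""
        return len(self.waveform)


@dataclass(frozen=True)
class CellState:
    S: int = REST
    idx: int = 0


def cell_config_from_trace(trace: APTrace, dt: float | None = None,
                           V_th: float | None = None,
                           V_rest: float | None = None,
                           delta_rest: float = 0.0) -> CellConfig:
    """Build a cell from a reconstructed trace, resampling to ``dt``.

    Defaults: ``dt`` is the trace step; ``V_rest`` is the first waveform
    sample; ``V_th`` sits 10 % of the waveform's full range above rest.
    """
    if dt is None:
        dt = trace.dt
    n = int(np.floor(trace.duration / dt)) + 1
    tt = trace.t[0] + np.arange(n) * dt
    w = np.interp(tt, trace.t, trace.v)
    if V_rest is None:
        V_rest = float(w[0])
    if V_th is None:
        V_th = V_rest + 0.1 * float(w.max() - w.min())
    return CellConfig(waveform=w, dt=float(dt), V_th=float(V_th),
                      V_rest=float(V_rest), delta_rest=float(delta_rest))


def step_cell(cfg: CellConfig, state: CellState, V_in: float):
    """Advance one sample; returns ``(state', V_out)``.

    A resting cell fires iff ``V_in >= V_th`` and then emits
    ``waveform[0]`` immediately.  A playing cell emits the next stored
    sample regardless of ``V_in``; after the k-th sample it rests.
    ``state'.S`` reflects the state *after* the step, so it returns to 1 on
    the step that emits the final playback sample.
    """
    if state.S == PLAYBACK:
        v = float(cfg.waveform[state.idx])
        idx = state.idx + 1
        if idx >= cfg.k:
            return CellState(REST, 0), v
        return CellState(PLAYBACK, idx), v
    if V_in >= cfg.V_th:
        v = float(cfg.waveform[0])
        if cfg.k == 1:
            return CellState(REST, 0), v
        return CellState(PLAYBACK, 1), v
    return CellState(REST, 0), float(cfg.V_rest)


def run_cell(cfg: CellConfig, stim_schedule, duration: float):
    """Drive a single cell with a stimulus schedule on the waveform grid.

    ``stim_schedule`` is a sorted list of ``(time_ms, V_sti)`` pairs; each
    stimulus is applied at the nearest sample of the ``cfg.dt`` grid (it
    snaps, since the controller is discrete).  Between stimuli the sensed
    voltage is ``V_rest``.

    Returns ``(t, V_out, S)``: the time grid, the emitted voltage, and the
    emitting state per sample (2 whenever the sample came from the
    playback table).
    """
    n_steps = int(np.floor(duration / cfg.dt)) + 1
    t = np.arange(n_steps) * cfg.dt
    stim = np.full(n_steps, cfg.V_rest)
    for time_ms, v_sti in stim_schedule:
        i = int(round(time_ms / cfg.dt))
        if 0 <= i < n_steps:
            stim[i] = max(stim[i], v_sti)
    v_out = np.empty(n_steps)
    s_out = np.empty(n_steps, dtype=int)
    state = CellState()
    for i in range(n_steps):
        was_playing = state.S == PLAYBACK
        triggered = (not was_playing) and stim[i] >= cfg.V_th
        state, v = step_cell(cfg, state, stim[i])
        v_out[i] = v
        s_out[i] = PLAYBACK if (was_playing or triggered) else REST
    return t, v_out, s_out
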