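"""Diffusion-coupled FM tissue in one and two dimensions.

Cells sit on a lattice with unit spacing and sense

    V_in[c] = V[c] + D * L(V)[c]

where ``L`` is the 5-point (or 3-point in 1-D) discrete Laplacian with
no-flux boundaries (a missing neighbor contributes the cell's own value)
and ``D`` the diffusion constant.  The diffusion term only *triggers* a
cell's two-state controller: while a cell is playing back its stored
waveform it emits the stored samples unchanged.  This trigger-only
coupling keeps the playback shape invariant, which is what makes the
adjacent-cell conduction delay independent of tissue size.

Dysfunctional ("lesioned") cells never fire and are clamped below resting
voltage, so they repel the wavefront, which must route around them.

Cell indexing is row-major and 1-based: cell 1 is the top-left corner,
cell N^2 the bottom-right of an N x N grid, and the mid cell is
(N^2 + 1) / 2.

Wavefront timing metrics (all in ms): the peak times ``Tp1``, ``Tpmid``,
``TpNN`` at the two corners and the mid cell; the differences
``T_mc1 = |Tp1 - Tpmid|`` and ``T_mNN = |TpNN - Tpmid|``; and the relative
adjacent peak time ``T_adj``, the lag between a stimulated cell's peak and
its orthogonal neighbors' peaks (asserted equal across those neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import CellConfig

__all__ = [
    "TissueConfig",
    "WavefrontMetrics",
    "StabilityError",
    "cell_index_to_rc",
    "mid_cell_index",
    "simulate_tissue",
    "compute_wavefront_metrics",
    "find_dmin",
    "apply_dysfunction",
]


class StabilityError(RuntimeError):
    """The coupled voltage field became non-finite."""


@dataclass(frozen=True)
class TissueConfig:
    """Configuration of a coupled lattice.

    ``shape`` is ``(1, M)`` for a chain or ``(N, N)`` for a sheet.
    ``stim_cells`` holds 1-based row-major cell indices stimulated at
    ``stim_time`` (ms) with voltage ``stim_amplitude`` (defaults to the
    cell threshold).  ``dysfunction_mask`` marks lesioned cells, which are
    clamped at ``clamp_voltage`` (default 5 mV below rest) and never fire.
    """

    shape: tuple[int, int]
    D: float
    cell: CellConfig
    stim_cells: tuple[int, ...]
    stim_time: float = 0.0
    stim_amplitude: float | None = None
    dysfunction_mask: np.ndarray | None = None
    clamp_voltage: float | None = None

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("D must be non-negative")
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError("shape must be positive")
        n = rows * cols
        for c in self.stim_cells:
            if not 1 <= c <= n:
                raise ValueError(f"stimulated cell {c} outside the lattice")
        if self.dysfunction_mask is not None:
            mask = np.asarray(self.dysfunction_mask, dtype=bool)
            object.__setattr__(self, "dysfunction_mask", mask)
            if mask.shape != self.shape:
                raise ValueError("dysfunction mask shape mismatch")
            for c in self.stim_cells:
                r, q = cell_index_to_rc(c, self.shape)
                if mask[r, q]:
                    raise ValueError(f"stimulated cell {c} is dysfunctional")

    @property
    def dt(self) -> float:
        return self.cell.dt


@dataclass(frozen=True)
class WavefrontMetrics:
    """Peak-time metrics; ``None`` marks a probe cell that never fired."""

    Tp1: float | None
    Tpmid: float | None
    TpNN: float | None
    T_mc1: float | None
    T_mNN: float | None
    T_adj: float | None


def cell_index_to_rc(idx: int, shape: tuple[int, int]) -> tuple[int, int]:
    """1-based row-major cell index -> (row, col)."""
    rows, cols = shape
    if not 1 <= idx <= rows * cols:
        raise ValueError(f"cell index {idx} outside {shape} lattice")
    return (idx - 1) // cols, (idx - 1) % cols


def mid_cell_index(shape: tuple[int, int]) -> int:
    """The (N^2 + 1)/2 mid cell (1-based); exact for odd lattices."""
    rows, cols = shape
    return (rows * cols + 1) // 2


def _laplacian(V: np.ndarray) -> np.ndarray:
    """5-point Laplacian with no-flux (edge-replicated) boundaries."""
    p = np.pad(V, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * V)


def simulate_tissue(cfg: TissueConfig, duration: float) -> np.ndarray:
    """Run the coupled lattice; returns voltages of shape (steps, rows, cols).

    Per step: the sensed voltage ``V + D * L(V)`` (plus the stimulus on
    stimulated cells at the stimulus step) feeds every resting cell's
    controller; playing cells emit their next stored sample; lesioned
    cells stay clamped.  Fully deterministic.
    """
    rows, cols = cfg.shape
    cell = cfg.cell
    k = cell.k
    dt = cell.dt
    n_steps = int(np.floor(duration / dt)) + 1
    stim_step = int(round(cfg.stim_time / dt))
    stim_amp = cfg.stim_amplitude if cfg.stim_amplitude is not None else cell.V_th
    clamp = (cfg.clamp_voltage if cfg.clamp_voltage is not None
             else cell.V_rest - 5.0)

    lesion = (cfg.dysfunction_mask if cfg.dysfunction_mask is not None
              else np.zeros(cfg.shape, dtype=bool))
    stim_mask = np.zeros(cfg.shape, dtype=bool)
    for c in cfg.stim_cells:
        stim_mask[cell_index_to_rc(c, cfg.shape)] = True

    V = np.full(cfg.shape, cell.V_rest)
    V[lesion] = clamp
    playing = np.zeros(cfg.shape, dtype=bool)
    idx = np.zeros(cfg.shape, dtype=np.int64)

    record = np.empty((n_steps, rows, cols))
    for s in range(n_steps):
        with np.errstate(invalid="ignore", over="ignore"):
            V_in = V + cfg.D * _laplacian(V)
        if s == stim_step:
            V_in = np.where(stim_mask, np.maximum(V_in, stim_amp), V_in)
        if not np.all(np.isfinite(V_in)):
            raise StabilityError(f"non-finite coupled voltage at step {s} "
                                 f"(t = {s * dt:.6g} ms); D = {cfg.D} too large")
        V_new = np.full(cfg.shape, cell.V_rest)
        # playback continues regardless of input
        was_playing = playing.copy()
        if was_playing.any():
            V_new[was_playing] = cell.waveform[idx[was_playing]]
            idx[was_playing] += 1
            done = was_playing & (idx >= k)
            playing = was_playing & ~done
            idx[done] = 0
        # cells that were resting at the start of the step fire on threshold
        fire = (~was_playing) & (~lesion) & (V_in >= cell.V_th)
        V_new[fire] = cell.waveform[0]
        if k > 1:
            playing = playing | fire
            idx[fire] = 1
        V_new[lesion] = clamp
        record[s] = V_new
        V = V_new
    return record


def _first_peak_times(record: np.ndarray, dt: float, rest_level: np.ndarray):
    """Per-cell time of the first sample attaining the maximum, or NaN for
    cells whose voltage never left its initial level."""
    vmax = record.max(axis=0)
    tp = record.argmax(axis=0) * dt
    fired = vmax > rest_level + 1e-12
    return np.where(fired, tp, np.nan)


def compute_wavefront_metrics(record: np.ndarray, cfg: TissueConfig,
                              ) -> WavefrontMetrics:
    """Wavefront-timing metrics from a simulated voltage record.

    The peak time of a cell is the time of the first sample attaining its
    maximum voltage.  ``T_adj`` is computed from every live, unstimulated
    orthogonal neighbor of the stimulated cell(s) and must agree across
    them to within half a step; disagreement raises ``ValueError``.
    Probe cells that never fire yield ``None`` metrics (non-propagation).
    """
    rows, cols = cfg.shape
    dt = cfg.dt
    lesion = (cfg.dysfunction_mask if cfg.dysfunction_mask is not None
              else np.zeros(cfg.shape, dtype=bool))
    rest_level = np.full(cfg.shape, cfg.cell.V_rest)
    tp = _first_peak_times(record, dt, rest_level)

    def tp_at(cell_idx):
        r, c = cell_index_to_rc(cell_idx, cfg.shape)
        val = tp[r, c]
        return None if np.isnan(val) else float(val)

    n = rows * cols
    Tp1 = tp_at(1)
    Tpmid = tp_at(mid_cell_index(cfg.shape))
    TpNN = tp_at(n)
    T_mc1 = abs(Tp1 - Tpmid) if (Tp1 is not None and Tpmid is not None) else None
    T_mNN = abs(TpNN - Tpmid) if (TpNN is not None and Tpmid is not None) else None

    stim_set = set(cfg.stim_cells)
    lags = []
    for c in cfg.stim_cells:
        r, q = cell_index_to_rc(c, cfg.shape)
        if np.isnan(tp[r, q]):
            continue
        for dr, dq in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, qq = r + dr, q + dq
            if not (0 <= rr < rows and 0 <= qq < cols):
                continue
            nb = rr * cols + qq + 1
            if nb in stim_set or lesion[rr, qq] or np.isnan(tp[rr, qq]):
                continue
            lags.append(abs(tp[r, q] - tp[rr, qq]))
    if not lags:
        T_adj = None
    else:
        if max(lags) - min(lags) >= dt / 2:
            raise ValueError("adjacent peak lags disagree across orthogonal "
                             f"neighbors: {sorted(set(lags))}")
        T_adj = float(lags[0])
    return WavefrontMetrics(Tp1, Tpmid, TpNN, T_mc1, T_mNN, T_adj)


def _propagates(cfg: TissueConfig, duration: float) -> bool:
    """Does any live, unstimulated cell fire?"""
    record = simulate_tissue(cfg, duration)
    rows, cols = cfg.shape
    lesion = (cfg.dysfunction_mask if cfg.dysfunction_mask is not None
              else np.zeros(cfg.shape, dtype=bool))
    stim_mask = np.zeros(cfg.shape, dtype=bool)
    for c in cfg.stim_cells:
        stim_mask[cell_index_to_rc(c, cfg.shape)] = True
    others = ~stim_mask & ~lesion
    return bool((record.max(axis=0)[others] > cfg.cell.V_rest + 1e-12).any())


def find_dmin(cfg_template: TissueConfig, D_bracket: tuple[float, float],
              tol: float = 1e-4, duration: float | None = None) -> float:
    """Smallest diffusion constant supporting cell-to-cell propagation.

    Bisects the propagation predicate (does a neighbor of the stimulated
    cell fire?) on ``D_bracket = (D_fail, D_propagate)``; the returned
    value propagates and lies within ``tol`` of the switch point.
    """
    lo, hi = D_bracket
    if not lo < hi:
        raise ValueError("invalid bracket")
    if duration is None:
        duration = cfg_template.stim_time + 2.5 * cfg_template.cell.k * cfg_template.dt
    if _propagates(replace(cfg_template, D=lo), duration):
        raise ValueError("lower bracket already propagates")
    if not _propagates(replace(cfg_template, D=hi), duration):
        raise ValueError("upper bracket does not propagate")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _propagates(replace(cfg_template, D=mid), duration):
            hi = mid
        else:
            lo = mid
    return hi


def apply_dysfunction(cfg: TissueConfig, region) -> TissueConfig:
    """Mark a rectangular region (or explicit cell list) as dysfunctional.

    ``region`` is either an iterable of 1-based cell indices or a
    ``(row_slice, col_slice)`` pair.  Stimulated cells cannot be lesioned.
    Returns a new config; masks accumulate across calls.
    """
    mask = (cfg.dysfunction_mask.copy() if cfg.dysfunction_mask is not None
            else np.zeros(cfg.shape, dtype=bool))
    if (isinstance(region, tuple) and len(region) == 2
            and all(isinstance(s, slice) for s in region)):
        mask[region] = True
    else:
        for c in region:
            mask[cell_index_to_rc(int(c), cfg.shape)] = True
    return replace(cfg, dysfunction_mask=mask)
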