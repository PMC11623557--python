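"""Diffusion-coupled tissue: propagation, symmetry, metrics, lesions."""

import numpy as np
import pytest

from fmcell.tissue import (StabilityError, TissueConfig, apply_dysfunction,
                           cell_index_to_rc, compute_wavefront_metrics,
                           find_dmin, mid_cell_index, simulate_tissue)

D_FHN = 0.15  # above the 2-cell propagation threshold for the FHN waveform


def tcfg(cell, shape, stim, D=D_FHN, **kw):
    return TissueConfig(shape=shape, D=D, cell=cell, stim_cells=stim, **kw)


def test_cell_indexing_is_row_major_from_top_left():
    assert cell_index_to_rc(1, (15, 15)) == (0, 0)
    assert cell_index_to_rc(225, (15, 15)) == (14, 14)
    assert mid_cell_index((15, 15)) == 113
    assert cell_index_to_rc(113, (15, 15)) == (7, 7)


class TestSimulate:
    def test_zero_coupling_only_stimulated_cell_fires(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 5), (3,), D=0.0)
        rec = simulate_tissue(cfg, 60.0)
        peaked = rec.max(axis=0)[0] > tissue_cell.V_rest + 1e-9
        assert list(peaked) == [False, False, True, False, False]

    def test_chain_wavefront_spreads_outward_from_mid(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 15), (8,))
        rec = simulate_tissue(cfg, 80.0)
        tp = rec.argmax(axis=0)[0]
        # peak times increase monotonically away from the stimulated cell
        assert np.all(np.diff(tp[:8]) < 0) and np.all(np.diff(tp[7:]) > 0)
        np.testing.assert_array_equal(tp, tp[::-1])

    def test_corner_stimulations_are_exact_mirrors(self, tissue_cell):
        c1 = tcfg(tissue_cell, (9, 9), (1,))
        cN = tcfg(tissue_cell, (9, 9), (81,))
        r1 = simulate_tissue(c1, 90.0)
        rN = simulate_tissue(cN, 90.0)
        np.testing.assert_array_equal(r1, rN[:, ::-1, ::-1])

    def test_unstable_field_raises(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 5), (3,), D=1e160)
        rec = simulate_tissue(cfg, 5.0)  # finite inputs merely trigger
        cfg2 = tcfg(tissue_cell, (1, 5), (3,), D=np.inf)
        with pytest.raises(StabilityError, match="step"):
            simulate_tissue(cfg2, 5.0)

    def test_stimulated_lesion_rejected(self, tissue_cell):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(ValueError, match="dysfunctional"):
            tcfg(tissue_cell, (3, 3), (5,), dysfunction_mask=mask)


class TestMetrics:
    def test_single_cell_tissue_degenerate(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 1), (1,), D=0.0)
        m = compute_wavefront_metrics(simulate_tissue(cfg, 60.0), cfg)
        assert m.Tp1 == m.Tpmid == m.TpNN
        assert m.T_mc1 == 0.0 and m.T_mNN == 0.0

    @pytest.mark.parametrize("N", [7, 15])
    def test_mid_stimulation_four_fold_symmetry(self, tissue_cell, N):
        cfg = tcfg(tissue_cell, (N, N), (mid_cell_index((N, N)),))
        m = compute_wavefront_metrics(simulate_tissue(cfg, 40.0 + 3 * N), cfg)
        assert m.Tp1 == m.TpNN
        assert m.T_mc1 == m.T_mNN
        assert m.T_mc1 == pytest.approx(abs(m.Tp1 - m.Tpmid))

    def test_tadj_identical_across_sizes(self, tissue_cell):
        vals = []
        for N in (7, 15, 31):
            cfg = tcfg(tissue_cell, (N, N), (mid_cell_index((N, N)),))
            m = compute_wavefront_metrics(simulate_tissue(cfg, 40 + 3 * N), cfg)
            vals.append(m.T_adj)
        assert max(vals) - min(vals) <= cfg.dt / 2

    def test_line_stimulation_balances_mid_distances(self, tissue_cell):
        N = 9
        line = tuple(i * N + 1 for i in range(N))
        cfg = tcfg(tissue_cell, (N, N), line)
        m = compute_wavefront_metrics(simulate_tissue(cfg, 40 + 3 * N), cfg)
        assert m.T_mc1 == m.T_mNN

    def test_non_propagation_marks_metrics_absent(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 5), (3,), D=0.0)
        m = compute_wavefront_metrics(simulate_tissue(cfg, 60.0), cfg)
        assert m.Tp1 is None and m.T_mc1 is None and m.T_adj is None
        assert m.Tpmid is not None


class TestDmin:
    def test_bisection_matches_dense_sweep(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 2), (1,), D=1.0)
        tol = 1e-4
        d_min = find_dmin(cfg, (1e-3, 1.0), tol=tol)
        # dense-sweep oracle on the same predicate
        from fmcell.tissue import _propagates
        import dataclasses
        grid = np.arange(max(d_min - 10 * tol, 1e-3), d_min + 10 * tol, tol / 2)
        flags = [_propagates(dataclasses.replace(cfg, D=float(D)), 120.0)
                 for D in grid]
        switch = grid[int(np.argmax(flags))]
        assert abs(d_min - switch) <= 2 * tol

    def test_returned_value_brackets_propagation(self, tissue_cell):
        import dataclasses
        from fmcell.tissue import _propagates
        cfg = tcfg(tissue_cell, (1, 2), (1,), D=1.0)
        tol = 1e-4
        d_min = find_dmin(cfg, (1e-3, 1.0), tol=tol)
        assert _propagates(dataclasses.replace(cfg, D=d_min), 120.0)
        assert not _propagates(
            dataclasses.replace(cfg, D=d_min * (1 - 10 * tol)), 120.0)

    def test_invalid_bracket_rejected(self, tissue_cell):
        cfg = tcfg(tissue_cell, (1, 2), (1,), D=1.0)
        with pytest.raises(ValueError, match="propagat"):
            find_dmin(cfg, (0.5, 1.0), tol=1e-3)  # lower end already works

    def test_tadj_non_increasing_in_diffusion(self, tissue_cell):
        cfg2 = tcfg(tissue_cell, (1, 2), (1,), D=1.0)
        d_min = find_dmin(cfg2, (1e-3, 1.0), tol=1e-4)
        vals = []
        for mult in range(1, 11):
            cfg = tcfg(tissue_cell, (1, 9), (5,), D=d_min * mult)
            m = compute_wavefront_metrics(simulate_tissue(cfg, 80.0), cfg)
            vals.append(m.T_adj)
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == vals[-2]  # plateau at high coupling


class TestDysfunction:
    def test_full_mask_never_fires(self, tissue_cell):
        cfg = tcfg(tissue_cell, (3, 3), (), dysfunction_mask=np.ones((3, 3),
                                                                     bool))
        rec = simulate_tissue(cfg, 50.0)
        assert np.all(rec == tissue_cell.V_rest - 5.0)

    def test_lesioning_a_stimulated_cell_rejected(self, tissue_cell):
        cfg = tcfg(tissue_cell, (3, 3), (5,))
        with pytest.raises(ValueError, match="dysfunctional"):
            apply_dysfunction(cfg, (slice(None), slice(None)))

    def test_lesion_region_blocks_firing_and_delays_distal_peak(
            self, tissue_cell):
        N = 17
        mid = mid_cell_index((N, N))
        base = tcfg(tissue_cell, (N, N), (mid,))
        dur = 170.0
        mb = compute_wavefront_metrics(simulate_tissue(base, dur), base)
        one = apply_dysfunction(base, (slice(10, 11), slice(4, N)))
        rec1 = simulate_tissue(one, dur)
        m1 = compute_wavefront_metrics(rec1, one)
        # lesioned cells clamped below rest, never fire
        assert np.all(rec1[:, 10, 4:] == tissue_cell.V_rest - 5.0)
        assert m1.TpNN > mb.TpNN
        assert m1.Tpmid == mb.Tpmid
        assert m1.T_adj == mb.T_adj
        assert m1.Tp1 == mb.Tp1

    def test_two_lesions_delay_both_corners_and_never_speed_up(
            self, tissue_cell):
        N = 17
        mid = mid_cell_index((N, N))
        base = tcfg(tissue_cell, (N, N), (mid,))
        dur = 170.0
        mb = compute_wavefront_metrics(simulate_tissue(base, dur), base)
        one = apply_dysfunction(base, (slice(10, 11), slice(4, N)))
        m1 = compute_wavefront_metrics(simulate_tissue(one, dur), one)
        two = apply_dysfunction(one, (slice(6, 7), slice(0, N - 4)))
        m2 = compute_wavefront_metrics(simulate_tissue(two, dur), two)
        assert m2.Tp1 > m1.Tp1
        for m in (m1, m2):
            assert m.Tp1 >= mb.Tp1 and m.TpNN >= mb.TpNN
            assert m.Tpmid == mb.Tpmid and m.T_adj == mb.T_adj
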