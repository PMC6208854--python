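"""Graphical quantification: plot construction, fitting, comparators."""

import dataclasses

import numpy as np
import pytest

from impflow import (DataError, KineticParams, PlotSeries, TimeGrid,
                     estimate_alpha_P, fit_linear_section, gp_points,
                     gp_terminal_index, gp_to_cbf_exact, cbf_plot_points,
                     mean_to_regional, nims_cumulated_input, simulate_study)
from impflow.tacs import cumulative_integral


def collinear_series(n=10, slope=2.0, intercept=-1.0):
    x = np.linspace(1.0, 5.0, n)
    return PlotSeries(x=x, y=slope * x + intercept,
                      times=np.linspace(0.1, 2.0, n),
                      frame_indices=np.arange(n),
                      excluded=np.array([], dtype=int))


class TestCbfPlotPoints:
    def test_zero_brain_gives_zero_slope(self, microsphere_study):
        s = microsphere_study
        cb0 = s.Cb.with_values(np.zeros(len(s.Cb)))
        pts = cbf_plot_points(s.Cr, cb0, s.l)
        assert np.all(pts.y == 0)
        fit = fit_linear_section(pts, strategy="fixed_window",
                                 window=(5, len(pts) - 1))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_noiseless_points_lie_on_the_flow_line(self, params, grid):
        """Post-bolus points are collinear with slope F, intercept −F/(αP)."""
        s = simulate_study(params, grid, model="microsphere")
        pts = cbf_plot_points(s.Cr, s.Cb, s.l,
                              lambda_lipo=params.lambda_lipo)
        post = pts.times > s.t1
        fit = np.polyfit(pts.x[post], pts.y[post], 1)
        # oracle: exact algebra of the plot identity
        assert fit[0] == pytest.approx(params.F, rel=2e-3)
        assert fit[1] == pytest.approx(-params.F / (params.alpha * params.P),
                                       rel=2e-3)
        resid = pts.y[post] - (fit[0] * pts.x[post] + fit[1])
        assert np.max(np.abs(resid)) < 1e-6 * np.max(np.abs(pts.y[post]))

    def test_lambda_scaling_doubles_y_and_slope(self, microsphere_study,
                                                params):
        s = microsphere_study
        full = cbf_plot_points(s.Cr, s.Cb, s.l, lambda_lipo=0.8)
        half = cbf_plot_points(s.Cr, s.Cb, s.l, lambda_lipo=0.4)
        np.testing.assert_allclose(half.y, 2 * full.y, rtol=1e-12)

    def test_nonpositive_lung_frames_excluded(self, microsphere_study):
        s = microsphere_study
        lv = s.l.values.copy()
        lv[:3] = 0.0
        pts = cbf_plot_points(s.Cr, s.Cb, s.l.with_values(lv))
        assert list(pts.excluded) == [0, 1, 2]
        assert pts.frame_indices[0] == 3

    def test_mismatched_grids_rejected(self, microsphere_study):
        s = microsphere_study
        from impflow import TAC
        other = TAC(s.Cr.times[:-1], s.Cr.values[:-1], s.Cr.unit)
        with pytest.raises(DataError):
            cbf_plot_points(other, s.Cb, s.l)


class TestFitLinearSection:
    def test_exactly_collinear_points(self):
        for strategy, kwargs in (("fixed_window", {"window": (0, 9)}),
                                 ("auto", {})):
            fit = fit_linear_section(collinear_series(), strategy=strategy,
                                     **kwargs)
            assert fit.slope == pytest.approx(2.0)
            assert fit.intercept == pytest.approx(-1.0)
            assert fit.r2 == pytest.approx(1.0)

    def test_auto_excludes_curved_head(self, params, grid):
        """A small brain efflux curves the early plot; auto skips it."""
        p = dataclasses.replace(params, k2=0.15, E=1.0)
        s = simulate_study(p, grid, model="one_tissue")
        pts = cbf_plot_points(s.Cr, s.Cb, s.l, lambda_lipo=p.lambda_lipo)
        fit = fit_linear_section(pts, strategy="auto", r2_threshold=0.9999)
        # oracle: the known-linear tail (last third of the frames)
        n = len(pts)
        tail = slice(2 * n // 3, n)
        oracle = np.polyfit(pts.x[tail], pts.y[tail], 1)
        assert fit.window[0] > pts.frame_indices[0]
        assert fit.slope == pytest.approx(oracle[0], rel=0.05)

    def test_min_start_time_honoured(self):
        pts = collinear_series(n=12)
        fit = fit_linear_section(pts, strategy="auto",
                                 min_start_time=pts.times[4])
        assert fit.window[0] >= 4

    def test_degenerate_x_rejected(self):
        pts = PlotSeries(x=np.ones(6), y=np.arange(6.0),
                         times=np.arange(6.0) + 1,
                         frame_indices=np.arange(6),
                         excluded=np.array([], dtype=int))
        with pytest.raises(DataError):
            fit_linear_section(pts, strategy="fixed_window", window=(0, 5))

    def test_no_linear_window_raises(self):
        rng = np.random.default_rng(3)
        pts = PlotSeries(x=np.linspace(0, 1, 30), y=rng.random(30),
                         times=np.linspace(0.1, 2, 30),
                         frame_indices=np.arange(30),
                         excluded=np.array([], dtype=int))
        with pytest.raises(DataError):
            fit_linear_section(pts, strategy="auto")

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_linear_section(collinear_series(n=2))


class TestAlphaP:
    def test_arithmetic(self):
        fit = dataclasses.replace(
            fit_linear_section(collinear_series()), slope=0.4,
            intercept=-1.6e-4)
        assert estimate_alpha_P(fit) == pytest.approx(2500.0)

    def test_noiseless_simulation_recovers_alpha_P(self, params, grid):
        s = simulate_study(params, grid, model="microsphere")
        pts = cbf_plot_points(s.Cr, s.Cb, s.l, lambda_lipo=params.lambda_lipo)
        post = np.flatnonzero(pts.times > s.t1)
        fit = fit_linear_section(pts, strategy="fixed_window",
                                 window=(int(post[0]), int(post[-1])))
        assert estimate_alpha_P(fit) == pytest.approx(
            params.alpha * params.P, rel=0.01)

    def test_nonnegative_intercept_rejected(self):
        fit = fit_linear_section(collinear_series(intercept=1.0))
        with pytest.raises(DataError):
            estimate_alpha_P(fit)


class TestGPMethod:
    def test_zero_brain_gives_zero_slope(self, microsphere_study):
        s = microsphere_study
        pts = gp_points(s.Cr, s.Cb.with_values(np.zeros(len(s.Cb))))
        fit = fit_linear_section(pts, strategy="fixed_window",
                                 window=(0, len(pts) - 1))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_brain_scaling_doubles_slope(self, microsphere_study):
        s = microsphere_study
        one = gp_points(s.Cr, s.Cb)
        two = gp_points(s.Cr, s.Cb.with_values(2 * s.Cb.values))
        np.testing.assert_allclose(two.y, 2 * one.y, rtol=1e-12)

    def test_underestimates_flow_when_lungs_retain_tracer(self, params,
                                                          grid):
        """F_GP < F whenever κ > 0 — the lung-retention flaw."""
        s = simulate_study(params, grid, model="microsphere")
        assert s.kappa > 0
        f_gp = gp_terminal_index(float(s.Cb.values[-1]), params.P, params.D,
                                 params.lambda_lipo)
        assert f_gp < params.F
        # Eq.-16-style oracle: the deficit is exactly the lung fraction
        assert f_gp == pytest.approx(params.F * (1 - s.kappa), rel=1e-6)

    def test_late_frames_excluded(self, microsphere_study):
        pts = gp_points(microsphere_study.Cr, microsphere_study.Cb)
        assert len(pts.excluded) > 0
        assert pts.excluded.max() == len(microsphere_study.Cr) - 1

    def test_kappa_correction_recovers_flow(self, params, grid):
        """Terminal GP index / (1−κ) equals true F in noiseless simulation."""
        for k_lung in (0.28, 0.5, 0.8, 1.3):
            p = dataclasses.replace(params, k_lung=k_lung)
            s = simulate_study(p, grid, model="microsphere")
            f_gp = gp_terminal_index(float(s.Cb.values[-1]), p.P, p.D,
                                     p.lambda_lipo)
            assert gp_to_cbf_exact(f_gp, s.kappa) == pytest.approx(
                p.F, rel=0.01)

    @pytest.mark.parametrize("kappa,factor", [(0.0, 1.0), (0.5, 2.0)])
    def test_correction_arithmetic(self, kappa, factor):
        assert gp_to_cbf_exact(0.2, kappa) == pytest.approx(0.2 * factor)

    @pytest.mark.parametrize("kappa", [-0.1, 1.0, 1.5])
    def test_invalid_kappa_rejected(self, kappa):
        with pytest.raises(DataError):
            gp_to_cbf_exact(0.2, kappa)


class TestNIMS:
    def test_zero_at_lung_peak(self, microsphere_study, params):
        s = microsphere_study
        L_max = float(s.L.values.max())
        out = nims_cumulated_input(s.L, L_max, params.D, params.P)
        i_peak = int(np.argmax(s.L.values))
        assert out.estimate.values[i_peak] == pytest.approx(0.0, abs=1e-12)

    def test_underestimates_true_cumulated_input(self, params):
        """With κ > 0 the L_max normalisation undershoots the truth at 3 min."""
        grid3 = TimeGrid.default(n_frames=90)  # 3 minutes
        s = simulate_study(params, grid3.refined(10), model="microsphere")
        # independent truth: trapezoid of the simulated arterial curve
        true_cum = cumulative_integral(s.Ca).values
        L_max = float(s.L.values.max())
        out = nims_cumulated_input(s.L, L_max, params.D, params.P)
        assert s.kappa > 0
        assert out.estimate.values[-1] < true_cum[-1]

    def test_dose_substitution_recovers_truth_after_bolus(self, params):
        grid3 = TimeGrid.default(n_frames=90)
        s = simulate_study(params, grid3.refined(10), model="microsphere")
        true_cum = cumulative_integral(s.Ca).values
        out = nims_cumulated_input(s.L, float(s.L.values.max()), params.D,
                                   params.P)
        post = s.L.times > s.t1
        rel = np.abs(out.exact.values[post] - true_cum[post]) / true_cum[post]
        assert rel.max() < 0.01

    def test_bad_lmax_rejected(self, microsphere_study, params):
        with pytest.raises(DataError):
            nims_cumulated_input(microsphere_study.L, 0.0, params.D, params.P)


class TestMeanToRegional:
    def test_uniform_image(self):
        out = mean_to_regional(0.4, np.full((4, 4), 7.0))
        np.testing.assert_allclose(out, 0.4)

    def test_mask_mean_preserved(self):
        rng = np.random.default_rng(4)
        img = rng.random((16, 16)) + 0.1
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        out = mean_to_regional(0.55, img, mask)
        assert out[mask].mean() == pytest.approx(0.55, rel=1e-14)

    def test_two_valued_image(self):
        img = np.array([[1.0, 3.0], [1.0, 3.0]])
        out = mean_to_regional(0.4, img)
        np.testing.assert_allclose(np.unique(out), [0.2, 0.6])

    def test_zero_mean_rejected(self):
        with pytest.raises(DataError):
            mean_to_regional(0.4, np.zeros((3, 3)))
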