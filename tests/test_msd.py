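"""MSD estimation, diffusive-ballistic model fitting, anomalous-exponent
estimation and motion classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dprtrack import (MSDCurve, classify_motion, compute_msd,
                      fit_alpha_loglog, fit_diffusion_ballistic,
                      summarize_motion)
from dprtrack.msd import MotionFit, analyse_trajectory

from conftest import brute_force_msd, make_track, simulate_ensemble
from dprtrack import MotionModel


class TestComputeMSD:
    def test_stationary_track_zero_everywhere(self):
        c = compute_msd(make_track(np.zeros((6, 2))))
        assert np.all(c.msd == 0.0)

    def test_ballistic_closed_form(self):
        xy = np.column_stack([np.arange(5.0), np.zeros(5)])
        c = compute_msd(make_track(xy))
        np.testing.assert_allclose(c.msd, np.arange(1, 5.0) ** 2)

    def test_four_point_worked_example(self):
        # all-ordered-pairs oracle on (0,0),(1,0),(1,1),(3,1):
        # lag1 (1+1+4)/3 = 2; lag2 (2+5)/2 = 3.5; lag3 10
        c = compute_msd(make_track([(0, 0), (1, 0), (1, 1), (3, 1)]))
        np.testing.assert_allclose(c.msd, [2.0, 3.5, 10.0])
        np.testing.assert_array_equal(c.n_pairs, [3, 2, 1])

    def test_gapped_track_uses_present_pairs_only(self):
        tr = make_track([(0, 0), (1, 0), (3, 0)], frames=[0, 1, 3])
        c = compute_msd(tr)
        np.testing.assert_allclose(c.lags, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(c.msd, [1.0, 4.0, 9.0])
        np.testing.assert_array_equal(c.n_pairs, [1, 1, 1])

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            compute_msd(make_track([(0, 0)]))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_oracle(self, data):
        n = data.draw(st.integers(2, 10))
        all_frames = data.draw(
            st.lists(st.integers(0, 14), min_size=n, max_size=n,
                     unique=True))
        frames = np.sort(all_frames)
        coords = data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2 * n,
            max_size=2 * n))
        xy = np.array(coords).reshape(n, 2)
        track = make_track(xy, frames=frames)
        c = compute_msd(track)
        lags, msds, counts = brute_force_msd(track)
        np.testing.assert_allclose(c.lags, lags)
        np.testing.assert_allclose(c.msd, msds, rtol=1e-12, atol=1e-12)
        np.testing.assert_array_equal(c.n_pairs, counts)


def curve(lags, msd):
    lags = np.asarray(lags, dtype=float)
    return MSDCurve(lags=lags, msd=np.asarray(msd, dtype=float),
                    n_pairs=np.full(len(lags), 10, dtype=int))


class TestFitDiffusionBallistic:
    def test_pure_linear_recovers_D(self):
        lags = np.arange(1, 21.0)
        fit = fit_diffusion_ballistic(curve(lags, 0.4 * lags))
        assert fit.D == pytest.approx(0.1, abs=1e-9)
        assert fit.v == pytest.approx(0.0, abs=1e-9)
        assert not fit.directed_flag

    def test_pure_quadratic_recovers_v(self):
        lags = np.arange(1, 21.0)
        fit = fit_diffusion_ballistic(curve(lags, 0.25 * lags ** 2))
        assert fit.v == pytest.approx(0.5, abs=1e-9)
        assert fit.D == pytest.approx(0.0, abs=1e-7)
        assert fit.directed_flag

    def test_all_zero_curve_returns_zeros(self):
        lags = np.arange(1, 11.0)
        fit = fit_diffusion_ballistic(curve(lags, np.zeros(10)))
        assert fit.D == 0.0 and fit.v == 0.0

    def test_fit_range_excludes_long_lags(self):
        lags = np.arange(1, 41.0)
        msd = 0.4 * lags
        msd[lags > 20] += 100.0  # corrupt beyond the fitted range
        fit = fit_diffusion_ballistic(curve(lags, msd), fit_range=20.0)
        assert fit.D == pytest.approx(0.1, abs=1e-9)

    def test_too_few_lags_raises(self):
        with pytest.raises(ValueError):
            fit_diffusion_ballistic(curve([1.0, 2.0], [0.4, 0.8]))

    def test_directed_recovery_median_v(self):
        pairs = simulate_ensemble(
            MotionModel("directed", D=0.01, v=(0.3, 0.0)), 60, 60, 1.0,
            seed=21)
        vs = [fit_diffusion_ballistic(compute_msd(t), 20.0).v
              for t, _ in pairs]
        assert abs(np.median(vs) - 0.3) / 0.3 < 0.1


class TestAlphaLogLog:
    def test_linear_curve_alpha_one(self):
        lags = np.arange(1, 21.0)
        assert fit_alpha_loglog(curve(lags, 3 * lags)) == pytest.approx(1.0)

    def test_quadratic_curve_alpha_two(self):
        lags = np.arange(1, 21.0)
        assert fit_alpha_loglog(
            curve(lags, 3 * lags ** 2)) == pytest.approx(2.0)

    def test_plateauing_curve_matches_regression_oracle(self):
        # independent closed-form OLS oracle on the transformed points
        lags = np.arange(1, 21.0)
        msd = 0.25 * (1 - np.exp(-lags / 3.0))
        alpha = fit_alpha_loglog(curve(lags, msd), lag_fraction=0.25)
        k = 5  # ceil(0.25 * 20)
        x, y = np.log(lags[:k]), np.log(msd[:k])
        slope = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sum((x - x.mean()) ** 2))
        assert alpha < 1.0
        assert alpha == pytest.approx(slope, abs=1e-9)

    def test_all_zero_curve_warns_and_flags_constrained(self):
        lags = np.arange(1, 11.0)
        with pytest.warns(UserWarning):
            alpha = fit_alpha_loglog(curve(lags, np.zeros(10)))
        assert classify_motion(alpha) == "constrained"


class TestClassify:
    @pytest.mark.parametrize("alpha,expected", [
        (1.0, "diffusive"), (2.0, "transported"), (0.4, "constrained"),
        (0.8, "diffusive"), (1.5, "transported"), (0.79, "constrained"),
    ])
    def test_default_bins(self, alpha, expected):
        assert classify_motion(alpha) == expected

    def test_nonfinite_alpha_raises(self):
        with pytest.raises(ValueError):
            classify_motion(float("nan"))


class TestSummarize:
    def _fit(self, cls, v=0.0, directed=False):
        return MotionFit(D=0.01, v=v, sse=0.0, alpha=1.0, motion_class=cls,
                         directed_flag=directed, fit_range=20.0)

    def test_all_diffusive_degenerate_composition(self):
        s = summarize_motion([self._fit("diffusive")] * 4)
        assert s["fractions"] == {"constrained": 0.0, "diffusive": 1.0,
                                  "transported": 0.0}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        classes = ["constrained", "diffusive", "transported"]
        fits = [self._fit(rng.choice(classes)) for _ in range(37)]
        s = summarize_motion(fits)
        assert sum(s["fractions"].values()) == pytest.approx(1.0)
        assert s["n_tracks"] == 37

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_motion([])


def test_speed_estimate_invariant_under_rotation_translation():
    """Fitted v must not change when all trajectories are rotated and
    translated rigidly."""
    pairs = simulate_ensemble(
        MotionModel("directed", D=0.01, v=(0.2, 0.1)), 10, 40, 1.0, seed=9)
    theta = 0.7
    Rm = np.array([[np.cos(theta), -np.sin(theta)],
                   [np.sin(theta), np.cos(theta)]])
    shift = np.array([3.0, -2.0])
    for traj, _ in pairs:
        f0 = analyse_trajectory(traj)
        moved = make_track(traj.xy @ Rm.T + shift, frames=traj.frames)
        f1 = analyse_trajectory(moved)
        assert f1.v == pytest.approx(f0.v, rel=1e-9, abs=1e-12)
        assert f1.alpha == pytest.approx(f0.alpha, rel=1e-9)
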