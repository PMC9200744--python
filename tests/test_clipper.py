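import numpy as np
import pytest

from sasclip import (
    ClipCriteria,
    ExperimentalProfile,
    ProfileSeries,
    build_profile_series,
    duration,
    enumerate_matching_windows,
    evaluate_window,
    fit_scale_offset,
    longest_matching_window,
    make_target_profile,
    normalize_curve,
    debye_intensity,
)
from sasclip.clipper import _batch_window_stats
from sasclip.profile_fit import squared_residual_band

from conftest import random_trajectory


def brute_force_passing_windows(trajectory, exp, criteria, min_length=1):
    """Oracle: recompute every window's fit from raw frames, no prefix sums."""
    rows = [
        normalize_curve(debye_intensity(f, exp.q)).intensity for f in trajectory.frames
    ]
    n = len(rows)
    out = []
    for s in range(n):
        for e in range(s + min_length, n + 1):
            model = np.sum(rows[s:e], axis=0)
            try:
                fit = fit_scale_offset(exp, model, n_models=e - s)
            except ValueError:
                continue
            ok = fit.chi2 < criteria.chi2_max
            if criteria.use_residual_band:
                band = squared_residual_band(fit, exp, criteria.resid_q_max)
                ok = ok and band.value < criteria.resid_max
            if ok:
                out.append((s, e, fit))
    return out


def brute_force_longest(trajectory, exp, criteria):
    wins = brute_force_passing_windows(trajectory, exp, criteria)
    if not wins:
        return None
    best = max(wins, key=lambda w: (w[1] - w[0], -w[0]))
    return best[0], best[1]


def random_exp_profile(rng, trajectory, n_q=10):
    """A loose target: noisy average of a random window of the trajectory."""
    n = trajectory.n_frames
    s = int(rng.integers(0, n))
    e = int(rng.integers(s + 1, n + 1))
    return make_target_profile(
        trajectory,
        (s, e),
        noise_fraction=float(rng.uniform(0.005, 0.05)),
        seed=int(rng.integers(2**31)),
        q=np.linspace(0.02, 0.35, n_q),
    )


class TestProfileSeries:
    def test_single_frame_series(self, rng):
        traj = random_trajectory(rng, n_frames=1)
        exp = random_exp_profile(rng, traj)
        series = build_profile_series(traj, exp)
        expected = normalize_curve(debye_intensity(traj.frames[0], exp.q)).intensity
        np.testing.assert_allclose(series.per_frame[0], expected, rtol=1e-12)

    def test_identical_frames_window_sums(self, rng):
        traj = random_trajectory(rng, n_frames=1)
        frames = tuple(traj.frames * 5)
        from sasclip import Trajectory

        traj5 = Trajectory(frames=frames)
        exp = random_exp_profile(rng, traj5)
        series = build_profile_series(traj5, exp)
        np.testing.assert_allclose(
            series.window_sum(1, 4), 3 * series.per_frame[0], rtol=1e-12
        )

    def test_window_sum_matches_direct_summation(self, rng):
        traj = random_trajectory(rng, n_frames=20)
        exp = random_exp_profile(rng, traj)
        series = build_profile_series(traj, exp)
        for _ in range(20):
            s = int(rng.integers(0, 19))
            e = int(rng.integers(s + 1, 21))
            np.testing.assert_allclose(
                series.window_sum(s, e),
                series.per_frame[s:e].sum(axis=0),
                rtol=1e-10,
            )

    def test_empty_window_rejected(self, rng):
        traj = random_trajectory(rng, n_frames=4)
        series = build_profile_series(traj, random_exp_profile(rng, traj))
        with pytest.raises(ValueError):
            series.window_sum(2, 2)


class TestClipCriteria:
    def test_thresholds_positive(self):
        with pytest.raises(ValueError):
            ClipCriteria(chi2_max=0.0)


class TestEvaluateWindow:
    def test_self_consistent_window_passes(self, rng):
        traj = random_trajectory(rng, n_frames=6)
        exp = make_target_profile(
            traj, (1, 5), noise_fraction=0.0, q=np.linspace(0.02, 0.3, 12)
        )
        series = build_profile_series(traj, exp)
        fit, ok = evaluate_window(series, 1, 5, exp, ClipCriteria())
        assert ok and fit.chi2 == pytest.approx(0.0, abs=1e-16)

    def test_threshold_is_strict(self, rng):
        traj = random_trajectory(rng, n_frames=6)
        exp = random_exp_profile(rng, traj)
        series = build_profile_series(traj, exp)
        fit, _ = evaluate_window(
            series, 0, 6, exp, ClipCriteria(use_residual_band=False)
        )
        # a window whose chi2 exactly equals the threshold must fail
        at_boundary = ClipCriteria(chi2_max=fit.chi2, use_residual_band=False)
        _, ok = evaluate_window(series, 0, 6, exp, at_boundary)
        assert not ok

    def test_passes_flag_matches_no_prefix_oracle(self, rng):
        traj = random_trajectory(rng, n_frames=12)
        exp = random_exp_profile(rng, traj)
        series = build_profile_series(traj, exp)
        criteria = ClipCriteria()
        oracle = {(s, e) for s, e, _ in brute_force_passing_windows(traj, exp, criteria)}
        for s in range(12):
            for e in range(s + 1, 13):
                _, ok = evaluate_window(series, s, e, exp, criteria)
                assert ok == ((s, e) in oracle)


class TestLongestMatchingWindow:
    @pytest.mark.parametrize("band", [False, True])
    def test_agrees_with_brute_force(self, band):
        rng = np.random.default_rng(4242)
        for trial in range(15):
            traj = random_trajectory(rng, n_frames=int(rng.integers(3, 25)))
            exp = random_exp_profile(rng, traj)
            criteria = ClipCriteria(use_residual_band=band)
            series = build_profile_series(traj, exp)
            result = longest_matching_window(series, exp, criteria)
            expected = brute_force_longest(traj, exp, criteria)
            if expected is None:
                assert not result.found
            else:
                assert (result.start_frame, result.end_frame) == expected

    def test_all_identical_passing_frames_full_window(self, rng):
        from sasclip import Trajectory

        base = random_trajectory(rng, n_frames=1)
        traj = Trajectory(frames=tuple(base.frames * 8))
        exp = make_target_profile(
            traj, (0, 8), noise_fraction=0.0, q=np.linspace(0.02, 0.3, 12)
        )
        series = build_profile_series(traj, exp)
        result = longest_matching_window(series, exp, ClipCriteria())
        assert (result.start_frame, result.end_frame) == (0, 8)
        assert result.duration_ns == 16.0

    def test_no_window_found(self, rng):
        traj = random_trajectory(rng, n_frames=8)
        # target from an unrelated trajectory with tiny errors: nothing fits
        other = random_trajectory(rng, n_frames=3, n_beads=9)
        exp = make_target_profile(
            other, (0, 3), noise_fraction=1e-6, seed=1, q=np.linspace(0.02, 0.35, 12)
        )
        series = build_profile_series(traj, exp)
        result = longest_matching_window(
            series, exp, ClipCriteria(chi2_max=1e-6, use_residual_band=False)
        )
        assert not result.found

    def test_min_duration_is_reported_not_enforced(self, rng):
        traj = random_trajectory(rng, n_frames=4)
        exp = make_target_profile(
            traj, (0, 4), noise_fraction=0.0, q=np.linspace(0.02, 0.3, 12)
        )
        series = build_profile_series(traj, exp)
        result = longest_matching_window(
            series, exp, ClipCriteria(min_duration=700.0), frame_interval=2.0
        )
        assert result.found  # 8 ns window still returned
        assert result.meets_min_duration is False

    def test_non_monotone_criterion_counterexample(self, rng):
        # a passing window that contains a failing sub-window: the target is
        # the average of two dissimilar frames, so [0, 2) fits exactly while
        # neither single frame does
        traj = random_trajectory(rng, n_frames=2, n_beads=8)
        exp = make_target_profile(
            traj, (0, 2), noise_fraction=0.0, q=np.linspace(0.02, 0.35, 15)
        )
        series = build_profile_series(traj, exp)
        strict = ClipCriteria(chi2_max=1e-10, use_residual_band=False)
        _, full_ok = evaluate_window(series, 0, 2, exp, strict)
        _, first_ok = evaluate_window(series, 0, 1, exp, strict)
        _, second_ok = evaluate_window(series, 1, 2, exp, strict)
        assert full_ok and not first_ok and not second_ok


class TestEnumerateMatchingWindows:
    def test_identical_frames_combinatorial_count(self, rng):
        from sasclip import Trajectory

        base = random_trajectory(rng, n_frames=1)
        traj = Trajectory(frames=tuple(base.frames * 4))
        exp = make_target_profile(
            traj, (0, 4), noise_fraction=0.0, q=np.linspace(0.02, 0.3, 12)
        )
        series = build_profile_series(traj, exp)
        wins = enumerate_matching_windows(series, exp, ClipCriteria(), min_length=2)
        assert [(s, e) for s, e, _ in wins] == [
            (0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 4),
        ]

    def test_no_passing_window_empty_list(self, rng):
        traj = random_trajectory(rng, n_frames=5)
        other = random_trajectory(rng, n_frames=2, n_beads=9)
        exp = make_target_profile(
            other, (0, 2), noise_fraction=1e-6, seed=2, q=np.linspace(0.02, 0.35, 12)
        )
        series = build_profile_series(traj, exp)
        assert (
            enumerate_matching_windows(
                series, exp, ClipCriteria(chi2_max=1e-8, use_residual_band=False)
            )
            == []
        )

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(777)
        for trial in range(8):
            traj = random_trajectory(rng, n_frames=int(rng.integers(3, 15)))
            exp = random_exp_profile(rng, traj)
            criteria = ClipCriteria()
            series = build_profile_series(traj, exp)
            got = enumerate_matching_windows(series, exp, criteria, min_length=2)
            expected = brute_force_passing_windows(traj, exp, criteria, min_length=2)
            assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in expected]
            for (_, _, f1), (_, _, f2) in zip(got, expected):
                assert f1.chi2 == pytest.approx(f2.chi2, rel=1e-9)


class TestDuration:
    @pytest.mark.parametrize(
        "start, end, interval, expected",
        [
            (0, 1345, 2.0, 2690.0),  # the worked Table-1 row
            (0, 1, 2.0, 2.0),
            (0, 350, 2.0, 700.0),  # the minimum-duration boundary
            (100, 600, 2.0, 1000.0),
        ],
    )
    def test_values(self, start, end, interval, expected):
        assert duration(start, end, interval) == expected

    def test_empty_window(self):
        with pytest.raises(ValueError):
            duration(5, 5)


class TestBatchStats:
    def test_batch_matches_single_fits(self, rng):
        traj = random_trajectory(rng, n_frames=10)
        exp = random_exp_profile(rng, traj, n_q=14)
        series = build_profile_series(traj, exp)
        S = np.array([series.window_sum(s, s + 3) for s in range(7)])
        chi2, band, _, c, offs = _batch_window_stats(S, exp, ClipCriteria())
        for k in range(7):
            fit = fit_scale_offset(exp, S[k])
            assert chi2[k] == pytest.approx(fit.chi2, rel=1e-9)
            assert c[k] == pytest.approx(fit.c, rel=1e-9)
            assert band[k] == pytest.approx(
                squared_residual_band(fit, exp, 0.25).value, rel=1e-9
            )
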