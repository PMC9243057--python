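"""IdPhi kinematics chain, VTE classification, and pass segmentation."""
import numpy as np
import pytest

from conftest import pass_kinematics
from vtesync.synthetic import TrajectoryParams, simulate_pass
from vtesync.trajectory import (
    IdPhiParams,
    PositionTrack,
    Rect,
    adaptive_derivative,
    analyze_track,
    classify_vte,
    compute_idphi,
    compute_phi,
    segment_passes,
    smooth_track,
    zln_scores,
)


class TestSmoothTrack:
    def test_constant_track_unchanged(self):
        t = np.arange(50) / 30
        track = PositionTrack(t, np.full(50, 3.0), np.full(50, -2.0))
        sm = smooth_track(track, 30)
        np.testing.assert_allclose(sm.x, 3.0)
        np.testing.assert_allclose(sm.y, -2.0)

    def test_window_one_is_identity(self, rng):
        t = np.arange(40) / 30
        x = rng.normal(size=40)
        sm = smooth_track(PositionTrack(t, x, x), 1)
        np.testing.assert_array_equal(sm.x, x)

    def test_noise_variance_reduced(self, rng):
        t = np.arange(300) / 30
        clean = np.sin(2 * np.pi * 0.3 * t)
        noisy = clean + rng.normal(0, 0.5, len(t))
        sm = smooth_track(PositionTrack(t, noisy, noisy), 30)
        assert np.var(sm.x - clean) < np.var(noisy - clean)

    def test_length_preserved_and_edges_renormalized(self):
        t = np.arange(10) / 30
        track = PositionTrack(t, np.ones(10), np.ones(10))
        sm = smooth_track(track, 30)
        assert len(sm) == 10
        np.testing.assert_allclose(sm.x, 1.0)  # truncated kernel still sums to 1


class TestAdaptiveDerivative:
    def test_linear_signal_exact_slope(self):
        t = np.arange(60) / 30
        for tol in (0.01, 1.0, 100.0):
            d = adaptive_derivative(2 * t, t, tolerance=tol)
            np.testing.assert_allclose(d, 2.0, atol=1e-9)

    def test_constant_signal_zero_slope(self):
        t = np.arange(30) / 30
        np.testing.assert_allclose(
            adaptive_derivative(np.full(30, 7.0), t, 0.1), 0.0, atol=1e-12)

    def test_quadratic_matches_central_differences(self):
        """On t^2 the adaptive slope tracks 2t within 5% away from edges."""
        t = np.arange(90) / 30
        v = t**2
        d = adaptive_derivative(v, t, tolerance=0.01)
        central = np.gradient(v, t)
        interior = slice(10, -10)
        np.testing.assert_allclose(d[interior], central[interior], rtol=0.05)

    def test_rejects_non_increasing_time(self):
        t = np.array([0.0, 0.1, 0.1, 0.2])
        with pytest.raises(ValueError, match="strictly increasing"):
            adaptive_derivative(t, t, 0.1)


class TestComputePhi:
    @pytest.mark.parametrize("dx, dy, expected",
                             [(1, 0, 0.0), (0, 1, np.pi / 2), (-1, 0, np.pi)])
    def test_atan2_convention(self, dx, dy, expected):
        phi, _ = compute_phi(np.array([float(dx)]), np.array([float(dy)]))
        assert phi[0] == pytest.approx(expected)

    def test_unwrap_spans_three_turns(self):
        angles = np.linspace(0, 6 * np.pi, 400)
        phi, _ = compute_phi(np.cos(angles), np.sin(angles))
        assert phi[-1] - phi[0] == pytest.approx(6 * np.pi, abs=1e-9)
        assert np.all(np.abs(np.diff(phi)) < np.pi)

    def test_wrapped_output_matches_pointwise_atan2(self, rng):
        heading = np.cumsum(rng.normal(0, 0.3, 200))
        dx, dy = np.cos(heading), np.sin(heading)
        phi, _ = compute_phi(dx, dy)
        wrapped = np.angle(np.exp(1j * phi))
        np.testing.assert_allclose(wrapped, np.arctan2(dy, dx), atol=1e-9)

    def test_zero_velocity_carried_forward_and_flagged(self):
        dx = np.array([1.0, 0.0, 1.0])
        dy = np.array([1.0, 0.0, -1.0])
        phi, flagged = compute_phi(dx, dy)
        assert flagged
        assert phi[1] == pytest.approx(phi[0])


class TestComputeIdphi:
    def test_ballistic_matches_analytic_heading_change(self, geometry):
        cp, truth, _ = pass_kinematics("ballistic", 3, 0.0, geometry)
        assert abs(cp.idphi - truth) < 0.3

    def test_sweep_minus_ballistic_matches_truth_difference(self, geometry):
        sweep = TrajectoryParams(seed=5, sweep_count=1, noise_sd=0.0)
        cp_s, truth_s, _ = pass_kinematics("vte_sweep", 5, 0.0, geometry)
        cp_b, truth_b, _ = pass_kinematics("ballistic", 5, 0.0, geometry)
        measured = cp_s.idphi - cp_b.idphi
        expected = truth_s - truth_b
        assert measured == pytest.approx(expected, rel=0.2)

    def test_rate_invariance_under_resampling(self, geometry):
        """Doubling the sampling rate changes IdPhi by < 5%."""
        t, x, y, _ = simulate_pass(TrajectoryParams(seed=2), "vte_sweep")
        t2 = np.linspace(t[0], t[-1], 2 * len(t) - 1)
        x2, y2 = np.interp(t2, t, x), np.interp(t2, t, y)
        p = IdPhiParams()
        p2 = IdPhiParams(smooth_window=60, min_window=6, max_window=30)
        a = compute_idphi(t, x, y, p).idphi
        b = compute_idphi(t2, x2, y2, p2).idphi
        assert abs(a - b) / a < 0.05

    def test_too_short_pass_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_idphi(np.array([0.0, 0.1]), np.zeros(2), np.zeros(2))

    def test_idphi_nonnegative(self, pass_batch):
        for noise, records in pass_batch.items():
            assert all(r["idphi"] >= 0 for r in records)


class TestClassifyVte:
    def test_zln_textbook_values(self):
        """ln scores {1,2,3} z-score to {-1,0,1}; one trial crosses 0."""
        z, _ = zln_scores(np.exp([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)
        labels = classify_vte(np.exp([1.0, 2.0, 3.0]))
        assert [lab.is_vte for lab in labels] == [False, False, True]

    def test_scale_invariance(self, rng):
        scores = rng.lognormal(0, 1, 40)
        a = [lab.is_vte for lab in classify_vte(scores)]
        b = [lab.is_vte for lab in classify_vte(scores * 37.2)]
        assert a == b

    def test_zln_standardized(self, rng):
        z, _ = zln_scores(rng.lognormal(0, 1, 100))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_identical_scores_refused(self):
        with pytest.raises(ValueError, match="identical"):
            classify_vte(np.full(10, 2.5))

    def test_zero_idphi_floored_and_flagged(self):
        labels = classify_vte(np.array([0.0, 1.0, 2.0, 3.0]))
        assert "idphi_floored" in labels[0].qc_flags
        assert np.isfinite(labels[0].zln_idphi)

    def test_union_rule_head_sweep_only_adds(self, rng):
        scores = rng.lognormal(0, 1, 30)
        sweeps = rng.random(30) < 0.3
        with_hs = classify_vte(scores, head_sweep=sweeps)
        without = classify_vte(scores)
        n_with = sum(lab.is_vte for lab in with_hs)
        n_without = sum(lab.is_vte for lab in without)
        assert n_with >= n_without
        for lab, hs in zip(with_hs, sweeps):
            assert lab.is_vte == (lab.is_vte_idphi or bool(hs))


class TestHeadSweep:
    def test_sweep_pass_detected(self, geometry):
        _, _, swept = pass_kinematics("vte_sweep", 7, 0.0, geometry)
        assert swept

    def test_ballistic_pass_not_detected(self, geometry):
        _, _, swept = pass_kinematics("ballistic", 7, 0.0, geometry)
        assert not swept

    def test_pause_pass_not_detected(self, geometry):
        _, _, swept = pass_kinematics("vte_pause", 7, 0.0, geometry)
        assert not swept

    def test_excursion_outside_choice_point_rejected(self, geometry):
        """An arm-entering excursion beyond the search box is not a sweep."""
        from vtesync.trajectory import detect_head_sweep

        cp, _, _ = pass_kinematics("ballistic", 9, 0.0, geometry)
        # plant a deep excursion into the left arm (outside the box) before
        # the committed right-arm run
        x = cp.raw_x.copy()
        committed = geometry.in_arm(cp.x, cp.y) & ~geometry.search_box.contains(cp.x, cp.y)
        commit_at = int(np.argmax(committed))
        x[commit_at - 3] = geometry.left_arm.x_min + 1.0  # far outside the box
        cp.raw_x = x
        swept, flags = detect_head_sweep(cp, geometry)
        assert not swept
        assert "sweep_outside_choice_point" in flags


class TestSegmentation:
    def test_session_pass_count_and_arms(self, small_cohort):
        s = small_cohort[0]
        passes, labels = analyze_track(s.position, s.geometry,
                                       expected_trials=len(s.truth))
        assert len(passes) == len(s.truth)
        assert [p.exit_arm for p in passes] == [t.arm for t in s.truth]

    def test_no_crossing_warns_and_returns_empty(self, geometry):
        t = np.arange(100) / 30
        track = PositionTrack(t, np.full(100, 30.0), np.linspace(-30, 30, 100))
        with pytest.warns(UserWarning, match="never crosses"):
            assert segment_passes(track, geometry) == []

    def test_trial_count_mismatch_is_hard_error(self, small_cohort):
        s = small_cohort[0]
        with pytest.raises(ValueError, match="metadata"):
            analyze_track(s.position, s.geometry, expected_trials=len(s.truth) + 3)


class TestLabelRecovery:
    @pytest.mark.parametrize("noise, min_accuracy", [(0.0, 1.0), (0.5, 0.9)])
    def test_generator_labels_recovered(self, pass_batch, noise, min_accuracy):
        """zlnIdPhi>0 plus head-sweep union recovers planted pass types."""
        records = pass_batch[noise]
        labels = classify_vte(
            np.array([r["idphi"] for r in records]),
            head_sweep=np.array([r["swept"] for r in records]),
        )
        truth = np.array([r["vte"] for r in records])
        pred = np.array([lab.is_vte for lab in labels])
        assert (pred == truth).mean() >= min_accuracy


def test_geometry_rejects_overlapping_arms():
    from vtesync.trajectory import ChoicePointRegion

    with pytest.raises(ValueError, match="disjoint"):
        ChoicePointRegion(
            choice=Rect(-5, 5, -5, 5),
            left_arm=Rect(-30, 1, -5, 5),
            right_arm=Rect(-1, 30, -5, 5),
        )
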