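"""Tracking-pipeline unit tests with independent oracles: brute-force
neighbour counts, circumcircle geometry, analytic MSD laws, hand-evaluated
torque, percentile arithmetic."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoturbine import synth, track
from nanoturbine.synth import LocalizationSet

from conftest import circle_points, make_rotor_locs


def locs_from_xy(xy, uncertainty=10.0, frame_rate=200.0, frames=None):
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(xy)) if frames is None else frames,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "uncertainty": np.broadcast_to(uncertainty, len(xy)).copy(),
        }
    )
    return LocalizationSet(df, frame_rate)


class TestUncertaintyFilter:
    def test_strictly_below_threshold(self):
        locs = locs_from_xy(np.zeros((5, 2)), uncertainty=[10, 20, 49.9, 50, 60])
        kept = track.filter_by_uncertainty(locs, 50.0)
        assert len(kept) == 3
        np.testing.assert_array_equal(kept.uncertainty, [10, 20, 49.9])

    def test_empty_and_identity(self):
        empty = LocalizationSet.empty()
        assert len(track.filter_by_uncertainty(empty)) == 0
        locs = locs_from_xy(np.zeros((4, 2)), uncertainty=5.0)
        kept = track.filter_by_uncertainty(locs)
        pd.testing.assert_frame_equal(kept.data, locs.data)


class TestDensityFilter:
    def test_isolated_record_removed(self):
        xy = np.vstack([np.zeros((20, 2)), [[1e5, 1e5]]])
        kept = track.filter_by_density(locs_from_xy(xy))
        assert len(kept) == 20

    def test_coincident_records_kept(self):
        kept = track.filter_by_density(locs_from_xy(np.zeros((16, 2))))
        assert len(kept) == 16  # each has exactly 15 neighbours

    def test_matches_brute_force_on_random_cloud(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 500, size=(500, 2))
        radius = 37.0
        kept = track.filter_by_density(locs_from_xy(xy), min_neighbors=5, radius=radius)
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        neigh = (d <= radius).sum(axis=1) - 1  # exclude self
        np.testing.assert_array_equal(np.sort(kept.xy, axis=0), np.sort(xy[neigh >= 5], axis=0))


class TestClustering:
    def test_two_circles_give_two_clusters(self):
        rng = np.random.default_rng(1)
        a = circle_points(1000, 150, center=(0, 0), rng=rng, noise=10)
        b = circle_points(1000, 150, center=(1000.0, 0), rng=rng, noise=10)
        clusters = track.cluster_localizations(locs_from_xy(np.vstack([a, b])))
        assert len(clusters) == 2
        centers = sorted(c.xy.mean(axis=0)[0] for c in clusters)
        assert centers[0] == pytest.approx(0.0, abs=20)
        assert centers[1] == pytest.approx(1000.0, abs=20)

    def test_too_few_points_no_clusters(self):
        assert track.cluster_localizations(locs_from_xy(np.zeros((10, 2)))) == []

    def test_single_dense_cluster(self):
        pts = circle_points(500, 150, noise=10)
        clusters = track.cluster_localizations(locs_from_xy(pts))
        assert len(clusters) == 1
        assert len(clusters[0]) == 500


class TestCircleFit:
    def test_circumcircle(self):
        c = track.fit_circle(np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]))
        assert c.center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert c.radius == pytest.approx(1.0, rel=1e-12)

    @given(
        cx=st.floats(-1e4, 1e4),
        cy=st.floats(-1e4, 1e4),
        r=st.floats(1e-2, 1e4),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_exact_on_noiseless_circles(self, cx, cy, r, seed):
        pts = circle_points(25, r, center=(cx, cy), rng=np.random.default_rng(seed))
        c = track.fit_circle(pts)
        assert c.radius == pytest.approx(r, rel=1e-9)
        assert c.center[0] == pytest.approx(cx, abs=max(1e-9 * r, 1e-9))
        assert c.center[1] == pytest.approx(cy, abs=max(1e-9 * r, 1e-9))

    def test_noisy_radius_recovery(self):
        pts = circle_points(2000, 150.0, rng=np.random.default_rng(5), noise=15.0)
        c = track.fit_circle(pts)
        assert c.radius == pytest.approx(150.0, rel=0.02)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(track.CircleFitError):
            track.fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        line = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(track.CircleFitError):
            track.fit_circle(line)


class TestAnnulusValidity:
    def test_points_on_circle_are_valid(self):
        pts = circle_points(1000, 150.0)
        c = track.Circle(center=(0, 0), radius=150.0)
        valid, rho_a, rho_c = track.annulus_validity(pts, c)
        assert valid and rho_c == 0.0 and rho_a > 0

    def test_points_at_center_are_invalid(self):
        pts = np.zeros((1000, 2))
        c = track.Circle(center=(0, 0), radius=150.0)
        valid, rho_a, rho_c = track.annulus_validity(pts, c)
        assert not valid and rho_a == 0.0

    def test_uniform_disk_has_no_annular_enrichment(self):
        # under a uniform null the annulus and the equal-area central disk
        # have identical expected densities; check agreement within
        # Poisson error at n = 1e5 (so the test statistic is centred,
        # i.e. a uniform cloud carries no evidence of circular motion)
        rng = np.random.default_rng(2)
        n = 100_000
        r = 150.0 * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        c = track.fit_circle(pts)
        _, rho_a, rho_c = track.annulus_validity(pts, c)
        area = 4 * math.pi * c.radius * 1.0
        n_a, n_c = rho_a * area, rho_c * area
        assert abs(n_a - n_c) < 5 * math.sqrt(n_a + n_c)

    def test_tie_is_invalid(self):
        c = track.Circle(center=(0, 0), radius=100.0)
        valid, rho_a, rho_c = track.annulus_validity(np.empty((0, 2)), c)
        assert not valid and rho_a == rho_c == 0.0

    def test_degenerate_circle_reports_invalid(self):
        c = track.Circle(center=(0, 0), radius=0.5)
        valid, *_ = track.annulus_validity(np.zeros((10, 2)), c, half_width=1.0)
        assert not valid


class TestCumulativeAngle:
    CIRCLE = track.Circle(center=(0.0, 0.0), radius=1.0)

    @staticmethod
    def on_circle(degs):
        th = np.radians(degs)
        return np.column_stack([np.cos(th), np.sin(th)])

    def test_simple_quarter_turns(self):
        traj = track.extract_cumulative_angle(self.on_circle([0, 90, 180]), self.CIRCLE, 1.0)
        np.testing.assert_allclose(traj.cum_angle, [0, math.pi / 2, math.pi], atol=1e-12)

    def test_wrap_through_180(self):
        traj = track.extract_cumulative_angle(self.on_circle([0, 170, -170]), self.CIRCLE, 1.0)
        np.testing.assert_allclose(
            traj.cum_angle, np.radians([0, 170, 190]), atol=1e-12
        )

    def test_noiseless_drift_is_exactly_linear(self, acq_clean):
        locs, truth = make_rotor_locs(omega_rev=5.0, D_r=0.0, acq=acq_clean)
        circle = track.fit_circle(locs.xy)
        traj = track.extract_cumulative_angle(locs.xy, circle, acq_clean.frame_rate)
        expected = truth.omega_d * traj.times
        np.testing.assert_allclose(traj.cum_angle, expected, atol=1e-6)
        # ~200 rotations over the ~40 s acquisition at 5 rev/s
        assert traj.net_displacement / (2 * math.pi) == pytest.approx(200, rel=0.01)

    def test_long_gap_keeps_longest_segment(self):
        frames = np.concatenate([np.arange(100), np.arange(300, 700)])
        th = 0.01 * frames
        pts = np.column_stack([np.cos(th), np.sin(th)])
        with pytest.warns(UserWarning, match="gap"):
            traj = track.extract_cumulative_angle(
                pts, self.CIRCLE, 200.0, frames=frames, max_gap=50
            )
        assert len(traj.frames) == 400
        assert traj.frames[0] == 300


class TestMSD:
    def test_linear_trajectory_exact_quadratic(self):
        w = 3.0
        t = np.arange(400) / 200.0
        traj = track.AngularTrajectory(times=t, cum_angle=w * t, frames=np.arange(400))
        curve = track.compute_msd(traj)
        np.testing.assert_allclose(curve.msd, w**2 * curve.lags**2, rtol=1e-12)

    def test_constant_angle_zero_msd(self):
        t = np.arange(100) / 200.0
        traj = track.AngularTrajectory(times=t, cum_angle=np.zeros(100), frames=np.arange(100))
        assert np.all(track.compute_msd(traj).msd == 0.0)

    def test_pure_diffusion_slope(self):
        D_r = 0.1
        truth = synth.RotorTruth(omega_d=0.0, D_r=D_r)
        acq = synth.AcquisitionParams(n_frames=100_000)
        theta = synth.simulate_angle_series(truth, acq, seed=23)
        t = np.arange(acq.n_frames) * acq.dt
        traj = track.AngularTrajectory(times=t, cum_angle=theta - theta[0], frames=np.arange(acq.n_frames))
        curve = track.compute_msd(traj, max_lag_fraction=0.002)
        slope = float(np.sum(curve.lags * curve.msd) / np.sum(curve.lags**2))
        assert slope == pytest.approx(2 * D_r, rel=0.10)

    def test_too_short_rejected(self):
        t = np.arange(5) / 200.0
        traj = track.AngularTrajectory(times=t, cum_angle=t, frames=np.arange(5))
        with pytest.raises(ValueError):
            track.compute_msd(traj)


class TestMSDFit:
    LAGS = np.linspace(0.005, 2.0, 100)

    def make_curve(self, msd):
        return track.MSDCurve(lags=self.LAGS, msd=msd, counts=np.full(len(self.LAGS), 1000))

    def test_closed_form_inversion(self):
        fit = track.fit_msd(self.make_curve(4 * self.LAGS**2 + 0.2 * self.LAGS), net_displacement=-1.0)
        assert fit.omega_d == pytest.approx(-2.0, rel=1e-9)
        assert fit.D_r == pytest.approx(0.1, rel=1e-9)

    def test_pure_diffusion_curve(self):
        fit = track.fit_msd(self.make_curve(0.2 * self.LAGS), net_displacement=0.0)
        assert fit.omega_d == 0.0
        assert fit.D_r == pytest.approx(0.1, rel=1e-9)

    def test_all_zero_curve(self):
        fit = track.fit_msd(self.make_curve(np.zeros(len(self.LAGS))), net_displacement=0.0)
        assert fit.omega_d == 0.0 and fit.D_r == 0.0

    def test_sign_from_net_displacement(self):
        curve = self.make_curve(4 * self.LAGS**2)
        assert track.fit_msd(curve, net_displacement=5.0).omega_d > 0
        assert track.fit_msd(curve, net_displacement=-5.0).omega_d < 0

    def test_full_rotor_recovery_within_5pct(self, acq_default):
        locs, truth = make_rotor_locs(omega_rev=10.0, D_r=0.5, seed=99, acq=acq_default)
        circle = track.fit_circle(locs.xy)
        traj = track.extract_cumulative_angle(locs.xy, circle, acq_default.frame_rate)
        fit = track.fit_msd(track.compute_msd(traj), traj.net_displacement)
        assert fit.omega_d == pytest.approx(truth.omega_d, rel=0.05)
        assert math.copysign(1, fit.omega_d) == math.copysign(1, truth.omega_d)

    def test_superlinear_msd_for_driven_rotor(self, acq_default):
        locs, _ = make_rotor_locs(omega_rev=5.0, D_r=0.5, seed=3, acq=acq_default)
        circle = track.fit_circle(locs.xy)
        traj = track.extract_cumulative_angle(locs.xy, circle, acq_default.frame_rate)
        curve = track.compute_msd(traj)
        # lags[k] = (k+1)*dt, so MSD(2 tau_k) lives at index 2k+1
        for k in range(len(curve.lags) // 2 - 1):
            assert curve.msd[2 * k + 1] / curve.msd[k] > 2.0


class TestTorque:
    def test_zero_and_linearity(self):
        p = track.TorqueParams()
        assert track.estimate_torque(0.0, p) == 0.0
        g1 = track.estimate_torque(3.0, p)
        assert track.estimate_torque(6.0, p) == pytest.approx(2 * g1)
        assert track.estimate_torque(-3.0, p) == pytest.approx(-g1)

    def test_hand_evaluated_reference(self):
        # eta = 1e-3 Pa s, L = 300 nm, d = 7 nm, omega = 2*pi*10 rad/s:
        # p = 42.857, ln p - 0.662 + 0.917/p - 0.050/p^2 = 3.1174,
        # xi_r = pi*1e-3*(3e-7)^3/(3*3.1174) = 9.07e-24 N m s -> 0.570 pN nm
        gamma = track.estimate_torque(2 * math.pi * 10, track.TorqueParams())
        assert gamma == pytest.approx(0.57, rel=0.01)

    def test_invalid_aspect_ratio(self):
        with pytest.raises(ValueError):
            track.TorqueParams(L=5.0, d=7.0)

    def test_wall_correction_scales(self):
        g1 = track.estimate_torque(1.0, track.TorqueParams())
        g3 = track.estimate_torque(1.0, track.TorqueParams(wall_correction=3.0))
        assert g3 == pytest.approx(3 * g1)


class TestSummaries:
    @staticmethod
    def results_from_speeds(speeds):
        return [
            track.RotorResult(id=i, circle=None, valid=True, omega_rev=s)
            for i, s in enumerate(speeds)
        ]

    def test_small_example(self):
        s = track.summarize_speeds(self.results_from_speeds([1, 2, 3, 4, 5]))
        row = s.iloc[0]
        assert row["median"] == 3 and row["q1"] == 2 and row["q3"] == 4
        assert row["whisker_low"] == -1.0 and row["whisker_high"] == 7.0

    def test_single_value_has_no_sem(self):
        row = track.summarize_speeds(self.results_from_speeds([2.5])).iloc[0]
        assert row["median"] == row["mean"] == 2.5
        assert math.isnan(row["sem"])

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(4)
        speeds = rng.normal(3, 2, size=200)
        row = track.summarize_speeds(self.results_from_speeds(speeds)).iloc[0]
        q1, med, q3 = np.percentile(speeds, [25, 50, 75])
        assert row["q1"] == q1 and row["median"] == med and row["q3"] == q3
        assert row["mean"] == pytest.approx(np.mean(speeds))

    def test_empty(self):
        assert len(track.summarize_speeds([])) == 0


class TestAnalyzeDataset:
    def test_three_rotor_recovery(self):
        acq = synth.AcquisitionParams(n_frames=4000)
        revs = [3.0, -6.0, 9.0]
        rotors = [
            synth.RotorTruth(omega_d=2 * math.pi * r, D_r=0.3, center=(i * 1000.0, 0.0))
            for i, r in enumerate(revs)
        ]
        locs, _ = synth.generate_array_dataset(rotors, [], acq, seed=31)
        results = [r for r in track.analyze_dataset(locs) if r.valid]
        assert len(results) == 3
        found = sorted(r.omega_rev for r in results)
        for est, true in zip(found, sorted(revs)):
            assert est == pytest.approx(true, rel=0.10)

    def test_empty_table(self):
        assert track.analyze_dataset(LocalizationSet.empty()) == []

    def test_free_diffusers_fully_rejected(self):
        # realistic free diffusion (~1 um^2/s) never survives the
        # 15-in-50-nm density filter
        acq = synth.AcquisitionParams(n_frames=4000)
        locs = synth.simulate_diffuser(1.0e6, (0.0, 0.0), acq, seed=55)
        results = track.analyze_dataset(locs)
        assert not any(r.valid for r in results)

    def test_row_permutation_invariance(self):
        acq = synth.AcquisitionParams(n_frames=2000)
        rotors = [
            synth.RotorTruth(omega_d=2 * math.pi * 4, D_r=0.2, center=(0.0, 0.0)),
            synth.RotorTruth(omega_d=-2 * math.pi * 7, D_r=0.2, center=(1500.0, 0.0)),
        ]
        locs, _ = synth.generate_array_dataset(rotors, [], acq, seed=77)
        shuffled = LocalizationSet(
            locs.data.sample(frac=1.0, random_state=0), locs.frame_rate
        )
        res_a = track.analyze_dataset(locs)
        res_b = track.analyze_dataset(shuffled)
        key = lambda r: r.circle.center[0]
        for a, b in zip(sorted(res_a, key=key), sorted(res_b, key=key)):
            assert a.valid == b.valid
            assert a.omega_rev == pytest.approx(b.omega_rev, rel=1e-9)
            assert a.circle.radius == pytest.approx(b.circle.radius, rel=1e-9)
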