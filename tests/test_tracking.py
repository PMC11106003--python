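"""Birmingham-method tracking: MDP closed form, iterative trimming,
stream partitioning and end-to-end robustness."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import special_ortho_group

from peptrack import (
    DEFAULT_GEOMETRY,
    DegenerateGeometryError,
    EmptyTrajectoryError,
    InsufficientDataError,
    ListModeStream,
    LoR,
    TrackingConfig,
    corrupted_static_sample,
    default_emission,
    locate,
    mdp,
    partition_stream,
    perpendicular_distance,
    simulate_listmode,
    track,
)
from peptrack import Trajectory
from peptrack.simulate import TrajectoryModel
from peptrack.tracking import point_line_distances


def random_bundle(rng, n, spread=50.0):
    """Random line bundle: anchors in a box, uniform directions."""
    p1 = rng.uniform(-spread, spread, (n, 3))
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return p1, p1 + 200.0 * d


def lines_through(point, rng, n, radius=120.0):
    """Exact lines through a point with random directions."""
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    point = np.asarray(point, dtype=float)
    return point - radius * d, point + radius * d


class TestPerpendicularDistance:
    def test_point_on_line(self):
        lor = LoR(0.0, np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        assert perpendicular_distance(lor, np.array([17.3, 0, 0])) == 0.0

    def test_three_four_five(self):
        lor = LoR(0.0, np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        assert perpendicular_distance(lor, np.array([5.0, 3.0, 4.0])) == pytest.approx(
            5.0
        )

    def test_matches_parametric_minimisation(self, rng):
        for _ in range(20):
            p1, p2 = (rng.uniform(-10, 10, 3) for _ in range(2))
            p = rng.uniform(-10, 10, 3)
            lor = LoR(0.0, p1, p2)
            d = p2 - p1

            def dist_at(s):
                return float(np.linalg.norm(p1 + s * d - p))

            res = minimize_scalar(dist_at, bounds=(-100, 100), method="bounded",
                                  options={"xatol": 1e-12})
            assert perpendicular_distance(lor, p) == pytest.approx(
                res.fun, abs=1e-9
            )


class TestMdp:
    def test_orthogonal_axes_intersect_origin(self):
        p1 = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        p2 = -p1
        point, rms = mdp((p1, p2))
        np.testing.assert_allclose(point, 0.0, atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_two_perpendicular_skew_lines(self):
        # x-axis and the line through (0,0,2) parallel to y: midpoint of the
        # common perpendicular is (0,0,1)
        p1 = np.array([[-1.0, 0, 0], [0, -1.0, 2.0]])
        p2 = np.array([[1.0, 0, 0], [0, 1.0, 2.0]])
        point, rms = mdp((p1, p2))
        np.testing.assert_allclose(point, [0, 0, 1.0], atol=1e-12)
        assert rms == pytest.approx(1.0, abs=1e-12)

    def test_accepts_lor_sequence(self):
        lors = [
            LoR(0.0, np.array([-1.0, 0, 0]), np.array([1.0, 0, 0])),
            LoR(0.1, np.array([0, -1.0, 0]), np.array([0, 1.0, 0])),
            LoR(0.2, np.array([0, 0, -1.0]), np.array([0, 0, 1.0])),
        ]
        point, _ = mdp(lors)
        np.testing.assert_allclose(point, 0.0, atol=1e-12)

    def test_parallel_bundle_degenerate(self):
        p1 = np.array([[0.0, 0, 0], [0, 1.0, 0], [0, 2.0, 0]])
        p2 = p1 + np.array([1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError, match="condition number"):
            mdp((p1, p2))

    def test_fewer_than_two_lines_rejected(self):
        with pytest.raises(InsufficientDataError):
            mdp((np.zeros((1, 3)), np.ones((1, 3))))

    def test_rigid_invariance(self, rng):
        p1, p2 = random_bundle(rng, 12)
        base, _ = mdp((p1, p2))
        for i in range(5):
            rot = special_ortho_group.rvs(3, random_state=100 + i)
            shift = rng.uniform(-30, 30, 3)
            moved, _ = mdp((p1 @ rot.T + shift, p2 @ rot.T + shift))
            np.testing.assert_allclose(moved, rot @ base + shift, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_residual_is_rms_of_distances(self, seed):
        rng = np.random.default_rng(seed)
        p1, p2 = random_bundle(rng, 8)
        point, rms = mdp((p1, p2))
        d = point_line_distances(p1, p2, point)
        assert rms == pytest.approx(np.sqrt(np.mean(d**2)), rel=1e-12)


def one_window_config(size, f, **kw):
    return TrackingConfig(schedule=((0.0, math.inf, size),), f=f, **kw)


class TestLocate:
    def test_f_one_equals_plain_mdp(self, rng):
        p1, p2 = random_bundle(rng, 40)
        t = np.linspace(0, 1, 40)
        cfg = one_window_config(40, 1.0)
        pt = locate(t, p1, p2, cfg)
        point, rms = mdp((p1, p2))
        np.testing.assert_allclose(pt.position, point, atol=1e-12)
        assert pt.n_final == 40 and pt.rms_residual_mm == pytest.approx(rms)
        assert pt.error_estimate_mm == pytest.approx(rms / math.sqrt(40))

    def test_constructed_corruption_recovered_exactly(self, rng):
        target = np.array([10.0, -5.0, 30.0])
        p1t, p2t = lines_through(target, rng, 90)
        p1n, p2n = random_bundle(rng, 10, spread=100.0)
        p1 = np.vstack([p1t, p1n])
        p2 = np.vstack([p2t, p2n])
        order = rng.permutation(100)
        cfg = one_window_config(100, 0.5)
        pt = locate(np.linspace(0, 1, 100), p1[order], p2[order], cfg)
        np.testing.assert_allclose(pt.position, target, atol=1e-6)
        assert pt.n_final == 50

    def test_all_lines_through_origin(self, rng):
        p1, p2 = lines_through([0, 0, 0], rng, 30)
        pt = locate(np.linspace(0, 1, 30), p1, p2, one_window_config(30, 0.5))
        np.testing.assert_allclose(pt.position, 0.0, atol=1e-9)
        assert pt.rms_residual_mm == pytest.approx(0.0, abs=1e-9)

    def test_final_count_exactly_ceil_f_n(self, rng):
        for n, f in [(150, 0.1), (137, 0.3), (100, 0.77)]:
            p1, p2 = random_bundle(rng, n)
            pt = locate(
                np.linspace(0, 1, n), p1, p2, one_window_config(n, f)
            )
            assert pt.n_final == max(math.ceil(f * n), 10)
            assert pt.n_initial == n

    def test_residual_decreases_with_stronger_trimming(self, rng):
        # corrupt sample: trimmed fits are tighter than the plain fit
        sample = corrupted_static_sample(
            geom=DEFAULT_GEOMETRY,
            point=np.array([10.0, -5.0, 30.0]),
            n=150,
            corrupt_fraction=0.3,
            seed=0,
        )
        residuals = [
            locate(sample.t, sample.p1, sample.p2, one_window_config(150, f))
            .rms_residual_mm
            for f in (0.1, 0.5, 1.0)
        ]
        assert residuals[0] < residuals[1] < residuals[2]

    def test_undersized_sample_rejected(self, rng):
        p1, p2 = random_bundle(rng, 50)
        with pytest.raises(InsufficientDataError):
            locate(np.linspace(0, 1, 50), p1, p2, one_window_config(150, 0.1))

    def test_midpoint_timestamp_mode(self, rng):
        p1, p2 = random_bundle(rng, 20)
        t = np.linspace(2.0, 4.0, 20)
        cfg = one_window_config(20, 1.0, timestamp_mode="midpoint")
        assert locate(t, p1, p2, cfg).t == pytest.approx(3.0)


class TestPartitionStream:
    def make_stream(self, t):
        n = len(t)
        p1 = np.tile([120.0, 0.0, 0.0], (n, 1))
        p2 = np.tile([-120.0, 0.0, 1.0], (n, 1))
        return ListModeStream(t=np.asarray(t, dtype=float), p1=p1, p2=p2)

    def test_exact_division(self):
        stream = self.make_stream(np.linspace(0, 10, 1000))
        cfg = one_window_config(100, 0.1)
        bounds = partition_stream(stream, cfg)
        assert bounds == [(i * 100, (i + 1) * 100) for i in range(10)]

    def test_trailing_remainder_dropped(self):
        stream = self.make_stream(np.linspace(0, 10, 1050))
        cfg = one_window_config(100, 0.1)  # min_lors/f = 100
        bounds = partition_stream(stream, cfg)
        assert len(bounds) == 10 and bounds[-1][1] == 1000

    def test_trailing_partial_kept_if_usable(self):
        stream = self.make_stream(np.linspace(0, 10, 1050))
        cfg = TrackingConfig(
            schedule=((0.0, math.inf, 100),), f=0.5, min_lors=10
        )  # min usable = 20
        bounds = partition_stream(stream, cfg)
        assert bounds[-1] == (1000, 1050)

    def test_empty_stream(self):
        stream = self.make_stream([])
        assert partition_stream(stream, one_window_config(100, 0.1)) == []

    def test_adaptive_schedule_window_durations(self, default_geom):
        # decaying 1.5 kBq source at 9% sensitivity: early 150-LoR windows
        # span ~1-5 s; 1000-LoR windows stretch as activity decays, passing
        # through ~30 s after about two half-lives
        traj = TrajectoryModel(
            times=np.array([0.0, 9000.0]), points=np.zeros((2, 3))
        )
        em = default_emission(
            duration_s=9000.0, seed=13, scatter_fraction=0.0,
            randoms_fraction=0.0, intrinsic_rate_cps=0.0, discretize=False,
        )
        stream, _ = simulate_listmode(traj, em, default_geom)
        cfg = TrackingConfig(
            schedule=((0.0, 60.0, 150), (60.0, math.inf, 1000)), f=0.1
        )
        bounds = partition_stream(stream, cfg)
        sizes = np.array([b - a for a, b in bounds])
        spans = np.array([stream.t[b - 1] - stream.t[a] for a, b in bounds])
        starts = np.array([stream.t[a] for a, b in bounds])
        # a sample straddling the 60 s switch grows to the late size
        early = spans[sizes == 150]
        assert (early >= 0.5).all() and (early <= 5.0).all()
        late = spans[(sizes == 1000) & (starts >= 60.0)]
        assert late[0] == pytest.approx(1000 / 135.0, rel=0.3)
        # windows stretch roughly as the inverse of the decayed activity
        assert late[-5:].mean() > 3.0 * late[:5].mean()
        two_half_lives = spans[(sizes == 1000) & (starts > 2 * 4062.6)]
        assert (two_half_lives > 25.0).all()


class TestTrack:
    def test_noiseless_static_source(self, default_geom):
        source = np.array([5.0, -10.0, 10.0])
        traj = TrajectoryModel(
            times=np.array([0.0, 30.0]), points=np.vstack([source, source])
        )
        em = default_emission(
            duration_s=30.0, seed=4, sensitivity=0.3, positron_sigma_mm=0.0,
            scatter_fraction=0.0, randoms_fraction=0.0, intrinsic_rate_cps=0.0,
            discretize=False,
        )
        stream, _ = simulate_listmode(traj, em, default_geom)
        result = track(stream, one_window_config(150, 0.5))
        assert len(result) >= 5
        err = np.linalg.norm(result.positions - source, axis=1)
        assert err.max() < 1e-6

    def test_corrupt_stream_tracked_within_a_millimetre(self, default_geom):
        source = np.array([10.0, -5.0, 30.0])
        traj = TrajectoryModel(
            times=np.array([0.0, 30.0]), points=np.vstack([source, source])
        )
        em = default_emission(
            duration_s=30.0, seed=8, sensitivity=0.3, positron_sigma_mm=0.0,
            scatter_fraction=0.0, randoms_fraction=0.3, intrinsic_rate_cps=0.0,
        )
        stream, _ = simulate_listmode(traj, em, default_geom)
        result = track(stream, one_window_config(150, 0.1))
        err = np.linalg.norm(result.positions - source, axis=1)
        assert err.max() < 1.0

    def test_empty_stream_raises(self):
        stream = ListModeStream(t=np.zeros(0), p1=np.zeros((0, 3)), p2=np.zeros((0, 3)))
        with pytest.raises(EmptyTrajectoryError):
            track(stream, one_window_config(100, 0.1))

    def test_trajectory_csv_roundtrip(self, tmp_path, default_geom, rng):
        sample = corrupted_static_sample(
            default_geom, np.array([0.0, 0.0, 0.0]), 150, 0.3, seed=1
        )
        result = track(sample, one_window_config(150, 0.1))
        path = result.to_csv(tmp_path / "traj.csv")
        back = Trajectory.from_csv(path)
        np.testing.assert_allclose(back.positions, result.positions, atol=1e-9)
        np.testing.assert_allclose(back.t, result.t, atol=1e-12)
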