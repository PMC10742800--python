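"""Geometric state parameters against independent closed-form oracles."""

import numpy as np
import pytest

from pairturn import (
    ArenaConfig,
    Trajectory,
    UndefinedAngleError,
    assign_leader,
    build_pair_state_series,
    compute_ald,
    compute_fdis,
    compute_heading,
    compute_los,
    compute_roa,
    compute_rpa,
    compute_wdis,
    estimate_eye_tail,
    unwrap_roa,
)

BL = 0.0333


def _traj(points, fs=50.0):
    pts = np.asarray(points, float)
    return Trajectory("A", np.arange(len(pts)), pts, fs)


class TestHeading:
    def test_displacement_vectors(self):
        h, dh = compute_heading(_traj([(0, 0), (0.01, 0), (0.01, 0.01)]))
        assert np.allclose(h[1], (0.01, 0))
        assert np.allclose(h[2], (0, 0.01))
        assert np.allclose(dh[2], (-0.01, 0.01))

    def test_constant_velocity_zero_dheading(self):
        pts = np.column_stack([np.arange(10) * 0.01, np.zeros(10)])
        _, dh = compute_heading(_traj(pts))
        assert np.allclose(dh[2:], 0.0)


class TestRoaAndUnwrap:
    @pytest.mark.parametrize("pos, expected", [
        ((0.15, 0.0), 0.0),
        ((0.0, 0.15), np.pi / 2),
        ((-0.1, -0.1), -3 * np.pi / 4),
    ])
    def test_known_angles(self, pos, expected):
        assert compute_roa(np.array(pos)) == pytest.approx(expected)

    def test_origin_rejected(self):
        with pytest.raises(UndefinedAngleError):
            compute_roa(np.array([0.0, 0.0]))

    def test_unwrap_removes_jump(self):
        out = unwrap_roa(np.array([3.1, -3.1]))
        assert out[1] == pytest.approx(-3.1 + 2 * np.pi)

    def test_unwrap_identity_within_branch(self):
        x = np.linspace(-2.0, 2.0, 50)
        assert np.allclose(unwrap_roa(x), x)

    def test_full_lap_winding(self):
        ang = np.linspace(0, 2 * np.pi, 400, endpoint=True)
        roa = compute_roa(np.column_stack([0.15 * np.cos(ang), 0.15 * np.sin(ang)]))
        u = unwrap_roa(roa)
        assert u[-1] - u[0] == pytest.approx(2 * np.pi)


class TestDistances:
    def test_fdis_one_body_length(self):
        assert compute_fdis(np.array([0.1, 0.0]), np.array([0.1 - BL, 0.0]), BL) \
            == pytest.approx(1.0)

    def test_fdis_coincident(self):
        assert compute_fdis(np.array([0.1, 0.0]), np.array([0.1, 0.0]), BL) == 0.0

    def test_wdis_interior_point(self, arena):
        val = compute_wdis(np.array([0.15, 0.0]), arena)
        assert val == pytest.approx(0.025 / arena.body_length)

    def test_wdis_at_wall_and_centreline(self, arena):
        assert compute_wdis(np.array([arena.inner_radius, 0.0]), arena) == 0.0
        mid = compute_wdis(np.array([arena.mid_radius, 0.0]), arena)
        assert mid == pytest.approx(arena.half_width / arena.body_length)

    def test_wdis_outside_clamped_with_warning(self, arena):
        with pytest.warns(UserWarning):
            assert compute_wdis(np.array([0.2, 0.0]), arena) == 0.0


class TestAngles:
    @pytest.mark.parametrize("heading, expected", [
        ((0.0, 1.0), 1.0),                      # tangential
        ((1.0, 0.0), 0.0),                      # radial
        ((1.0, 1.0), np.sqrt(2) / 2),           # 45 degrees
    ])
    def test_ald_cases(self, heading, expected):
        val = compute_ald(np.array([0.15, 0.0]), np.array(heading))
        assert val == pytest.approx(expected)

    @pytest.mark.parametrize("leader_offset, expected", [
        ((0.02, 0.0), 0.0),          # dead ahead of heading +x
        ((-0.02, 0.0), np.pi),       # dead astern
        ((0.0, 0.02), np.pi / 2),    # abeam
    ])
    def test_rpa_cases(self, leader_offset, expected):
        pos_f = np.array([0.1, 0.1])
        val = compute_rpa(pos_f + leader_offset, pos_f, np.array([1.0, 0.0]))
        assert val == pytest.approx(expected)

    def test_eye_tail_geometry(self):
        eye, tail = estimate_eye_tail(np.zeros(2), np.array([1.0, 0.0]), BL)
        assert np.allclose(eye, (BL / 2, 0))
        assert np.allclose(tail, (-BL / 2, 0))
        # unnormalised heading is normalised first
        eye, tail = estimate_eye_tail(np.zeros(2), np.array([3.0, 4.0]), BL)
        assert np.allclose(eye, BL / 2 * np.array([0.6, 0.8]))
        assert np.linalg.norm(eye - tail) == pytest.approx(BL, abs=1e-12)

    def test_los_collinear_and_known_value(self):
        # leader's eye and tail on one ray from the follower's eye
        assert compute_los(np.array([0.0, 0.1]), np.array([0.0, 0.2]),
                           np.zeros(2)) == pytest.approx(0.0)
        val = compute_los(np.array([0.0, 0.1]), np.array([0.0333, 0.1]), np.zeros(2))
        assert val == pytest.approx(np.arctan(0.333), abs=1e-9)

    def test_los_rotation_invariant(self, rng):
        for _ in range(20):
            eye_l, tail_l, eye_f = rng.normal(size=(3, 2))
            base = compute_los(eye_l, tail_l, eye_f)
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            rotated = compute_los(
                eye_f + rot @ (eye_l - eye_f), eye_f + rot @ (tail_l - eye_f), eye_f)
            assert rotated == pytest.approx(base, abs=1e-9)


class TestRandomConfigOracles:
    """Rpa/Los/ald/Roa against brute-force arccos/atan2 arithmetic."""

    N = 1000

    def test_geometry_against_arccos_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(self.N):
            pos_l, pos_f = rng.uniform(-0.17, 0.17, size=(2, 2))
            head_f = rng.normal(size=2)
            if np.linalg.norm(pos_l - pos_f) < 1e-9 or np.linalg.norm(head_f) < 1e-9:
                continue

            def ang(u, v):
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                return np.arccos(np.clip(c, -1, 1))

            assert compute_rpa(pos_l, pos_f, head_f) == pytest.approx(
                ang(pos_l - pos_f, head_f), abs=1e-9)

            if np.linalg.norm(pos_f) > 1e-9:
                expected_roa = np.arctan2(pos_f[1], pos_f[0])
                assert compute_roa(pos_f) == pytest.approx(expected_roa, abs=1e-12)
                expected_ald = abs(np.sin(ang(head_f, pos_f)))
                assert compute_ald(pos_f, head_f) == pytest.approx(expected_ald, abs=1e-9)

            eye_l, tail_l = estimate_eye_tail(pos_l, rng.normal(size=2) + 1e-3, BL)
            eye_f = pos_f
            if min(np.linalg.norm(eye_l - eye_f), np.linalg.norm(tail_l - eye_f)) > 1e-9:
                assert compute_los(eye_l, tail_l, eye_f) == pytest.approx(
                    ang(eye_l - eye_f, tail_l - eye_f), abs=1e-9)

    def test_fdis_wdis_arithmetic_oracle(self, arena):
        rng = np.random.default_rng(7)
        for _ in range(self.N):
            rho = rng.uniform(arena.inner_radius, arena.outer_radius, size=2)
            ang = rng.uniform(0, 2 * np.pi, size=2)
            pts = np.column_stack([rho * np.cos(ang), rho * np.sin(ang)])
            expected = np.linalg.norm(pts[0] - pts[1]) / arena.body_length
            assert compute_fdis(pts[0], pts[1], arena.body_length) \
                == pytest.approx(expected, abs=1e-9)
            expected_w = min(rho[0] - arena.inner_radius,
                             arena.outer_radius - rho[0]) / arena.body_length
            assert compute_wdis(pts[0], arena) == pytest.approx(expected_w, abs=1e-9)


class TestCircularMotionClosedForm:
    def test_constant_angular_speed_circle(self, arena):
        # ccw on the centreline: speed = omega * radius, ald -> 1,
        # unwrapped Roa slope = omega
        fs, omega, radius = 50.0, 1.2, arena.mid_radius
        t = np.arange(600) / fs
        pts = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        traj = _traj(pts, fs)
        h, _ = compute_heading(traj)
        speed = np.linalg.norm(h, axis=1) * fs
        # chord-vs-arc correction is O((omega/fs)^2)
        assert np.allclose(speed[1:], omega * radius, rtol=2e-4)
        ald = compute_ald(pts[1:], h[1:])
        assert np.all(ald > 1 - 1e-3)
        u = unwrap_roa(compute_roa(pts))
        slopes = np.diff(u) * fs
        assert np.allclose(slopes, omega, rtol=1e-9)


class TestLeaderRule:
    def test_ccw_larger_roa_leads(self):
        assert assign_leader(0.5, 0.3, +1)[0] == "A"

    def test_cw_smaller_roa_leads(self):
        assert assign_leader(0.5, 0.3, -1)[0] == "B"

    def test_tie_carries_previous(self):
        out = assign_leader(np.array([0.5, 0.4, 0.2]),
                            np.array([0.3, 0.4, 0.3]), np.ones(3))
        assert list(out) == ["A", "A", "B"]


class TestPairStateSeries:
    def test_channel_order_frozen(self, clean_series):
        _, series, _ = clean_series
        assert list(series.data.columns) == [
            "Fdis", "Wldis", "Wfdis", "Rpa", "Lald", "Fald",
            "Lspeed", "Fspeed", "DlHeading", "DfHeading"]

    def test_all_channels_finite(self, clean_series):
        _, series, _ = clean_series
        assert np.isfinite(series.values).all()
        assert np.isfinite(series.los).all()

    def test_ranges(self, clean_series):
        _, series, _ = clean_series
        df = series.data
        assert (df["Fdis"] >= 0).all()
        assert df["Rpa"].between(0, np.pi).all()
        assert df["Lald"].between(0, 1).all()
        assert df["Fald"].between(0, 1).all()
        assert (df["Lspeed"] >= 0).all()
        assert ((series.los >= 0) & (series.los <= np.pi)).all()

    def test_leader_constant_between_turns(self, clean_series):
        _, series, gt = clean_series
        # ground truth: away from manoeuvres the leader identity is fixed
        fs = series.arena.fs
        for turn in gt.turns:
            lo = turn.pair_epoint - int(3 * fs)
            hi = min(turn.epoints.values()) - int(0.5 * fs)
            mask = (series.frames >= lo) & (series.frames <= hi)
            leaders = set(series.leader[mask])
            assert leaders == {turn.leader_pre}

    def test_mirrored_tangential_pair_constant_fdis(self, arena):
        fs, omega, radius = 50.0, 1.0, arena.mid_radius
        t = np.arange(300) / fs
        a = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        traj_a = Trajectory("A", np.arange(len(t)), a, fs)
        traj_b = Trajectory("B", np.arange(len(t)), -a, fs)
        series = build_pair_state_series(traj_a, traj_b, arena)
        fdis = series.data["Fdis"].to_numpy()
        assert np.allclose(fdis, fdis[0], rtol=1e-9)
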