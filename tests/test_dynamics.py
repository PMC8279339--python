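"""Inverse-dynamics oracles: statics, pendulum, equivariance, zero input."""

import numpy as np
import pytest

from gravgait.conditioning import lowpass
from gravgait.dynamics import (
    build_segment_frames,
    joint_angles,
    joint_powers,
    kabsch,
    load_segment_parameters,
    net_moments,
)
from gravgait.errors import DynamicsError, FrameConstructionError


def _static_markers(standing, n=200):
    return {k: np.tile(v, (n, 1)) for k, v in standing.items()}


def _rotx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


class TestFrames:
    def test_standing_leg_segments_are_vertical(self, walker_noiseless):
        res, _ = walker_noiseless
        poses = build_segment_frames(_static_markers(res.standing, 5),
                                     res.standing)
        up = np.array([0.0, 0.0, 1.0])
        for seg in ("thigh", "shank"):
            z = poses.frames[seg][0][:, 2]
            ang = np.rad2deg(np.arccos(np.clip(z @ up, -1, 1)))
            assert ang < 1.0

    def test_rigid_rotation_equivariance(self, walker_noiseless):
        res, _ = walker_noiseless
        Q = _rotx(np.deg2rad(30.0))
        rotated = {k: v @ Q.T for k, v in res.markers.items()}
        p0 = build_segment_frames(res.markers, res.standing)
        p1 = build_segment_frames(rotated, res.standing)
        for seg in ("thigh", "shank", "foot", "pelvis"):
            np.testing.assert_allclose(p1.frames[seg],
                                       Q @ p0.frames[seg], atol=1e-9)

    def test_cluster_noise_degrades_gracefully(self, walker_noiseless):
        # 1 mm marker noise, 6 Hz filtered as in the pipeline: mean frame
        # orientation error below half a degree
        res, _ = walker_noiseless
        rng = np.random.default_rng(0)
        cleanf = {k: lowpass(v, 6.0, 100) for k, v in res.markers.items()}
        noisyf = {k: lowpass(v + rng.normal(0, 0.001, v.shape), 6.0, 100)
                  for k, v in res.markers.items()}
        p0 = build_segment_frames(cleanf, res.standing)
        p1 = build_segment_frames(noisyf, res.standing)
        for seg in ("thigh", "shank"):
            tr = np.einsum("nij,nij->n", p0.frames[seg], p1.frames[seg])
            ang = np.rad2deg(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
            assert ang.mean() < 0.5

    def test_collinear_cluster_rejected(self):
        ref = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3.0]])
        with pytest.raises(FrameConstructionError):
            kabsch(ref, ref + 0.1)


class TestJointAngles:
    def test_standing_pose_is_zero_everywhere(self, walker_noiseless):
        res, _ = walker_noiseless
        poses = build_segment_frames(_static_markers(res.standing, 5),
                                     res.standing)
        st = build_segment_frames(res.standing, res.standing)
        ang, flags = joint_angles(poses, st)
        for j in ("hip", "knee", "ankle"):
            assert np.abs(ang[j]).max() < 1e-9
            assert not flags[j].any()

    def test_prescribed_knee_flexion_recovered(self, walker_noiseless):
        res, _ = walker_noiseless
        knee = 0.5 * (res.standing["r_lat_epi"] + res.standing["r_med_epi"])
        R = _rotx(np.deg2rad(-20.0))       # flexion: ankle moves posterior
        markers = {}
        shank_foot = [f"r_{m}" for m in (
            "lat_mall", "med_mall", "heel", "mt1", "mt5", "hallux",
            "shank_c1", "shank_c2", "shank_c3", "shank_c4")]
        for k, v in res.standing.items():
            pos = knee + R @ (v - knee) if k in shank_foot else v
            markers[k] = np.tile(pos, (5, 1))
        st = build_segment_frames(res.standing, res.standing)
        ang, _ = joint_angles(build_segment_frames(markers, res.standing), st)
        # knee extension positive -> 20 degrees flexion reads -20
        assert ang["knee"][0] == pytest.approx(-20.0, abs=0.5)
        assert abs(ang["hip"][0]) < 0.5

    def test_lab_frame_invariance(self, walker_noiseless):
        res, _ = walker_noiseless
        Q = _rotx(np.deg2rad(17.0))
        rotated = {k: v @ Q.T for k, v in res.markers.items()}
        st = build_segment_frames(res.standing, res.standing)
        a0, _ = joint_angles(build_segment_frames(res.markers, res.standing),
                             st)
        a1, _ = joint_angles(build_segment_frames(rotated, res.standing), st)
        for j in ("hip", "knee", "ankle"):
            np.testing.assert_allclose(a1[j], a0[j], atol=1e-6)

    def test_walker_knee_angle_matches_ik_truth(self, walker_noiseless):
        res, _ = walker_noiseless
        st = build_segment_frames(res.standing, res.standing)
        ang, _ = joint_angles(build_segment_frames(res.markers, res.standing),
                              st)
        # generator truth logs flexion-positive angles from its own IK
        np.testing.assert_allclose(-ang["knee"],
                                   res.truth["knee_flexion_deg"], atol=0.5)


class TestNetMoments:
    def test_static_stance_matches_lever_arm_oracle(self, walker_noiseless):
        res, _ = walker_noiseless
        n = 50
        poses = build_segment_frames(_static_markers(res.standing, n),
                                     res.standing)
        params = load_segment_parameters()
        body_mass = 70.0
        grf = np.zeros((n, 3))
        grf[:, 1], grf[:, 2] = 20.0, 300.0
        ankle = poses.joints["ankle"][0]
        cop_pt = ankle + np.array([0.0, 0.08, -ankle[2]])
        cop = np.tile(cop_pt, (n, 1))
        M = net_moments(poses, grf, cop, body_mass)
        # closed form: ankle balance of GRF and foot weight (statics)
        mf = params["foot"]["mass_fraction"] * body_mass
        toe = poses.points["toe_mid"][0]
        com = ankle + params["foot"]["com_fraction"] * (toe - ankle)
        arm_cop, arm_com = cop_pt - ankle, com - ankle
        mx = (arm_cop[1] * grf[0, 2] - arm_cop[2] * grf[0, 1]
              + arm_com[1] * (-mf * 9.81))
        oracle_pf = mx                    # plantarflexion-positive
        assert abs(M["ankle"][n // 2] - oracle_pf) < 0.5

    def test_zero_input_gives_zero_moments(self, walker_noiseless):
        res, _ = walker_noiseless
        n = 50
        poses = build_segment_frames(_static_markers(res.standing, n),
                                     res.standing)
        M = net_moments(poses, np.zeros((n, 3)), np.full((n, 3), np.nan),
                        70.0, gravity=0.0)
        for j in ("ankle", "knee", "hip"):
            assert np.abs(M[j]).max() < 1e-9

    def test_swinging_foot_matches_pendulum_oracle(self, walker_noiseless):
        res, _ = walker_noiseless
        standing = res.standing
        n, rate = 400, 100.0
        t = np.arange(n) / rate
        th0, om = np.deg2rad(15.0), 2 * np.pi * 0.8
        theta = th0 * np.sin(om * t)
        ankle = 0.5 * (standing["r_lat_mall"] + standing["r_med_mall"])
        markers = {}
        for k, v in standing.items():
            if k in ("r_heel", "r_mt1", "r_mt5", "r_hallux"):
                arr = np.array([ankle + _rotx(a) @ (v - ankle)
                                for a in theta])
            else:
                arr = np.tile(v, (n, 1))
            markers[k] = arr
        poses = build_segment_frames(markers, standing)
        M = net_moments(poses, np.zeros((n, 3)), np.full((n, 3), np.nan),
                        70.0)
        params = load_segment_parameters()
        mf = params["foot"]["mass_fraction"] * 70.0
        toe0 = 0.5 * (standing["r_mt1"] + standing["r_mt5"])
        com0 = ankle + params["foot"]["com_fraction"] * (toe0 - ankle)
        r = com0 - ankle
        L = np.linalg.norm(toe0 - ankle)
        I_piv = mf * (params["foot"]["gyration_fraction"] * L) ** 2 \
            + mf * np.linalg.norm(r) ** 2
        alpha = -th0 * om * om * np.sin(om * t)
        oracle = np.empty(n)
        for i in range(n):
            rv = _rotx(theta[i]) @ r
            oracle[i] = -(I_piv * alpha[i] + rv[1] * mf * 9.81)
        mid = slice(50, n - 50)
        scale = np.abs(oracle[mid]).max()
        assert np.abs(M["ankle"][mid] - oracle[mid]).max() < 0.01 * scale

    def test_missing_cop_during_stance_rejected(self, walker_noiseless):
        res, _ = walker_noiseless
        n = 30
        poses = build_segment_frames(_static_markers(res.standing, n),
                                     res.standing)
        grf = np.zeros((n, 3))
        grf[:, 2] = 100.0
        with pytest.raises(DynamicsError):
            net_moments(poses, grf, np.full((n, 3), np.nan), 70.0)


class TestJointPowers:
    def test_constant_angle_zero_power(self):
        m = {"knee": np.full(100, 50.0)}
        a = {"knee": np.full(100, 10.0)}
        assert np.abs(joint_powers(m, a)["knee"]).max() == 0.0

    def test_moment_times_angular_velocity(self):
        # 100 N m with angle rising at 2 rad/s -> 200 W
        t = np.arange(100) / 100.0
        m = {"hip": np.full(100, 100.0)}
        a = {"hip": np.rad2deg(2.0 * t)}
        p = joint_powers(m, a)["hip"]
        np.testing.assert_allclose(p[1:-1], 200.0, rtol=1e-9)

    def test_extension_moment_during_flexion_absorbs(self):
        t = np.arange(100) / 100.0
        m = {"knee": np.full(100, 50.0)}          # extension moment
        a = {"knee": np.rad2deg(-1.0 * t)}        # flexing
        assert np.all(joint_powers(m, a)["knee"][1:-1] < 0.0)

    def test_power_integrates_to_work(self, rng):
        t = np.arange(500) / 100.0
        ang = 30.0 * np.sin(t)
        m = {"ankle": 80.0 * np.cos(0.7 * t)}
        p = joint_powers(m, {"ankle": ang})["ankle"]
        omega = np.gradient(np.deg2rad(ang), 0.01)
        work_direct = np.trapezoid(m["ankle"] * omega, dx=0.01)
        work_power = np.trapezoid(p, dx=0.01)
        assert work_power == pytest.approx(work_direct, abs=1e-9)
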