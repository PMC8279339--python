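"""Scalar feature extraction and ensemble averaging."""

import numpy as np
import pandas as pd
import pytest

from gravgait.errors import RangeError
from gravgait.events import StrideSegmentation
from gravgait.features import (
    ensemble_average,
    extract_grf_peaks,
    extract_kinetic_peaks,
    force_vectors,
    stride_length,
)
from gravgait.synthetic.waveforms import synth_ap_ml_forces, synth_vertical_grf


def _seg(rhs1=0.3, rto=1.0, rhs2=1.45, **kw):
    return StrideSegmentation(rhs1=rhs1, rto=rto, rhs2=rhs2, source="force",
                              **kw)


def _stance_grf(peak1=1.05, trough=0.75, peak2=1.0, braking=-0.12,
                prop=0.03, ml=0.05):
    """Embed analytic stance waveforms (in BW units) in a longer record."""
    n = 2000
    seg = _seg()
    vz = synth_vertical_grf(peak1, trough, peak2, 0.7, 1.0)
    ap, mlw = synth_ap_ml_forces(braking, prop, ml, 0.7, 1.0)
    grf = np.zeros((n, 3))
    i0 = 300
    grf[i0:i0 + vz.size, 2] = vz
    grf[i0:i0 + vz.size, 1] = ap
    grf[i0:i0 + vz.size, 0] = mlw
    return grf, seg


class TestGrfPeaks:
    def test_peaks_match_waveform_parameters(self):
        grf, seg = _stance_grf()
        peaks = extract_grf_peaks(grf, seg)
        assert peaks["peak_vertical_grf"] == pytest.approx(1.05)
        assert peaks["peak_braking"] == pytest.approx(-0.12)
        assert peaks["peak_accelerating"] == pytest.approx(0.03)
        assert peaks["peak_abs_ml"] == pytest.approx(0.05)

    def test_zero_stance_gives_zero_peaks(self):
        peaks = extract_grf_peaks(np.zeros((2000, 3)), _seg())
        assert all(v == 0.0 for v in peaks.values())

    @pytest.mark.parametrize("c", [0.31, 0.5, 2.0])
    def test_peaks_commute_with_positive_rescaling(self, c):
        grf, seg = _stance_grf()
        p1 = extract_grf_peaks(grf, seg)
        p2 = extract_grf_peaks(c * grf, seg)
        for k in p1:
            assert p2[k] == pytest.approx(c * p1[k])

    def test_empty_stance_rejected(self):
        with pytest.raises(Exception):
            extract_grf_peaks(np.zeros((100, 3)), _seg())


def _bump(center_pct, width_pct=8.0, height=1.0, n=1001):
    pct = np.linspace(0, 100, n)
    return height * np.exp(-0.5 * ((pct - center_pct) / width_pct) ** 2)


class TestKineticPeaks:
    def test_single_early_bump_lands_in_early_window(self):
        moments = {"hip": np.zeros(1001), "knee": _bump(25.0, 4.0, 2.0),
                   "ankle": np.zeros(1001)}
        powers = {j: np.zeros(1001) for j in moments}
        peaks = extract_kinetic_peaks(moments, powers, toe_off_percent=62.0)
        assert peaks["peak_knee_ext_moment_early"] == pytest.approx(2.0,
                                                                    rel=1e-6)
        assert peaks["peak_knee_ext_moment_transition"] < 0.05

    def test_two_bumps_split_between_windows(self):
        knee = _bump(25.0, 3.0, 2.0) + _bump(55.0, 3.0, 1.2)
        moments = {"hip": np.zeros(1001), "knee": knee,
                   "ankle": np.zeros(1001)}
        powers = {j: np.zeros(1001) for j in moments}
        peaks = extract_kinetic_peaks(moments, powers, toe_off_percent=62.0)
        assert peaks["peak_knee_ext_moment_early"] == pytest.approx(2.0,
                                                                    rel=1e-3)
        assert peaks["peak_knee_ext_moment_transition"] == pytest.approx(
            1.2, rel=1e-3)

    def test_all_zero_series_give_zero_peaks(self):
        z = {j: np.zeros(1001) for j in ("hip", "knee", "ankle")}
        peaks = extract_kinetic_peaks(z, z, toe_off_percent=60.0)
        assert all(v == 0.0 for v in peaks.values())

    def test_sign_conventions(self):
        # hip flexion reported positive from a flexion (negative) moment
        moments = {"hip": -_bump(30.0, 5.0, 1.5), "knee": np.zeros(1001),
                   "ankle": _bump(50.0, 5.0, 1.4)}
        powers = {"hip": np.zeros(1001), "knee": -_bump(55.0, 4.0, 0.8),
                  "ankle": np.zeros(1001)}
        peaks = extract_kinetic_peaks(moments, powers, toe_off_percent=62.0)
        assert peaks["peak_hip_flexion_moment"] == pytest.approx(1.5, rel=1e-6)
        assert peaks["peak_ankle_pf_moment"] == pytest.approx(1.4, rel=1e-6)
        assert peaks["peak_knee_power_abs_transition"] == pytest.approx(
            0.8, rel=1e-6)


class TestForceVectors:
    def test_m_shape_timings_and_values(self):
        grf, seg = _stance_grf(peak1=1.05, trough=0.7, peak2=0.98)
        fv = force_vectors(grf, seg)
        assert not fv.degenerate
        # construction: peaks at 25%/75%, trough at 50% of the 0.7 s stance
        t0 = 0.3
        assert fv.times[0] == pytest.approx(t0 + 0.25 * 0.7, abs=0.005)
        assert fv.times[1] == pytest.approx(t0 + 0.50 * 0.7, abs=0.005)
        assert fv.times[2] == pytest.approx(t0 + 0.75 * 0.7, abs=0.005)
        assert fv.vectors[0][1] == pytest.approx(1.05, rel=1e-6)
        assert fv.vectors[1][1] == pytest.approx(0.7, rel=1e-6)

    def test_symmetric_m_shape_minimum_at_midstance(self):
        grf, seg = _stance_grf(peak1=1.0, trough=0.7, peak2=1.0)
        fv = force_vectors(grf, seg)
        assert fv.times[1] == pytest.approx(0.3 + 0.35, abs=0.005)

    def test_scaling_halves_magnitudes_keeps_angles(self):
        grf, seg = _stance_grf()
        fv1 = force_vectors(grf, seg)
        fv2 = force_vectors(0.5 * grf, seg)
        for (a1, z1), (a2, z2) in zip(fv1.vectors, fv2.vectors):
            assert a2 == pytest.approx(0.5 * a1, abs=1e-12)
            assert z2 == pytest.approx(0.5 * z1, abs=1e-12)
        np.testing.assert_allclose(fv1.angles_deg, fv2.angles_deg, atol=1e-9)

    def test_single_peak_flagged_degenerate(self):
        grf, seg = _stance_grf(peak1=1.0, trough=0.999, peak2=0.9999)
        fv = force_vectors(grf, seg)
        assert fv.degenerate and len(fv.vectors) == 1


class TestStrideLength:
    def test_displacement_over_leg_length(self):
        t = np.arange(200) / 100.0
        heel_y = 1.2 * t                      # constant 1.2 m/s drift
        seg = _seg(rhs1=0.3, rto=1.0, rhs2=1.4)
        # displacement 1.2 * 1.1 = 1.32 m over a 0.88 m leg
        assert stride_length(heel_y, t, seg, 0.88) == pytest.approx(1.5,
                                                                    abs=0.02)

    def test_zero_displacement(self):
        t = np.arange(200) / 100.0
        assert stride_length(np.ones(200), t, _seg(), 0.9) == 0.0

    def test_doubling_leg_length_halves_value(self):
        t = np.arange(200) / 100.0
        heel_y = 0.9 * t
        a = stride_length(heel_y, t, _seg(), 0.8)
        b = stride_length(heel_y, t, _seg(), 1.6)
        assert b == pytest.approx(a / 2)

    def test_events_outside_trajectory_rejected(self):
        t = np.arange(50) / 100.0             # 0.5 s only
        with pytest.raises(RangeError):
            stride_length(np.ones(50), t, _seg(), 0.9)


class TestEnsembleAverage:
    @staticmethod
    def _df(rows):
        return pd.DataFrame(rows, columns=["participant_id", "gravity_level",
                                           "target_speed", "v"])

    def test_single_participant_grand_mean_is_trial_mean(self):
        df = self._df([("P1", 1.0, 1.2, 2.0), ("P1", 1.0, 1.2, 4.0)])
        out = ensemble_average(df, ["v"])
        assert out.loc[0, "v_mean"] == pytest.approx(3.0)

    def test_two_participants_closed_form(self):
        df = self._df([("P1", 1.0, 1.2, 1.0), ("P2", 1.0, 1.2, 3.0)])
        out = ensemble_average(df, ["v"])
        assert out.loc[0, "v_mean"] == pytest.approx(2.0)
        assert out.loc[0, "v_std"] == pytest.approx(np.sqrt(2.0))

    def test_unbalanced_trials_use_unweighted_participant_means(self):
        # P1 has 3 trials at 1.0 each, P2 has 1 trial at 5.0: the two-stage
        # grand mean is (1 + 5)/2 = 3, not the pooled (3*1 + 5)/4 = 2
        df = self._df([("P1", 1.0, 1.2, 1.0)] * 3 + [("P2", 1.0, 1.2, 5.0)])
        out = ensemble_average(df, ["v"])
        assert out.loc[0, "v_mean"] == pytest.approx(3.0)
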