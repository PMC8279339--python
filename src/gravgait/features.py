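"""Scalar gait features: GRF peaks, joint moment/power peaks in their
stance windows, sagittal force vectors at three stance points, stride
length, and two-stage ensemble averaging.

Window conventions for the kinetic peaks (percent of stride, configurable):
the early-mid-stance knee extension peak is searched in 0-40% of stride;
the transition peak between 40% and toe-off + 10%; hip and ankle peaks
over stance.  These windows robustly separate the two knee-moment peaks
across walking speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from gravgait.errors import RangeError
from gravgait.events import StrideSegmentation

#: Early-mid-stance window upper bound, percent of stride.
EARLY_WINDOW_END = 40.0

#: Transition-window extension past toe-off, percent of stride.
TRANSITION_PAST_TOEOFF = 10.0


def extract_grf_peaks(grf_bw: np.ndarray, segmentation: StrideSegmentation
                      ) -> dict[str, float]:
    """Stance-phase GRF peaks from bodyweight-normalized forces (N, 3),
    lab axes (x ML, y AP, z vertical), at the analog rate.

    Returns peak vertical (max), braking (min AP, <= 0), accelerating
    (max AP), and peak absolute ML.
    """
    lo, hi = segmentation.stance_range_analog
    if hi <= lo:
        raise RangeError("empty stance range")
    stance = np.asarray(grf_bw, float)[lo:hi]
    if stance.size == 0:
        raise RangeError("stance range outside force series")
    return {
        "peak_vertical_grf": float(stance[:, 2].max()),
        "peak_braking": float(stance[:, 1].min()),
        "peak_accelerating": float(stance[:, 1].max()),
        "peak_abs_ml": float(np.abs(stance[:, 0]).max()),
    }


def extract_kinetic_peaks(moments: dict[str, np.ndarray],
                          powers: dict[str, np.ndarray],
                          toe_off_percent: float) -> dict[str, float]:
    """Moment and power peaks from stride-normalized (1001-point) joint
    kinetics in the reported sign conventions (extension / plantarflexion
    and generation positive)."""
    n = len(next(iter(moments.values())))
    pct = np.linspace(0.0, 100.0, n)
    stance = pct <= toe_off_percent
    early = pct <= EARLY_WINDOW_END
    transition = (pct >= EARLY_WINDOW_END) & (
        pct <= toe_off_percent + TRANSITION_PAST_TOEOFF)
    for name, w in (("stance", stance), ("early", early),
                    ("transition", transition)):
        if not w.any():
            raise RangeError(f"empty {name} window")
    return {
        # moments: hip flexion reported as a positive flexion magnitude
        "peak_hip_flexion_moment": float(np.max(-moments["hip"][stance])),
        "peak_knee_ext_moment_early": float(np.max(moments["knee"][early])),
        "peak_knee_ext_moment_transition": float(
            np.max(moments["knee"][transition])),
        "peak_ankle_pf_moment": float(np.max(moments["ankle"][stance])),
        # powers: generation positive; knee transition absorption reported
        # as a positive absorption magnitude
        "peak_hip_power_gen": float(np.max(powers["hip"][stance])),
        "peak_knee_power_gen_early": float(np.max(powers["knee"][early])),
        "peak_knee_power_abs_transition": float(
            np.max(-powers["knee"][transition])),
        "peak_ankle_power_gen": float(np.max(powers["ankle"][stance])),
    }


@dataclass
class ForceVectorSet:
    """Sagittal (AP, vertical) force vectors at the three stance points:
    first vertical peak, post-peak minimum, second vertical peak."""

    times: list[float]                  # s, strictly increasing
    vectors: list[tuple[float, float]]  # (AP, vertical) in BW
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not all(
                a < b for a, b in zip(self.times, self.times[1:])):
            raise RangeError("force-vector timings must be increasing")

    @property
    def angles_deg(self) -> list[float]:
        """Vector angle from vertical, degrees (positive tilts forward)."""
        return [float(np.rad2deg(np.arctan2(ap, vz)))
                for ap, vz in self.vectors]


def force_vectors(grf_bw: np.ndarray, segmentation: StrideSegmentation,
                  rate: float = 1000.0) -> ForceVectorSet:
    """Locate the two vertical-GRF peaks and the intervening minimum within
    stance and return the sagittal force vectors there.

    A single-peaked stance (possible at strong bodyweight support) yields a
    degenerate set carrying only the global peak.
    """
    lo, hi = segmentation.stance_range_analog
    stance = np.asarray(grf_bw, float)[lo:hi]
    if stance.size == 0:
        raise RangeError("empty stance range")
    vz = stance[:, 2]
    peaks, _ = find_peaks(vz, prominence=0.02 * max(vz.max(), 1e-9))
    if peaks.size < 2:
        i = int(np.argmax(vz))
        t = (lo + i) / rate
        return ForceVectorSet(times=[t], degenerate=True,
                              vectors=[(float(stance[i, 1]), float(vz[i]))])
    i1, i2 = int(peaks[0]), int(peaks[-1])
    im = i1 + int(np.argmin(vz[i1:i2 + 1]))
    idx = [i1, im, i2]
    return ForceVectorSet(
        times=[(lo + i) / rate for i in idx],
        vectors=[(float(stance[i, 1]), float(vz[i])) for i in idx])


def stride_length(heel_xy: np.ndarray, time: np.ndarray,
                  segmentation: StrideSegmentation,
                  leg_length: float) -> float:
    """Stride length normalized to leg length: AP displacement of the
    right heel marker between the two heel strikes."""
    time = np.asarray(time, float)
    if segmentation.rhs1 < time[0] or segmentation.rhs2 > time[-1]:
        raise RangeError("stride events outside heel trajectory extent")
    heel_y = np.asarray(heel_xy, float)
    if heel_y.ndim == 2:
        heel_y = heel_y[:, 1]
    y1 = np.interp(segmentation.rhs1, time, heel_y)
    y2 = np.interp(segmentation.rhs2, time, heel_y)
    return float(abs(y2 - y1) / leg_length)


def ensemble_average(df: pd.DataFrame, value_cols: list[str],
                     condition_cols: list[str] = ("gravity_level",
                                                  "target_speed"),
                     participant_col: str = "participant_id") -> pd.DataFrame:
    """Two-stage condition averages: trials -> participant-condition means,
    then unweighted participant means with across-participant SD.

    Missing conditions simply stay absent from the output.
    """
    condition_cols = list(condition_cols)
    per_participant = (df.groupby(condition_cols + [participant_col])
                       [list(value_cols)].mean().reset_index())
    grouped = per_participant.groupby(condition_cols)[list(value_cols)]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{c}_{stat}" for c, stat in out.columns]
    return out.reset_index()
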