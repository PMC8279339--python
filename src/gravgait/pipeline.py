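"""End-to-end processing: raw trial -> events -> conditioned signals ->
inverse dynamics -> scalar features -> condition-level feature table.

Processing chain per trial (mirroring the study's pipeline):

1. stride segmentation from the 18 N vertical-GRF threshold with the
   delay-offset kinematic fallback for the second heel strike;
2. GRF peaks from 20 Hz low-pass filtered plate forces normalized to
   bodyweight at 1 G;
3. EMG: zero-lag 30 Hz high-pass, rectification, stance/swing RMS;
4. inverse dynamics on 6 Hz low-pass filtered markers and forces, moments
   and powers normalized to body mass, stride-normalized to 1001 points;
5. stride length from heel-marker AP displacement, normalized to leg
   length.

Cohort post-processing averages trials within participant x condition,
normalizes EMG RMS per participant/muscle/phase by the maximum across
conditions, and hands the table to the statistics stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gravgait.constants import ANALOG_RATE, EMG_CHANNELS, MARKER_RATE
from gravgait.conditioning import (
    condition_emg,
    lowpass,
    normalize_kinetics,
    normalize_rms,
    phase_rms,
    time_normalize,
)
from gravgait.dynamics import (
    build_segment_frames,
    joint_angles,
    joint_powers,
    net_moments,
)
from gravgait.errors import GaitError
from gravgait.events import classify_trial, segment_stride
from gravgait.features import (
    extract_grf_peaks,
    extract_kinetic_peaks,
    stride_length,
)
from gravgait.trial_io import TrialRecord


def right_plate_wrench(trial: TrialRecord, segmentation
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Force and CoP of the plate under the analysed right stance."""
    p = segmentation.right_plate
    return trial.plate_forces[p], trial.plate_cop[p]


def trial_features(trial: TrialRecord, expected_stride_time: float | None = None,
                   run_dynamics: bool = True) -> dict:
    """All scalar features of one trial (one row of the feature table)."""
    seg = segment_stride(trial, expected_stride_time=expected_stride_time)
    validity = classify_trial(trial, seg)
    row: dict = {
        "participant_id": trial.meta.participant_id,
        "gravity_level": trial.meta.gravity_level,
        "target_speed": trial.meta.target_speed,
        "good": validity.good,
        "validity_reasons": ";".join(validity.reasons),
        "rhs1": seg.rhs1, "rto": seg.rto, "rhs2": seg.rhs2,
        "event_source": seg.source,
    }

    # GRF peaks: 20 Hz low-pass, bodyweight (1 G) normalization
    force, cop = right_plate_wrench(trial, seg)
    f20 = lowpass(force, 20.0, ANALOG_RATE)
    f20_bw, _, _ = normalize_kinetics(f20, None, None, trial.meta.body_mass)
    row.update(extract_grf_peaks(f20_bw, seg))

    # EMG: 30 Hz high-pass + rectification, phase RMS
    for muscle in EMG_CHANNELS:
        rect = condition_emg(trial.emg[muscle], ANALOG_RATE)
        row[f"stance_rms_{muscle}"] = phase_rms(rect, seg, "stance")
        row[f"swing_rms_{muscle}"] = phase_rms(rect, seg, "swing")

    # stride length from the raw heel trajectory
    row["stride_length_norm"] = stride_length(
        trial.markers["r_heel"], trial.marker_time, seg,
        trial.meta.leg_length)

    if run_dynamics:
        row.update(trial_joint_kinetic_peaks(trial, seg))
    return row


def trial_joint_kinetics(trial: TrialRecord, seg):
    """Stride-normalized (1001-point) sagittal angle, moment (N m kg^-1)
    and power (W kg^-1) series per joint, plus the toe-off percentage."""
    # 6 Hz low-pass on markers and forces feeding the dynamics
    markers_f = {name: lowpass(arr, 6.0, MARKER_RATE)
                 for name, arr in trial.markers.items()}
    poses = build_segment_frames(markers_f, trial.standing,
                                 time=trial.marker_time)
    standing_poses = build_segment_frames(trial.standing, trial.standing)
    angles, _ = joint_angles(poses, standing_poses)

    force, cop = right_plate_wrench(trial, seg)
    f6 = lowpass(force, 6.0, ANALOG_RATE)
    # decimate the analog wrench onto the kinematic grid (common origin)
    step = ANALOG_RATE // MARKER_RATE
    nk = trial.marker_time.size
    f6k = f6[::step][:nk]
    if f6k.shape[0] < nk:          # marker grid may overrun by one sample
        pad = np.repeat(f6k[-1:], nk - f6k.shape[0], axis=0)
        f6k = np.vstack([f6k, pad])
    copk = interpolate_cop(cop, seg, nk, step)
    moments = net_moments(poses, f6k, copk, trial.meta.body_mass)
    powers = joint_powers(moments, angles)

    _, m_norm, p_norm = normalize_kinetics(
        None,
        np.column_stack([moments[j] for j in ("hip", "knee", "ankle")]),
        np.column_stack([powers[j] for j in ("hip", "knee", "ankle")]),
        trial.meta.body_mass)

    m_strided = time_normalize(m_norm, trial.marker_time, seg)
    p_strided = time_normalize(p_norm, trial.marker_time, seg)
    joints = ("hip", "knee", "ankle")
    a_strided = time_normalize(
        np.column_stack([angles[j] for j in joints]), trial.marker_time, seg)
    return (
        {j: a_strided.values[:, k] for k, j in enumerate(joints)},
        {j: m_strided.values[:, k] for k, j in enumerate(joints)},
        {j: p_strided.values[:, k] for k, j in enumerate(joints)},
        m_strided.toe_off_percent,
    )


def interpolate_cop(cop: np.ndarray, seg, nk: int, step: int) -> np.ndarray:
    """Decimate the CoP and fill unloaded (NaN) gaps by nearest loaded
    value, so that force smeared slightly past stance by the 6 Hz filter
    still has a finite application point."""
    copk = cop[::step][:nk].copy()
    if copk.shape[0] < nk:
        copk = np.vstack([copk, np.repeat(copk[-1:], nk - copk.shape[0],
                                          axis=0)])
    valid = np.isfinite(copk).all(axis=1)
    if not valid.any():
        return np.zeros_like(copk)
    idx_valid = np.flatnonzero(valid)
    if idx_valid.size == 1:
        return np.tile(copk[idx_valid[0]], (nk, 1))
    idx_all = np.arange(nk)
    # choose the closer of the neighbouring loaded samples on each side
    pos = np.searchsorted(idx_valid, idx_all).clip(1, idx_valid.size - 1)
    left, right = idx_valid[pos - 1], idx_valid[pos]
    nearest = np.where(idx_all - left <= right - idx_all, left, right)
    return copk[nearest]


def trial_joint_kinetic_peaks(trial: TrialRecord, seg) -> dict:
    _, moments, powers, toe_pct = trial_joint_kinetics(trial, seg)
    return extract_kinetic_peaks(moments, powers, toe_pct)


def cohort_features(trials, expected_stride_time=None,
                    run_dynamics: bool = True,
                    skip_bad: bool = False) -> pd.DataFrame:
    """Per-trial feature rows for an iterable of trials (or of
    ``(trial, truth)`` pairs, as produced by the generator)."""
    rows = []
    for item in trials:
        trial = item[0] if isinstance(item, tuple) else item
        try:
            row = trial_features(trial, expected_stride_time, run_dynamics)
        except GaitError as exc:
            row = {"participant_id": trial.meta.participant_id,
                   "gravity_level": trial.meta.gravity_level,
                   "target_speed": trial.meta.target_speed,
                   "good": False, "validity_reasons": f"error:{exc}"}
        if not skip_bad or row.get("good", False):
            rows.append(row)
    return pd.DataFrame(rows)


def condition_means(features: pd.DataFrame) -> pd.DataFrame:
    """Participant x condition means with EMG RMS normalized per
    participant/muscle/phase by the maximum across that participant's
    conditions (stance and swing independently).

    This is the table the mixed models consume: one row per participant
    and condition.
    """
    value_cols = [c for c in features.columns
                  if c.startswith(("peak_", "stance_rms_", "swing_rms_"))
                  or c == "stride_length_norm"]
    per_cond = (features.groupby(
        ["participant_id", "gravity_level", "target_speed"])[value_cols]
        .mean().reset_index())
    for muscle in EMG_CHANNELS:
        for phase in ("stance", "swing"):
            col = f"{phase}_rms_{muscle}"
            if col not in per_cond.columns:
                continue
            for pid, idx in per_cond.groupby("participant_id").groups.items():
                vals = per_cond.loc[idx, col]
                normed = normalize_rms(dict(zip(idx, vals)))
                per_cond.loc[idx, col] = pd.Series(normed)
    return per_cond
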