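"""Gait-event detection, delay-offset correction, stride segmentation, and
trial-validity classification.

Events come from two routes:

* **Force route** — heel strike and toe-off are threshold crossings of the
  vertical ground reaction force at an 18 N cutoff, with sub-sample timing
  by linear interpolation and a 20 ms debounce against noise chatter.
* **Kinematic route** — when the second right heel strike falls beyond the
  instrumented plates, it is estimated from the heel marker's vertical
  minima and corrected by the *delay offset*: the lag between the
  force-detected and kinematically detected first heel strike is added to
  the kinematic second heel strike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from gravgait.constants import ANALOG_RATE, MARKER_RATE
from gravgait.errors import InvalidEventError, NoEventError
from gravgait.conditioning import FilterSpec, butterworth
from gravgait.trial_io import TrialRecord

#: Vertical-force contact threshold, N.
CONTACT_THRESHOLD = 18.0

#: Minimum duration of a supra/sub-threshold run to count as real, s.
DEBOUNCE = 0.020

#: Unloaded-plate baseline window at the start of the trial, s.
BASELINE_WINDOW = 0.100


@dataclass
class StrideSegmentation:
    """Event times and phase index ranges for one right stride."""

    rhs1: float                  # first right heel strike, s
    rto: float                   # right toe-off, s
    rhs2: float                  # second right heel strike, s
    source: str                  # "force" | "kinematic_offset"
    right_plate: int | None = None
    left_plate: int | None = None

    def __post_init__(self):
        if not (self.rhs1 < self.rto < self.rhs2):
            raise InvalidEventError(
                f"event ordering violated: rhs1={self.rhs1:.4f}, "
                f"rto={self.rto:.4f}, rhs2={self.rhs2:.4f}")
        if self.source not in ("force", "kinematic_offset"):
            raise InvalidEventError(f"unknown event source {self.source!r}")

    @property
    def stride_time(self) -> float:
        return self.rhs2 - self.rhs1

    # -- half-open sample index ranges at each stream's rate -------------

    def _ranges(self, rate: int) -> tuple[tuple[int, int], tuple[int, int]]:
        i0 = int(round(self.rhs1 * rate))
        i1 = int(round(self.rto * rate))
        i2 = int(round(self.rhs2 * rate))
        return (i0, i1), (i1, i2)

    @property
    def stance_range_analog(self) -> tuple[int, int]:
        return self._ranges(ANALOG_RATE)[0]

    @property
    def swing_range_analog(self) -> tuple[int, int]:
        return self._ranges(ANALOG_RATE)[1]

    @property
    def stance_range_kinematic(self) -> tuple[int, int]:
        return self._ranges(MARKER_RATE)[0]

    @property
    def swing_range_kinematic(self) -> tuple[int, int]:
        return self._ranges(MARKER_RATE)[1]


@dataclass
class TrialValidity:
    """Whether a trial meets the study's good-trial rule."""

    good: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.good != (len(self.reasons) == 0):
            raise InvalidEventError("good flag inconsistent with reasons list")


def detect_contacts(vertical_grf: np.ndarray, rate: float = ANALOG_RATE,
                    threshold: float = CONTACT_THRESHOLD,
                    debounce: float = DEBOUNCE,
                    ) -> tuple[list[float], list[float]]:
    """Contact on/off times from a baseline-free vertical GRF series.

    Returns interpolated threshold-crossing times for the starts of
    supra-threshold runs (contact on) and of sub-threshold runs (contact
    off).  Runs shorter than ``debounce`` are ignored in either direction.
    An all-subthreshold series yields two empty lists.
    """
    v = np.asarray(vertical_grf, float)
    above = v >= threshold
    if not above.any():
        return [], []

    # run-length encode, then drop runs shorter than the debounce window
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    edges = np.concatenate(([0], change, [v.size]))
    runs = [(int(edges[i]), int(edges[i + 1]), bool(above[edges[i]]))
            for i in range(edges.size - 1)]
    min_run = max(1, int(round(debounce * rate)))
    cleaned: list[list] = []
    for lo, hi, state in runs:
        if hi - lo < min_run and cleaned:
            cleaned[-1][1] = hi          # absorb the blip into the previous run
        elif hi - lo < min_run and not cleaned:
            cleaned.append([lo, hi, False])  # leading blip: treat as unloaded
        elif cleaned and cleaned[-1][2] == state:
            cleaned[-1][1] = hi
        else:
            cleaned.append([lo, hi, state])

    dt = 1.0 / rate
    ons, offs = [], []
    for lo, hi, state in cleaned:
        if lo == 0:
            if state:
                ons.append(0.0)
            continue
        prev, cur = v[lo - 1], v[lo]
        if cur != prev:
            frac = np.clip((threshold - prev) / (cur - prev), 0.0, 1.0)
        else:
            frac = 0.0
        t_cross = (lo - 1 + frac) * dt
        (ons if state else offs).append(float(t_cross))
    return ons, offs


def kinematic_heel_strike(heel_z: np.ndarray, rate: float = MARKER_RATE,
                          expected_stride_time: float | None = None,
                          min_prominence: float = 0.008) -> list[float]:
    """Heel-strike times as local minima of the heel marker height.

    The trajectory is zero-lag lowpass filtered at 6 Hz, minima are found
    with a minimum inter-event spacing of half the expected stride time,
    and each minimum is refined by local parabolic interpolation.
    """
    z = np.asarray(heel_z, float)
    if z.ndim == 2:
        z = z[:, 2]
    zf = butterworth(z, FilterSpec("lowpass", 6.0), rate)
    # default spacing guard: half the shortest plausible stride time
    distance = max(1, int(round(0.5 * (expected_stride_time or 0.7) * rate)))
    idx, _ = find_peaks(-zf, distance=distance, prominence=min_prominence)
    if idx.size == 0:
        raise NoEventError("no qualifying heel-height minimum found")
    times = []
    for i in idx:
        t = i / rate
        if 0 < i < z.size - 1:
            y0, y1, y2 = zf[i - 1], zf[i], zf[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                t += 0.5 * (y0 - y2) / denom / rate
        times.append(float(t))
    return times


def delay_offset_second_heelstrike(force_hs1: float, kin_hs1: float,
                                   kin_hs2: float) -> float:
    """Second right heel strike via the delay-offset rule.

    The delay between force-detected and kinematic first heel strike is
    added to the kinematic second heel strike:
    ``rhs2 = kin_hs2 + (force_hs1 - kin_hs1)``.
    """
    if kin_hs2 <= kin_hs1:
        raise InvalidEventError(
            f"kinematic heel strikes out of order: {kin_hs1} !< {kin_hs2}")
    return kin_hs2 + (force_hs1 - kin_hs1)


def remove_plate_baseline(vertical: np.ndarray, rate: float = ANALOG_RATE,
                          window: float = BASELINE_WINDOW) -> np.ndarray:
    """Subtract the unloaded-plate offset (median of the first ``window``
    seconds, before any contact)."""
    n = max(1, int(round(window * rate)))
    return vertical - float(np.median(vertical[:n]))


def _plate_contacts(trial: TrialRecord) -> list[tuple[list[float], list[float]]]:
    out = []
    for force in trial.plate_forces:
        vz = remove_plate_baseline(force[:, 2])
        out.append(detect_contacts(vz))
    return out


def segment_stride(trial: TrialRecord,
                   expected_stride_time: float | None = None,
                   match_window: float = 0.15) -> StrideSegmentation:
    """Segment the analysed right stride of a walking trial.

    The first plate contact of the trial is the right heel strike (the
    study's walkway protocol: right foot first); toe-off is that plate's
    contact-off.  The second right heel strike is taken from a force plate
    when a matching contact exists (source ``"force"``), otherwise from the
    delay-offset kinematic estimate (source ``"kinematic_offset"``).
    """
    contacts = _plate_contacts(trial)
    onsets = sorted((t, p) for p, (ons, _) in enumerate(contacts) for t in ons)
    if not onsets:
        raise NoEventError("no foot contact found on any plate")
    rhs1, right_plate = onsets[0]
    offs_right = [t for t in contacts[right_plate][1] if t > rhs1]
    if not offs_right:
        raise NoEventError("right-foot toe-off not found on its plate")
    rto = offs_right[0]

    heel = trial.markers["r_heel"][:, 2]
    kin_hs = kinematic_heel_strike(heel, MARKER_RATE, expected_stride_time)
    # kinematic match for the first (force-detected) heel strike
    kin_hs = np.asarray(kin_hs)
    i1 = int(np.argmin(np.abs(kin_hs - rhs1)))
    kin_hs1 = float(kin_hs[i1])
    # the first plate contact must belong to the right foot: a right-heel
    # kinematic event has to fall close to it
    if abs(kin_hs1 - rhs1) > 0.2 * (expected_stride_time or 0.75):
        raise NoEventError(
            "first plate contact does not match a right heel strike "
            "(left-foot-only contact?)")
    later = kin_hs[kin_hs > kin_hs1 + 0.25 * (expected_stride_time or 0.5)]
    if later.size == 0:
        raise NoEventError("no kinematic second heel strike found")
    kin_hs2 = float(later[0])
    rhs2_kin = delay_offset_second_heelstrike(rhs1, kin_hs1, kin_hs2)

    # does any other plate record a contact matching the second heel strike?
    rhs2, source = rhs2_kin, "kinematic_offset"
    best = match_window
    for t, p in onsets[1:]:
        if p != right_plate and abs(t - rhs2_kin) < best:
            rhs2, source, best = t, "force", abs(t - rhs2_kin)

    # left strike: next contact after rhs1 that is not the right second strike
    left_plate = None
    for t, p in onsets[1:]:
        if source == "force" and abs(t - rhs2) < 1e-9 and p != right_plate:
            continue
        if rhs1 < t < rhs2 - 0.1 * (rhs2 - rhs1):
            left_plate = p
            break

    return StrideSegmentation(rhs1=rhs1, rto=rto, rhs2=rhs2, source=source,
                              right_plate=right_plate, left_plate=left_plate)


def classify_trial(trial: TrialRecord,
                   segmentation: StrideSegmentation) -> TrialValidity:
    """Good-trial rule: timing-gate speed within +-5% of target (inclusive
    bound) and right-then-left strikes on distinct plates."""
    reasons = []
    target = trial.meta.target_speed
    if abs(trial.meta.gate_speed - target) > 0.05 * target + 1e-12:
        reasons.append("speed-out-of-band")
    if segmentation.left_plate is None:
        reasons.append("missing-contact")
    elif segmentation.left_plate == segmentation.right_plate:
        reasons.append("shared-plate-strike")
    return TrialValidity(good=not reasons, reasons=reasons)
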