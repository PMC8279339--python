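"""Signal conditioning: zero-lag Butterworth filtering, EMG envelope
processing, phase-specific RMS, stride time-normalization, moving-mean
smoothing, and kinetic normalizations.

Filter conventions
------------------
Zero-phase filtering applies a 4th-order Butterworth design forward and
backward (second-order sections), which doubles the attenuation: the
response at the nominal cutoff is |H|^2 = 0.5 (-6 dB), not -3 dB.  No
cutoff pre-warping correction is applied; this matches common gait-lab
practice.  Edges are handled with reflective padding of length 3 x order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from gravgait.constants import GRAVITY
from gravgait.errors import (
    InvalidAnthropometryError,
    InvalidFilterError,
    InvalidPhaseError,
    InvalidWindowError,
    RangeError,
    UndefinedNormalizationError,
)


@dataclass(frozen=True)
class FilterSpec:
    """A zero-lag Butterworth filter specification."""

    kind: str                # "lowpass" | "highpass"
    cutoff: float            # Hz
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass"):
            raise InvalidFilterError(f"unknown filter kind {self.kind!r}")
        if self.order % 2 != 0 or self.order < 2:
            raise InvalidFilterError("filter order must be a positive even number")
        if self.cutoff <= 0:
            raise InvalidFilterError("cutoff must be positive")


def butterworth(series: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Apply ``spec`` to ``series`` sampled at ``rate`` Hz.

    Zero-lag specs run forward-backward (two passes of the order-``spec.order``
    design), giving amplitude 0.5 at the nominal cutoff for a lowpass.
    Works on 1-D series or (N, k) sample-major arrays.
    """
    series = np.asarray(series, float)
    if spec.cutoff >= rate / 2:
        raise InvalidFilterError(
            f"cutoff {spec.cutoff} Hz >= Nyquist {rate / 2} Hz")
    n = series.shape[0]
    if n <= 3 * spec.order:
        raise InvalidFilterError(
            f"series length {n} too short for order {spec.order}")
    if not np.all(np.isfinite(series)):
        raise InvalidFilterError("series contains non-finite values")
    sos = signal.butter(spec.order, spec.cutoff, btype=spec.kind,
                        fs=rate, output="sos")
    if spec.zero_lag:
        return signal.sosfiltfilt(sos, series, axis=0, padtype="even",
                                  padlen=3 * spec.order)
    return signal.sosfilt(sos, series, axis=0)


def lowpass(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-lag 4th-order Butterworth lowpass (convenience wrapper)."""
    return butterworth(series, FilterSpec("lowpass", cutoff), rate)


def condition_emg(raw_emg: np.ndarray, rate: float = 1000.0,
                  highpass_cutoff: float = 30.0) -> np.ndarray:
    """High-pass (zero-lag, 30 Hz, 4th-order Butterworth) then full-wave
    rectify a raw EMG channel."""
    filt = butterworth(raw_emg, FilterSpec("highpass", highpass_cutoff), rate)
    return np.abs(filt)


def phase_rms(rectified_emg: np.ndarray, segmentation, phase: str) -> float:
    """Root-mean-square of the rectified EMG over a gait phase.

    ``phase`` is ``"stance"`` ([heel strike, toe-off)) or ``"swing"``
    ([toe-off, next heel strike)); ranges are half-open in samples at the
    analog rate.
    """
    if phase == "stance":
        lo, hi = segmentation.stance_range_analog
    elif phase == "swing":
        lo, hi = segmentation.swing_range_analog
    else:
        raise InvalidPhaseError(f"unknown phase {phase!r}")
    if hi <= lo:
        raise InvalidPhaseError(f"empty {phase} range [{lo}, {hi})")
    seg = np.asarray(rectified_emg, float)[lo:hi]
    if seg.size == 0:
        raise InvalidPhaseError(f"{phase} range outside series extent")
    return float(np.sqrt(np.mean(seg ** 2)))


def normalize_rms(rms_by_condition: dict) -> dict:
    """Normalize one participant/muscle/phase family of RMS values by its
    maximum across conditions; the maximum maps to exactly 1."""
    vals = np.array(list(rms_by_condition.values()), float)
    peak = vals.max() if vals.size else 0.0
    if peak <= 0:
        raise UndefinedNormalizationError(
            "all-zero RMS values: normalization undefined")
    return {k: float(v) / peak for k, v in rms_by_condition.items()}


@dataclass
class StrideNormalizedSeries:
    """A series resampled onto 0-100% of stride (1001 points by default)."""

    values: np.ndarray       # (n_points,) or (n_points, k)
    toe_off_percent: float   # stance/swing boundary, percent of stride

    def __post_init__(self):
        if not (0.0 < self.toe_off_percent < 100.0):
            raise RangeError(
                f"toe-off percent must lie in (0, 100), got {self.toe_off_percent}")


def time_normalize(series: np.ndarray, time: np.ndarray, segmentation,
                   n_points: int = 1001) -> StrideNormalizedSeries:
    """Linearly interpolate ``series`` (sampled at ``time``) onto ``n_points``
    equally spaced stride-phase points between the two heel strikes.

    Endpoints reproduce the series values at rhs1 and rhs2 exactly (up to
    interpolation of the sample grid).
    """
    series = np.asarray(series, float)
    time = np.asarray(time, float)
    t0, t1 = segmentation.rhs1, segmentation.rhs2
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise RangeError(
            f"stride [{t0:.3f}, {t1:.3f}] s outside series extent "
            f"[{time[0]:.3f}, {time[-1]:.3f}] s")
    tq = np.linspace(t0, t1, n_points)
    if series.ndim == 1:
        vals = np.interp(tq, time, series)
    else:
        vals = np.column_stack(
            [np.interp(tq, time, series[:, j]) for j in range(series.shape[1])])
    toe_pct = 100.0 * (segmentation.rto - t0) / (t1 - t0)
    return StrideNormalizedSeries(values=vals, toe_off_percent=toe_pct)


def moving_mean(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Centred moving average with symmetric truncation at the edges.

    Output length equals input length; near the edges the window shrinks
    symmetrically so the average stays centred on the output sample.
    """
    series = np.asarray(series, float)
    if window < 1:
        raise InvalidWindowError("window must be >= 1")
    n = series.shape[0]
    if window > n:
        raise InvalidWindowError(f"window {window} exceeds series length {n}")
    half = (window - 1) // 2
    # asymmetric halves for even windows: one extra sample on the right,
    # mirroring common moving-mean conventions
    right = window - 1 - half
    out = np.empty_like(series, dtype=float)
    for i in range(n):
        k = min(i, half, right, n - 1 - i)
        lo_full, hi_full = i - half, i + right + 1
        if lo_full >= 0 and hi_full <= n:
            out[i] = series[lo_full:hi_full].mean(axis=0)
        else:
            out[i] = series[i - k:i + k + 1].mean(axis=0)
    return out


def normalize_kinetics(forces: np.ndarray | None, moments: np.ndarray | None,
                       powers: np.ndarray | None, body_mass: float):
    """Normalize forces to bodyweight at 1 G and moments/powers to body mass.

    The force normalizer is ``body_mass * 9.81`` regardless of the trial's
    simulated gravity level.  Returns the tuple (forces_BW, moments_per_kg,
    powers_per_kg) with None propagated.
    """
    if body_mass <= 0:
        raise InvalidAnthropometryError(
            f"body_mass must be positive, got {body_mass}")
    bw = body_mass * GRAVITY
    f = None if forces is None else np.asarray(forces, float) / bw
    m = None if moments is None else np.asarray(moments, float) / body_mass
    p = None if powers is None else np.asarray(powers, float) / body_mass
    return f, m, p
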