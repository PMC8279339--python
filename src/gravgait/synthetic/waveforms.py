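"""Analytic force and EMG waveform primitives for the synthetic generator.

All stance-phase force waveforms are built from raised-cosine segments
blended C1-continuously, so their extrema are *exact* by construction:
the global maximum of the vertical waveform equals the configured peak to
the last bit, which gives downstream peak-extraction tests an analytic
truth channel.  Segment boundaries are snapped to the sample grid so the
extremum lands exactly on a sample.
"""

from __future__ import annotations

import numpy as np

from gravgait.constants import ANALOG_RATE
from gravgait.errors import InvalidParameterError


def _raised_cosine(n0: int, n1: int, v0: float, v1: float,
                   out: np.ndarray) -> None:
    """Fill out[n0:n1+1] with a half raised cosine from v0 to v1 (zero slope
    at both ends)."""
    n = n1 - n0
    if n <= 0:
        out[n0] = v1
        return
    u = np.arange(n + 1) / n
    out[n0:n1 + 1] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))


def synth_vertical_grf(peak1: float, trough: float, peak2: float,
                       stance_duration: float, bodyweight: float,
                       sample_rate: float = ANALOG_RATE) -> np.ndarray:
    """Noiseless double-peaked ('m'-shaped) vertical GRF over one stance.

    Parameters are in bodyweights; the returned series is in newtons,
    starts and ends at exactly 0, and its global maximum equals
    ``max(peak1, peak2) * bodyweight`` exactly.  Equal peak/trough
    parameters degenerate into a flat mid-stance plateau.
    """
    if stance_duration <= 0:
        raise InvalidParameterError("stance_duration must be positive")
    if bodyweight <= 0:
        raise InvalidParameterError("bodyweight must be positive")
    for name, val in (("peak1", peak1), ("trough", trough), ("peak2", peak2)):
        if val <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {val}")
    if trough > min(peak1, peak2):
        raise InvalidParameterError(
            f"trough ({trough}) must not exceed the peaks ({peak1}, {peak2})")

    n = int(round(stance_duration * sample_rate))
    if n < 8:
        raise InvalidParameterError("stance too short for the sample rate")
    # segment boundaries snapped to the sample grid: peaks at 25% and 75%
    # of stance, trough at 50%
    i1, im, i2 = round(0.25 * n), round(0.50 * n), round(0.75 * n)
    v = np.zeros(n + 1)
    _raised_cosine(0, i1, 0.0, peak1, v)
    _raised_cosine(i1, im, peak1, trough, v)
    _raised_cosine(im, i2, trough, peak2, v)
    _raised_cosine(i2, n, peak2, 0.0, v)
    v *= bodyweight
    v[0] = v[-1] = 0.0
    return v


def vertical_grf_threshold_times(peak1: float, peak2: float,
                                 stance_duration: float, bodyweight: float,
                                 threshold: float) -> tuple[float, float]:
    """Analytic first/last crossing times of ``threshold`` newtons for the
    noiseless vertical waveform of :func:`synth_vertical_grf`, measured from
    stance onset.  Uses the same grid-snapped segment boundaries."""
    n = int(round(stance_duration * ANALOG_RATE))
    t1 = round(0.25 * n) / ANALOG_RATE
    t2 = round(0.75 * n) / ANALOG_RATE
    T = n / ANALOG_RATE
    th1 = threshold / (peak1 * bodyweight)
    th2 = threshold / (peak2 * bodyweight)
    if not (0 < th1 < 1 and 0 < th2 < 1):
        raise InvalidParameterError("threshold outside waveform range")
    # rising segment: v = p1*(1-cos(pi t/t1))/2
    t_on = t1 / np.pi * np.arccos(1.0 - 2.0 * th1)
    # falling segment: v = p2*(1+cos(pi (t-t2)/(T-t2)))/2
    t_off = t2 + (T - t2) / np.pi * np.arccos(2.0 * th2 - 1.0)
    return float(t_on), float(t_off)


def _bump(n_total: int, center: int, halfwidth: int, height: float,
          out: np.ndarray) -> None:
    """Add a cos^2 bump of given height (exact at its centre sample)."""
    lo = max(0, center - halfwidth)
    hi = min(n_total - 1, center + halfwidth)
    idx = np.arange(lo, hi + 1)
    u = (idx - center) / halfwidth
    out[idx] += height * np.cos(0.5 * np.pi * u) ** 2


def synth_ap_ml_forces(braking_peak: float, propulsive_peak: float,
                       ml_peak: float, stance_duration: float,
                       bodyweight: float,
                       sample_rate: float = ANALOG_RATE,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless anterior-posterior and medial-lateral GRF over one stance.

    The AP series has its minimum (``braking_peak * bodyweight``, <= 0) in
    the first half of stance and its maximum (``propulsive_peak *
    bodyweight``) in the second half; the ML series peaks at
    ``ml_peak * bodyweight`` in absolute value.  Extrema are exact.
    """
    if stance_duration <= 0 or bodyweight <= 0:
        raise InvalidParameterError("duration and bodyweight must be positive")
    if braking_peak > 0:
        raise InvalidParameterError(f"braking_peak must be <= 0, got {braking_peak}")
    if propulsive_peak < 0:
        raise InvalidParameterError(
            f"propulsive_peak must be >= 0, got {propulsive_peak}")
    if ml_peak < 0:
        raise InvalidParameterError(f"ml_peak must be >= 0, got {ml_peak}")
    n = int(round(stance_duration * sample_rate))
    ap = np.zeros(n + 1)
    ml = np.zeros(n + 1)
    # non-overlapping supports keep the configured extrema exact
    _bump(n + 1, round(0.22 * n), round(0.17 * n), braking_peak * bodyweight, ap)
    _bump(n + 1, round(0.80 * n), round(0.17 * n), propulsive_peak * bodyweight, ap)
    _bump(n + 1, round(0.50 * n), round(0.40 * n), ml_peak * bodyweight, ml)
    return ap, ml


def synth_support_force(gravity_level: float, bodyweight: float,
                        fluctuation_amplitude: float, duration: float,
                        rng: np.random.Generator,
                        sample_rate: float = ANALOG_RATE) -> np.ndarray:
    """Harness support-force series: mean ``(1 - gravity_level) * bodyweight``
    with smooth friction-like fluctuations.

    The fluctuation is zero-mean coloured noise rescaled so its largest
    excursion equals ``fluctuation_amplitude * bodyweight`` exactly, which
    keeps every admissible series strictly inside the 5%-of-bodyweight
    band.
    """
    if not (0.0 < gravity_level <= 1.0):
        raise InvalidParameterError(
            f"gravity_level must be in (0, 1], got {gravity_level}")
    if bodyweight <= 0 or duration <= 0:
        raise InvalidParameterError("bodyweight and duration must be positive")
    if fluctuation_amplitude < 0 or fluctuation_amplitude >= 0.05:
        raise InvalidParameterError(
            f"fluctuation_amplitude must be in [0, 0.05), got "
            f"{fluctuation_amplitude}")
    n = int(round(duration * sample_rate))
    mean = (1.0 - gravity_level) * bodyweight
    if fluctuation_amplitude == 0.0:
        return np.full(n, mean)
    from gravgait.conditioning import FilterSpec, butterworth
    white = rng.standard_normal(n)
    smooth = butterworth(white, FilterSpec("lowpass", 1.5), sample_rate)
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= fluctuation_amplitude * bodyweight / peak
    return mean + smooth


def synth_emg(phase_profile, stride_time: float, first_contact: float,
              duration: float, rng: np.random.Generator,
              carrier_band: tuple[float, float] = (20.0, 450.0),
              sample_rate: float = ANALOG_RATE,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited-noise EMG with a prescribed stride-phase envelope.

    ``phase_profile`` maps stride phase in [0, 1) to a nonnegative envelope
    amplitude (callable, vectorized).  The carrier is Gaussian noise
    band-passed to ``carrier_band`` and normalized to unit RMS, so the RMS
    of the returned signal tracks the envelope RMS.  Returns
    ``(signal, envelope)``; the envelope is the exact truth channel.
    """
    if stride_time <= 0 or duration <= 0:
        raise InvalidParameterError("stride_time and duration must be positive")
    lo, hi = carrier_band
    if not (0 < lo < hi < sample_rate / 2):
        raise InvalidParameterError(f"invalid carrier band {carrier_band}")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    phase = ((t - first_contact) / stride_time) % 1.0
    env = np.asarray(phase_profile(phase), float)
    if env.shape != (n,):
        raise InvalidParameterError("phase_profile must be vectorized over phase")
    if np.any(env < 0) or not np.all(np.isfinite(env)):
        raise InvalidParameterError("phase profile must be a nonnegative envelope")
    if np.all(env == 0):
        return np.zeros(n), env
    from scipy import signal as sp_signal
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate,
                           output="sos")
    carrier = sp_signal.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(carrier ** 2))
    carrier /= rms
    return env * carrier, env
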