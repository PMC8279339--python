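"""Cohort-level synthetic-trial generation with ground truth.

The default configuration mirrors the study design: 12 participants, four
simulated gravity levels, four target speeds (0.4-1.6 m/s), and 4 good
trials per condition (768 trials).  Default ground-reaction-force shape
parameters are taken from the published per-condition peak table
(bilinearly interpolated over speed and gravity), per-muscle EMG envelopes
carry gravity multipliers that encode the reported direction structure
(quadriceps and medial gastrocnemius decreasing in stance, biceps femoris
increasing in stance, tibialis anterior increasing in swing, soleus and
lateral gastrocnemius unaffected), and participants get multiplicative
random intercepts so the repeated-measures structure of the data is real.

Every generated trial is paired with a :class:`TrialTruth` carrying the
analytic event times, waveform extrema, envelope RMS values, and the
applied multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from gravgait.constants import ANALOG_RATE, EMG_CHANNELS, GRAVITY, MARKER_RATE
from gravgait.errors import InvalidParameterError
from gravgait.trial_io import TrialMeta, TrialRecord
from gravgait.synthetic.walker import Anthropometry, synth_walker_markers
from gravgait.synthetic.waveforms import (
    synth_ap_ml_forces,
    synth_emg,
    synth_support_force,
    synth_vertical_grf,
    vertical_grf_threshold_times,
)

# -- published per-condition GRF peaks (bodyweights) ---------------------
# rows: gravity levels 1, 0.76, 0.45, 0.31 (descending); one block per speed
_TABLE_GRAVITY = np.array([1.0, 0.76, 0.45, 0.31])
_TABLE_SPEED = np.array([0.4, 0.8, 1.2, 1.6])
_TABLE_VERTICAL = np.array([
    [1.063, 0.842, 0.631, 0.382],
    [1.063, 0.853, 0.686, 0.479],
    [1.136, 0.990, 0.804, 0.595],
    [1.268, 1.141, 0.894, 0.669],
])
_TABLE_BRAKING = np.array([
    [-0.076, -0.063, -0.050, -0.025],
    [-0.126, -0.100, -0.078, -0.043],
    [-0.183, -0.155, -0.110, -0.061],
    [-0.232, -0.212, -0.141, -0.073],
])
_TABLE_PROPULSIVE = np.array([
    [0.015, 0.015, 0.012, 0.006],
    [0.018, 0.019, 0.019, 0.013],
    [0.033, 0.030, 0.028, 0.019],
    [0.032, 0.039, 0.028, 0.016],
])
_TABLE_ML = np.array([
    [0.038, 0.031, 0.026, 0.025],
    [0.056, 0.051, 0.044, 0.036],
    [0.072, 0.062, 0.055, 0.045],
    [0.075, 0.068, 0.059, 0.044],
])

#: Default stride time by target speed (s); interpolated in between.
_STRIDE_TIME_SPEED = np.array([0.4, 0.8, 1.2, 1.6])
_STRIDE_TIME = np.array([1.65, 1.35, 1.15, 1.00])

#: Stance duration as a fraction of stride time.
STANCE_FRACTION = 0.62

#: Start of the first right stance in each trial, s (leaves a clean
#: unloaded-plate baseline window).
FIRST_STANCE_START = 0.35


def _interp2(table: np.ndarray, speed: float, gravity: float) -> float:
    """Bilinear interpolation over the (speed, gravity) grid; gravity rows
    are stored in descending order."""
    g = np.clip(gravity, _TABLE_GRAVITY.min(), _TABLE_GRAVITY.max())
    s = np.clip(speed, _TABLE_SPEED.min(), _TABLE_SPEED.max())
    by_speed = [np.interp(g, _TABLE_GRAVITY[::-1], row[::-1]) for row in table]
    return float(np.interp(s, _TABLE_SPEED, by_speed))


@dataclass
class GRFShape:
    """Ground-reaction-force waveform parameters for one condition.

    Peaks are in bodyweights; ``stance_duration`` in seconds.  The global
    vertical maximum of the generated waveform is ``max(peak1, peak2)``.
    """

    peak1: float
    trough: float
    peak2: float
    braking: float
    propulsive: float
    ml: float
    stance_duration: float

    def __post_init__(self):
        for name in ("peak1", "trough", "peak2", "stance_duration"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.trough > min(self.peak1, self.peak2):
            raise InvalidParameterError("trough must not exceed the peaks")

    @property
    def peak_vertical(self) -> float:
        return max(self.peak1, self.peak2)


def default_stride_time(speed: float) -> float:
    return float(np.interp(speed, _STRIDE_TIME_SPEED, _STRIDE_TIME))


def default_grf_shape(speed: float, gravity_level: float) -> GRFShape:
    """Default condition waveform: published vertical/AP/ML peaks with the
    first vertical peak as the global maximum."""
    peak1 = _interp2(_TABLE_VERTICAL, speed, gravity_level)
    return GRFShape(
        peak1=peak1,
        trough=0.75 * peak1,
        peak2=0.97 * peak1,
        braking=_interp2(_TABLE_BRAKING, speed, gravity_level),
        propulsive=_interp2(_TABLE_PROPULSIVE, speed, gravity_level),
        ml=_interp2(_TABLE_ML, speed, gravity_level),
        stance_duration=STANCE_FRACTION * default_stride_time(speed),
    )


# -- EMG envelope structure ----------------------------------------------
# per muscle: list of (phase center, halfwidth, amplitude, gravity tag);
# tags: "stance"/"swing" bursts are scaled by that phase's gravity
# multiplier, "none" bursts are gravity-invariant
_EMG_BURSTS: dict[str, list[tuple[float, float, float, str]]] = {
    "tibialis_anterior": [(0.03, 0.06, 0.9, "stance"), (0.78, 0.16, 1.0, "swing")],
    "medial_gastrocnemius": [(0.42, 0.12, 1.0, "stance")],
    "lateral_gastrocnemius": [(0.42, 0.12, 0.9, "stance")],
    "soleus": [(0.45, 0.13, 1.0, "stance")],
    "rectus_femoris": [(0.10, 0.08, 1.0, "stance"), (0.70, 0.06, 0.5, "none")],
    "vastus_lateralis": [(0.12, 0.09, 1.0, "stance")],
    "vastus_medialis": [(0.12, 0.09, 1.0, "stance")],
    # stance burst kept clear of the stride wrap so the (null) swing RMS
    # does not inherit the stance-phase gravity effect
    "biceps_femoris": [(0.07, 0.05, 0.9, "stance"), (0.95, 0.06, 1.0, "none")],
}

_EMG_BASELINE = 0.05

#: Direction of the gravity effect per muscle and phase ("dec", "inc", None).
EMG_DIRECTIONS: dict[str, dict[str, str | None]] = {
    "tibialis_anterior": {"stance": None, "swing": "inc"},
    "medial_gastrocnemius": {"stance": "dec", "swing": None},
    "lateral_gastrocnemius": {"stance": None, "swing": None},
    "soleus": {"stance": None, "swing": None},
    "rectus_femoris": {"stance": "dec", "swing": None},
    "vastus_lateralis": {"stance": "dec", "swing": None},
    "vastus_medialis": {"stance": "dec", "swing": None},
    "biceps_femoris": {"stance": "inc", "swing": None},
}


def default_emg_multiplier(direction: str | None, gravity_level: float) -> float:
    """Amplitude multiplier encoding the reported gravity directions:
    decreasing muscles lose ~65% of the gravity-dependent share of their
    activity by 0.31 G; increasing muscles gain ~50% of the removed
    bodyweight fraction; unaffected muscles stay at 1."""
    if direction == "dec":
        return 0.35 + 0.65 * gravity_level
    if direction == "inc":
        return 1.5 - 0.5 * gravity_level
    return 1.0


def _cos2_bump_scalar(phi: np.ndarray, center: float, halfwidth: float
                      ) -> np.ndarray:
    d = (phi - center + 0.5) % 1.0 - 0.5
    out = np.zeros_like(phi)
    inside = np.abs(d) < halfwidth
    out[inside] = np.cos(0.5 * np.pi * d[inside] / halfwidth) ** 2
    return out


def emg_envelope_profile(muscle: str, stance_mult: float, swing_mult: float):
    """Vectorized stride-phase -> envelope function for one muscle with the
    given per-phase gravity multipliers applied burst-wise."""
    bursts = _EMG_BURSTS[muscle]

    def profile(phi: np.ndarray) -> np.ndarray:
        env = np.full_like(phi, _EMG_BASELINE, dtype=float)
        for center, halfw, amp, tag in bursts:
            mult = {"stance": stance_mult, "swing": swing_mult,
                    "none": 1.0}[tag]
            env += amp * mult * _cos2_bump_scalar(phi, center, halfw)
        return env

    return profile


# -- configuration and truth ---------------------------------------------


@dataclass
class GeneratorConfig:
    """Study-design configuration of the synthetic cohort."""

    n_participants: int = 12
    gravity_levels: tuple[float, ...] = (1.0, 0.76, 0.55, 0.31)
    speeds: tuple[float, ...] = (0.4, 0.8, 1.2, 1.6)
    trials_per_condition: int = 4
    body_mass: tuple[float, ...] | None = None     # kg per participant
    leg_length: tuple[float, ...] | None = None    # m per participant
    marker_noise_sd: float = 0.001                 # m
    force_noise_sd: float = 1.0                    # N
    emg_carrier_band: tuple[float, float] = (20.0, 450.0)
    support_fluctuation_amplitude: float = 0.04    # fraction of bodyweight
    participant_sd: float = 0.10   # multiplicative random-intercept SD
    trial_jitter_sd: float = 0.03  # per-trial multiplicative peak jitter SD
    seed: int = 0

    def __post_init__(self):
        if any(not (0.0 < g <= 1.0) for g in self.gravity_levels):
            raise InvalidParameterError("gravity levels must lie in (0, 1]")
        if self.trials_per_condition < 1:
            raise InvalidParameterError("trials_per_condition must be >= 1")
        if not (0.0 <= self.support_fluctuation_amplitude < 0.05):
            raise InvalidParameterError(
                "support_fluctuation_amplitude must be < 0.05")
        if self.n_participants < 1:
            raise InvalidParameterError("need at least one participant")

    @property
    def n_trials(self) -> int:
        return (self.n_participants * len(self.gravity_levels)
                * len(self.speeds) * self.trials_per_condition)


@dataclass
class TrialTruth:
    """Ground truth for one generated trial."""

    participant_id: str
    gravity_level: float
    target_speed: float
    rhs1: float                     # true first right heel strike (18 N), s
    rto: float                      # true right toe-off (18 N), s
    rhs2: float                     # true second right heel strike, s
    rhs2_on_plate: bool
    shape: GRFShape                 # waveform parameters actually applied
    stride_length: float            # m
    emg_rms: dict[str, dict[str, float]]         # muscle -> phase -> env RMS
    emg_multipliers: dict[str, dict[str, float]]  # muscle -> phase -> factor
    support_mean: float             # N
    support_max_dev: float          # N
    support_series: np.ndarray | None = field(default=None, repr=False)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d.pop("support_series")
        d["shape"] = asdict(self.shape)
        return d


@dataclass
class GroundTruth:
    """Cohort-level truth: per-trial records plus participant parameters."""

    trials: list[TrialTruth]
    participants: dict[str, dict]

    def to_jsonable(self) -> dict:
        return {
            "participants": self.participants,
            "trials": [t.to_jsonable() for t in self.trials],
        }


# -- trial generation -----------------------------------------------------


def generate_trial(*, participant_id: str = "P01", body_mass: float = 70.0,
                   leg_length: float = 0.88, gravity_level: float = 1.0,
                   target_speed: float = 1.2, shape: GRFShape | None = None,
                   stride_time: float | None = None,
                   emg_multipliers: dict[str, dict[str, float]] | None = None,
                   emg_amplitude: float = 2.0e-4,
                   rhs2_on_plate: bool = True, gate_speed: float | None = None,
                   seed: int | np.random.Generator = 0,
                   marker_noise_sd: float = 0.001, force_noise_sd: float = 1.0,
                   support_fluctuation_amplitude: float = 0.04,
                   carrier_band: tuple[float, float] = (20.0, 450.0),
                   keep_support_series: bool = False,
                   ) -> tuple[TrialRecord, TrialTruth]:
    """Generate one synthetic walking trial plus its ground truth.

    The right foot lands on plate 1, the left on plate 2, and the second
    right contact on plate 3 when ``rhs2_on_plate`` (otherwise it falls
    beyond the instrumented area and only the kinematic route can time it).
    True event times are the analytic 18 N crossings of the noiseless
    vertical waveform.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if stride_time is None:
        stride_time = default_stride_time(target_speed)
    if shape is None:
        shape = default_grf_shape(target_speed, gravity_level)
    bodyweight = body_mass * GRAVITY

    # widen the waveform support so the true (18 N to 18 N) stance equals
    # the configured duration regardless of peak height; otherwise the
    # stance/swing boundary would drift with gravity level and leak a
    # spurious gravity effect into phase-windowed quantities
    stance = shape.stance_duration
    for _ in range(3):
        t_on, t_off = vertical_grf_threshold_times(
            shape.peak1, shape.peak2, stance, bodyweight, threshold=18.0)
        stance *= shape.stance_duration / (t_off - t_on)
    t_on, t_off = vertical_grf_threshold_times(
        shape.peak1, shape.peak2, stance, bodyweight, threshold=18.0)
    s1 = FIRST_STANCE_START                       # first right stance onset
    sL = s1 + 0.5 * stride_time                   # left stance onset
    s2 = s1 + stride_time                         # second right stance onset
    rhs1, rto = s1 + t_on, s1 + t_off
    rhs2 = s2 + t_on
    duration = round(s2 + stance + 0.25, 3)

    nf = int(round(duration * ANALOG_RATE))
    force_time = np.arange(nf) / ANALOG_RATE
    vz = synth_vertical_grf(shape.peak1, shape.trough, shape.peak2, stance,
                            bodyweight)
    ap, ml = synth_ap_ml_forces(shape.braking, shape.propulsive, shape.ml,
                                stance, bodyweight)
    nstance = vz.size

    anth = Anthropometry.from_basics(body_mass, leg_length)
    hip_x = anth.hip_offsets[0]

    plate_forces = [np.zeros((nf, 3)) for _ in range(3)]
    plate_cop = [np.full((nf, 3), np.nan) for _ in range(3)]

    def place(plate: int, onset: float, side_sign: float, contact_y: float):
        i0 = int(round(onset * ANALOG_RATE))
        i1 = min(i0 + nstance, nf)
        m = i1 - i0
        plate_forces[plate][i0:i1, 0] = side_sign * ml[:m]
        plate_forces[plate][i0:i1, 1] = ap[:m]
        plate_forces[plate][i0:i1, 2] = vz[:m]
        # heel-to-toe CoP progression under the foot
        prog = np.linspace(0.0, 0.8 * anth.foot_length, m)
        plate_cop[plate][i0:i1, 0] = side_sign * hip_x
        plate_cop[plate][i0:i1, 1] = contact_y + prog
        plate_cop[plate][i0:i1, 2] = 0.0

    stride_len = target_speed * stride_time
    place(0, s1, +1.0, 0.0)
    place(1, sL, -1.0, 0.5 * stride_len)
    if rhs2_on_plate:
        place(2, s2, +1.0, stride_len)
    if force_noise_sd > 0:
        for p in range(3):
            plate_forces[p] = plate_forces[p] + rng.normal(
                0.0, force_noise_sd, size=(nf, 3))

    # markers: contact times are the true (18 N) heel-strike times
    walker = synth_walker_markers(
        speed=target_speed, stride_time=stride_time, anthropometry=anth,
        contact_times=[rhs1, rhs2], duration=duration, rng=rng,
        marker_noise_sd=marker_noise_sd,
        stance_fraction=min(0.75, (t_off - t_on) / stride_time))
    nk = walker.time.size

    # EMG: burst envelopes with per-phase gravity multipliers
    if emg_multipliers is None:
        emg_multipliers = {
            m: {ph: default_emg_multiplier(dir_, gravity_level)
                for ph, dir_ in phases.items()}
            for m, phases in EMG_DIRECTIONS.items()}
    emg = {}
    emg_rms: dict[str, dict[str, float]] = {}
    t_analog = force_time
    in_stance = (t_analog >= rhs1) & (t_analog < rto)
    in_swing = (t_analog >= rto) & (t_analog < rhs2)
    for muscle in EMG_CHANNELS:
        mult = emg_multipliers[muscle]
        profile = emg_envelope_profile(muscle, mult["stance"], mult["swing"])
        sig, env = synth_emg(profile, stride_time, rhs1, duration, rng,
                             carrier_band=carrier_band)
        emg[muscle] = emg_amplitude * sig
        emg_rms[muscle] = {
            "stance": float(emg_amplitude * np.sqrt(np.mean(env[in_stance] ** 2))),
            "swing": float(emg_amplitude * np.sqrt(np.mean(env[in_swing] ** 2))),
        }

    support = synth_support_force(gravity_level, bodyweight,
                                  support_fluctuation_amplitude, duration, rng)

    if gate_speed is None:
        gate_speed = target_speed * (1.0 + rng.uniform(-0.02, 0.02))

    meta = TrialMeta(participant_id=participant_id, body_mass=body_mass,
                     leg_length=leg_length, gravity_level=gravity_level,
                     target_speed=target_speed, gate_speed=gate_speed)
    trial = TrialRecord(
        marker_time=walker.time, markers=walker.markers,
        force_time=force_time, plate_forces=plate_forces, plate_cop=plate_cop,
        emg_time=force_time.copy(), emg=emg, standing=walker.standing,
        meta=meta)

    truth = TrialTruth(
        participant_id=participant_id, gravity_level=gravity_level,
        target_speed=target_speed, rhs1=rhs1, rto=rto, rhs2=rhs2,
        rhs2_on_plate=rhs2_on_plate, shape=shape, stride_length=stride_len,
        emg_rms=emg_rms, emg_multipliers=emg_multipliers,
        support_mean=float(np.mean(support)),
        support_max_dev=float(np.max(np.abs(support - np.mean(support)))),
        support_series=support if keep_support_series else None)
    return trial, truth


# -- cohort generation ----------------------------------------------------


def _participant_params(config: GeneratorConfig) -> dict[str, dict]:
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(999_999,)))
    out = {}
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        mass = (config.body_mass[i] if config.body_mass is not None
                else float(np.clip(rng.normal(70.0, 8.0), 45.0, 110.0)))
        leg = (config.leg_length[i] if config.leg_length is not None
               else float(np.clip(rng.normal(0.88, 0.04), 0.74, 1.02)))
        factors = {
            "grf": float(np.clip(1.0 + rng.normal(0.0, config.participant_sd),
                                 0.6, 1.4)),
            "stride": float(np.clip(1.0 + rng.normal(0.0, 0.05), 0.8, 1.2)),
        }
        for m in EMG_CHANNELS:
            factors[f"emg_{m}"] = float(np.clip(
                1.0 + rng.normal(0.0, config.participant_sd), 0.6, 1.4))
        out[pid] = {"body_mass": mass, "leg_length": leg, "factors": factors}
    return out


def iter_cohort(config: GeneratorConfig):
    """Yield ``(TrialRecord, TrialTruth)`` for every trial of the cohort,
    deterministically from ``config.seed``."""
    participants = _participant_params(config)
    index = 0
    for pid, pp in participants.items():
        fac = pp["factors"]
        for g in config.gravity_levels:
            for speed in config.speeds:
                base = default_grf_shape(speed, g)
                stride_time = default_stride_time(speed) * fac["stride"]
                for rep in range(config.trials_per_condition):
                    rng = np.random.default_rng(np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(index,)))
                    jit = 1.0 + rng.normal(0.0, config.trial_jitter_sd, size=4)
                    jit = np.clip(jit, 0.7, 1.3)
                    shape = GRFShape(
                        peak1=base.peak1 * fac["grf"] * jit[0],
                        trough=base.trough * fac["grf"] * jit[0],
                        peak2=base.peak2 * fac["grf"] * jit[0],
                        braking=base.braking * fac["grf"] * jit[1],
                        propulsive=base.propulsive * fac["grf"] * jit[2],
                        ml=base.ml * fac["grf"] * jit[3],
                        stance_duration=base.stance_duration * fac["stride"],
                    )
                    emg_jit = 1.0 + rng.normal(
                        0.0, config.trial_jitter_sd, size=len(EMG_CHANNELS))
                    mults = {}
                    for k, muscle in enumerate(EMG_CHANNELS):
                        pm = fac[f"emg_{muscle}"] * float(
                            np.clip(emg_jit[k], 0.7, 1.3))
                        mults[muscle] = {
                            ph: pm * default_emg_multiplier(dir_, g)
                            for ph, dir_ in EMG_DIRECTIONS[muscle].items()}
                    yield generate_trial(
                        participant_id=pid, body_mass=pp["body_mass"],
                        leg_length=pp["leg_length"], gravity_level=g,
                        target_speed=speed, shape=shape,
                        stride_time=stride_time, emg_multipliers=mults,
                        rhs2_on_plate=(rep % 2 == 0), seed=rng,
                        marker_noise_sd=config.marker_noise_sd,
                        force_noise_sd=config.force_noise_sd,
                        support_fluctuation_amplitude=(
                            config.support_fluctuation_amplitude),
                        carrier_band=config.emg_carrier_band)
                    index += 1


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[list[TrialRecord], GroundTruth]:
    """Materialize the whole cohort (use :func:`iter_cohort` for streaming
    over large configurations)."""
    trials, truths = [], []
    for trial, truth in iter_cohort(config):
        trials.append(trial)
        truths.append(truth)
    return trials, GroundTruth(trials=truths,
                               participants=_participant_params(config))
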