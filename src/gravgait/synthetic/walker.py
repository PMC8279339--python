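"""Sagittal 7-segment walker: forward-kinematic marker synthesis.

The walker (pelvis, 2x thigh, 2x shank, 2x foot) produces 100 Hz
trajectories for the full canonical marker set.  Foot motion is prescribed
directly — a periodic heel trajectory whose vertical minimum is an exact
local quadratic centred on each contact time, plus a foot-pitch profile —
and hip/knee angles follow from closed-form two-link inverse kinematics of
hip and ankle positions; forward kinematics of the resulting joint-angle
trajectories then reproduces the foot poses exactly.  This guarantees the
construction constraints downstream tests rely on: the heel-height minimum
coincides with each true contact time, the pelvis advances at exactly the
target speed, and stride length equals speed x stride time.

The walker aims at kinematic *plausibility* (timing, continuity, segment
rigidity), not at reproducing human joint-angle curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gravgait.constants import MARKER_RATE
from gravgait.errors import InvalidAnthropometryError, InvalidParameterError

#: Curvature of the heel-height dip at contact, m s^-2 (sets how sharply
#: the kinematic heel-strike minimum is localised).
DIP_CURVATURE = 5.0

#: Half-duration of the quadratic dip region around contact, s.
DIP_HALFWIDTH = 0.08

#: Default stance fraction of the stride.
STANCE_FRACTION = 0.62

#: Coda pelvis hip-centre offsets from the mid-ASIS point, as fractions of
#: the inter-ASIS distance: (lateral, posterior, inferior).
CODA_FRACTIONS = (0.36, 0.19, 0.30)


@dataclass
class Anthropometry:
    """Segment dimensions of one walker.  All lengths in metres.

    ``leg_length`` is trochanter height (thigh + shank); ``foot_length``
    is the heel-marker-to-hallux distance.
    """

    body_mass: float
    leg_length: float
    thigh_length: float
    shank_length: float
    foot_length: float
    inter_asis: float = 0.24
    heel_marker_height: float = 0.03

    def __post_init__(self):
        for name in ("body_mass", "leg_length", "thigh_length",
                     "shank_length", "foot_length", "inter_asis",
                     "heel_marker_height"):
            val = getattr(self, name)
            if val is None or not np.isfinite(val) or val <= 0:
                raise InvalidAnthropometryError(
                    f"anthropometry field {name!r} missing or non-positive: {val}")

    @classmethod
    def from_basics(cls, body_mass: float, leg_length: float) -> "Anthropometry":
        """Derive segment lengths from leg length with standard proportions."""
        if body_mass is None or body_mass <= 0:
            raise InvalidAnthropometryError(f"invalid body_mass {body_mass}")
        if leg_length is None or leg_length <= 0:
            raise InvalidAnthropometryError(f"invalid leg_length {leg_length}")
        return cls(
            body_mass=body_mass,
            leg_length=leg_length,
            thigh_length=0.53 * leg_length,
            shank_length=0.47 * leg_length,
            foot_length=0.22 * leg_length / 0.88,
        )

    @property
    def hip_offsets(self) -> np.ndarray:
        """(lateral, posterior-negated, inferior-negated) hip-centre offset of
        the *right* hip from the mid-ASIS point, lab axes."""
        fl, fp, fi = CODA_FRACTIONS
        d = self.inter_asis
        return np.array([fl * d, -fp * d, -fi * d])


# -- local marker tables (right side; x mirrored for the left) -----------

def _thigh_locals(anth: Anthropometry) -> dict[str, np.ndarray]:
    L1 = anth.thigh_length
    return {
        "troch": np.array([0.070, 0.000, -0.02]),
        "lat_epi": np.array([0.055, 0.000, -L1]),
        "med_epi": np.array([-0.055, 0.000, -L1]),
        "thigh_c1": np.array([0.070, 0.045, -0.30 * L1]),
        "thigh_c2": np.array([0.082, -0.045, -0.42 * L1]),
        "thigh_c3": np.array([0.055, 0.045, -0.58 * L1]),
        "thigh_c4": np.array([0.078, -0.045, -0.70 * L1]),
    }


def _shank_locals(anth: Anthropometry) -> dict[str, np.ndarray]:
    L2 = anth.shank_length
    return {
        "lat_mall": np.array([0.045, 0.000, -L2]),
        "med_mall": np.array([-0.045, 0.000, -L2]),
        "shank_c1": np.array([0.052, 0.040, -0.25 * L2]),
        "shank_c2": np.array([0.062, -0.040, -0.40 * L2]),
        "shank_c3": np.array([0.042, 0.040, -0.55 * L2]),
        "shank_c4": np.array([0.058, -0.040, -0.70 * L2]),
    }


def _foot_locals(anth: Anthropometry) -> dict[str, np.ndarray]:
    Lf = anth.foot_length
    return {
        "heel": np.array([0.0, 0.0, 0.0]),
        "mt1": np.array([-0.035, 0.70 * Lf, 0.0]),
        "mt5": np.array([0.045, 0.62 * Lf, 0.0]),
        "hallux": np.array([-0.005, Lf, 0.0]),
    }


#: Ankle joint centre in the foot frame (forward and up from the heel marker).
_ANKLE_LOCAL = np.array([0.0, 0.05, 0.055])


def _smootherstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (u * (6.0 * u - 15.0) + 10.0)


def _cos2_bump(phi: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Periodic cos^2 bump of unit height with compact support."""
    d = (phi - center + 0.5) % 1.0 - 0.5
    out = np.zeros_like(phi)
    inside = np.abs(d) < halfwidth
    out[inside] = np.cos(0.5 * np.pi * d[inside] / halfwidth) ** 2
    return out


@dataclass
class WalkerResult:
    """Markers plus the walker's internal truth."""

    time: np.ndarray
    markers: dict[str, np.ndarray]
    standing: dict[str, np.ndarray]
    truth: dict = field(default_factory=dict)


def synth_walker_markers(speed: float, stride_time: float,
                         anthropometry: Anthropometry,
                         contact_times: list[float], duration: float,
                         rng: np.random.Generator | None = None,
                         marker_noise_sd: float = 0.001,
                         stance_fraction: float = STANCE_FRACTION,
                         rate: int = MARKER_RATE) -> WalkerResult:
    """Generate marker trajectories for one walking pass.

    ``contact_times`` are the true right heel-strike times; consecutive
    entries must be one ``stride_time`` apart (constant-speed walker).
    """
    if stride_time <= 0 or speed < 0 or duration <= 0:
        raise InvalidParameterError("speed, stride_time, duration must be positive")
    gaps = np.diff(np.asarray(contact_times, float))
    if len(contact_times) < 1 or (gaps.size and not np.allclose(gaps, stride_time,
                                                                atol=1e-6)):
        raise InvalidParameterError(
            "contact_times must be spaced by stride_time")
    anth = anthropometry
    c0 = float(contact_times[0])
    T = stride_time
    s_frac = stance_fraction
    v = speed
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    L1, L2 = anth.thigh_length, anth.shank_length
    h0 = anth.heel_marker_height

    hip_off = anth.hip_offsets           # right hip from mid-ASIS
    x_r, x_l = hip_off[0], -hip_off[0]

    def heel_pitch(delta: float):
        """Heel position series and foot pitch for one leg (phase offset
        delta: 0 right, 0.5 left)."""
        m = (t - c0) / T - delta
        k = np.floor(m)
        phi = m - k
        y_contact = v * T * (k + delta)  # heel y at this stride's contact
        adv = np.where(phi < s_frac, 0.0,
                       _smootherstep((phi - s_frac) / (1.0 - s_frac)))
        heel_y = y_contact + adv * v * T
        # quadratic dip exactly centred on contact; plateau elsewhere
        d = T * np.minimum(phi, 1.0 - phi)
        q = 0.5 * DIP_CURVATURE * np.minimum(d, DIP_HALFWIDTH) ** 2
        # swing bump with support clear of the dip region
        lo_edge = s_frac
        hi_edge = 1.0 - 1.5 * DIP_HALFWIDTH / T
        center = 0.5 * (lo_edge + hi_edge)
        halfw = 0.5 * (hi_edge - lo_edge)
        bump = 0.10 * _cos2_bump(phi, center, halfw)
        heel_z = h0 + q + bump
        # foot pitch: plantarflex at push-off, slight dorsiflexion pre-landing
        alpha = (np.deg2rad(-25.0) * _cos2_bump(phi, s_frac, 0.12)
                 + np.deg2rad(8.0) * _cos2_bump(phi, 0.88, 0.10))
        return heel_y, heel_z, alpha, phi

    legs = {}
    for side, delta, x_side in (("r", 0.0, x_r), ("l", 0.5, x_l)):
        heel_y, heel_z, alpha, phi = heel_pitch(delta)
        ca, sa = np.cos(alpha), np.sin(alpha)
        # ankle = heel + R_pitch(alpha) @ ankle_local (rotation about lab X)
        ay, az = _ANKLE_LOCAL[1], _ANKLE_LOCAL[2]
        ankle = np.column_stack([
            np.full(n, x_side),
            heel_y + ca * ay - sa * az,
            heel_z + sa * ay + ca * az,
        ])
        legs[side] = dict(heel_y=heel_y, heel_z=heel_z, alpha=alpha,
                          ankle=ankle, phi=phi, x=x_side)

    # pelvis: constant AP speed (exactly v), vertical double-bounce, and a
    # height chosen so the hip-ankle distance never exceeds 98.5% of full
    # leg extension (keeps the two-link IK well posed); the -0.31*v*T AP
    # offset puts the hip over the stance foot at mid single support
    osc = 0.02 * np.cos(4.0 * np.pi * (legs["r"]["phi"] - 0.31))
    pelvis_y = v * (t - c0) - 0.31 * v * T
    need = 0.0
    for side in ("r", "l"):
        a = legs[side]["ankle"]
        dy = (pelvis_y + hip_off[1]) - a[:, 1]
        gap_sq = (0.985 * (L1 + L2)) ** 2 - dy ** 2
        if np.any(gap_sq <= 0):
            raise InvalidParameterError(
                "stride too long for this leg length: ankle out of reach")
        gap = np.sqrt(gap_sq)
        need = max(need, float(np.max(a[:, 2] + gap - (hip_off[2] + osc))))
    pelvis_z = need + osc
    pelvis = np.column_stack([np.zeros(n), pelvis_y, pelvis_z])

    markers: dict[str, np.ndarray] = {}
    # pelvis markers (level pelvis, identity orientation)
    d = anth.inter_asis
    pelvis_locals = {
        "r_asis": np.array([d / 2, 0.0, 0.0]),
        "l_asis": np.array([-d / 2, 0.0, 0.0]),
        "r_psis": np.array([0.06, -0.13, 0.0]),
        "l_psis": np.array([-0.06, -0.13, 0.0]),
    }
    for name, loc in pelvis_locals.items():
        markers[name] = pelvis + loc

    truth_angles = {}
    for side in ("r", "l"):
        leg = legs[side]
        mirror = 1.0 if side == "r" else -1.0
        hip = pelvis + hip_off * np.array([mirror, 1.0, 1.0])
        ankle = leg["ankle"]
        # planar two-link IK in the leg's sagittal plane
        D = ankle[:, 1:] - hip[:, 1:]
        L = np.linalg.norm(D, axis=1)
        L = np.minimum(L, (L1 + L2) * (1 - 1e-9))
        u = D / L[:, None]
        a_len = (L1 ** 2 - L2 ** 2 + L ** 2) / (2.0 * L)
        h = np.sqrt(np.maximum(L1 ** 2 - a_len ** 2, 0.0))
        w = np.column_stack([-u[:, 1], u[:, 0]])     # anterior normal
        knee_yz = hip[:, 1:] + a_len[:, None] * u + h[:, None] * w
        knee = np.column_stack([hip[:, 0], knee_yz])

        # segment frames: X lab-lateral, Z distal->proximal, Y = Z x X
        def frame_markers(origin, z_axis, locals_, mirror):
            X = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
            Z = z_axis / np.linalg.norm(z_axis, axis=1)[:, None]
            Y = np.cross(Z, X)
            Y /= np.linalg.norm(Y, axis=1)[:, None]
            Xo = np.cross(Y, Z)
            out = {}
            for name, loc in locals_.items():
                lx, ly, lz = mirror * loc[0], loc[1], loc[2]
                out[name] = origin + lx * Xo + ly * Y + lz * Z
            return out

        for name, pos in frame_markers(hip, hip - knee,
                                       _thigh_locals(anth), mirror).items():
            markers[f"{side}_{name}"] = pos
        for name, pos in frame_markers(knee, knee - ankle,
                                       _shank_locals(anth), mirror).items():
            markers[f"{side}_{name}"] = pos
        # foot markers via the pitch rotation about lab X
        ca, sa = np.cos(leg["alpha"]), np.sin(leg["alpha"])
        heel = np.column_stack([np.full(n, leg["x"]), leg["heel_y"],
                                leg["heel_z"]])
        for name, loc in _foot_locals(anth).items():
            lx, ly, lz = mirror * loc[0], loc[1], loc[2]
            markers[f"{side}_{name}"] = heel + np.column_stack([
                np.full(n, lx), ca * ly - sa * lz, sa * ly + ca * lz])

        if side == "r":
            # knee flexion angle (0 = straight leg), degrees
            thigh_v = knee - hip
            shank_v = ankle - knee
            cosang = np.sum(thigh_v * shank_v, axis=1) / (
                np.linalg.norm(thigh_v, axis=1) * np.linalg.norm(shank_v, axis=1))
            truth_angles["knee_flexion_deg"] = np.rad2deg(
                np.arccos(np.clip(cosang, -1.0, 1.0)))

    # neutral standing pose (noiseless): legs vertical, feet flat
    standing: dict[str, np.ndarray] = {}
    hip_z_st = h0 + _ANKLE_LOCAL[2] + L1 + L2
    pelvis_st = np.array([0.0, 0.0, hip_z_st - hip_off[2]])
    for name, loc in pelvis_locals.items():
        standing[name] = pelvis_st + loc
    for side, mirror in (("r", 1.0), ("l", -1.0)):
        hip_st = pelvis_st + hip_off * np.array([mirror, 1.0, 1.0])
        knee_st = hip_st + np.array([0.0, 0.0, -L1])
        ankle_st = knee_st + np.array([0.0, 0.0, -L2])
        for name, loc in _thigh_locals(anth).items():
            standing[f"{side}_{name}"] = hip_st + np.array(
                [mirror * loc[0], loc[1], loc[2]])
        for name, loc in _shank_locals(anth).items():
            standing[f"{side}_{name}"] = knee_st + np.array(
                [mirror * loc[0], loc[1], loc[2]])
        heel_st = ankle_st - _ANKLE_LOCAL
        for name, loc in _foot_locals(anth).items():
            standing[f"{side}_{name}"] = heel_st + np.array(
                [mirror * loc[0], loc[1], loc[2]])

    if rng is not None and marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, marker_noise_sd, size=markers[name].shape)

    truth = {
        "contact_times": list(contact_times),
        "stride_length": speed * stride_time,
        "pelvis_mean_speed": float(v),
        **truth_angles,
    }
    return WalkerResult(time=t, markers=markers, standing=standing, truth=truth)
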