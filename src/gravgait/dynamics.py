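"""Sagittal link-segment inverse dynamics for the right leg.

Segment poses come from least-squares (Kabsch) rigid-body fits of the
thigh/shank tracking clusters, calibrated to the anatomical markers in the
neutral-standing reference pose; the foot uses its anatomical markers
directly and the hip centre follows the Coda pelvis regression from the
ASIS/PSIS markers.  Joint angles are the sagittal component of the Cardan
X-Y-Z decomposition of each distal-relative-to-proximal rotation, zeroed
at the standing pose.  Net internal joint moments come from a bottom-up
Newton-Euler recursion (foot, shank, thigh) with Dempster/geometric
inertial parameters, segment accelerations by central differences, and
the measured ground-reaction wrench applied at the centre of pressure.

Sign conventions (all sagittal): ankle plantarflexion positive, knee
extension positive, hip extension positive; positive power = generation.

Gravity acts on the segments at full 1 G regardless of the simulated
gravity level: the harness supports the torso only, not the swinging limbs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from gravgait.constants import GRAVITY, MARKER_RATE
from gravgait.errors import DynamicsError, FrameConstructionError

#: Per-joint sign mapping from lab-X sagittal rotation to the reported
#: convention (hip/knee/ankle; extension, extension, plantarflexion positive).
JOINT_SIGNS = {"hip": -1.0, "knee": 1.0, "ankle": -1.0}

#: Gimbal-proximity flag threshold for the second Cardan rotation, degrees.
GIMBAL_LIMIT_DEG = 80.0


def load_segment_parameters() -> dict[str, dict[str, float]]:
    """Inertial-parameter table (overridable via the packaged CSV)."""
    out = {}
    path = resources.files("gravgait").joinpath("data/segment_parameters.csv")
    with path.open() as fh:
        rows = [r for r in csv.DictReader(
            line for line in fh if not line.startswith("#"))]
    for r in rows:
        out[r["segment"]] = {
            "mass_fraction": float(r["mass_fraction"]),
            "com_fraction": float(r["com_fraction"]),
            "gyration_fraction": float(r["gyration_fraction"]),
        }
    return out


def load_coda_fractions() -> tuple[float, float, float]:
    path = resources.files("gravgait").joinpath("data/coda_pelvis.csv")
    with path.open() as fh:
        rows = {r["offset"]: float(r["fraction"]) for r in csv.DictReader(
            line for line in fh if not line.startswith("#"))}
    return rows["lateral"], rows["posterior"], rows["inferior"]


# -- rigid-body fitting ---------------------------------------------------


def kabsch(ref: np.ndarray, cur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with cur ~= ref @ R.T + t.

    ``ref``/``cur`` are (m, 3) marker sets.  Raises on degenerate
    (collinear) marker configurations.
    """
    ref_c = ref - ref.mean(axis=0)
    cur_c = cur - cur.mean(axis=0)
    H = ref_c.T @ cur_c
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-30):
        raise FrameConstructionError("collinear marker set: frame undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cur.mean(axis=0) - ref.mean(axis=0) @ R.T
    return R, t


def _orthonormal_frame(x_hint: np.ndarray, z_axis: np.ndarray) -> np.ndarray:
    """Frame matrix with exact Z, Y = Z x X_hint, X = Y x Z (columns X,Y,Z).

    Vectorized over leading axis; inputs (N, 3)."""
    Z = z_axis / np.linalg.norm(z_axis, axis=-1, keepdims=True)
    Y = np.cross(Z, x_hint)
    ny = np.linalg.norm(Y, axis=-1, keepdims=True)
    if np.any(ny < 1e-10):
        raise FrameConstructionError("degenerate axis hint: frame undefined")
    Y = Y / ny
    X = np.cross(Y, Z)
    return np.stack([X, Y, Z], axis=-1)


@dataclass
class SegmentPoses:
    """Per-sample segment frames and joint centres for one leg."""

    time: np.ndarray
    frames: dict[str, np.ndarray]     # segment -> (N, 3, 3), columns X,Y,Z
    joints: dict[str, np.ndarray]     # hip/knee/ankle -> (N, 3)
    points: dict[str, np.ndarray]     # auxiliary points (toe_mid, heel)


def _as_series(markers: dict[str, np.ndarray], name: str) -> np.ndarray:
    arr = np.asarray(markers[name], float)
    return arr[None, :] if arr.ndim == 1 else arr


def build_segment_frames(markers: dict[str, np.ndarray],
                         standing: dict[str, np.ndarray],
                         side: str = "r",
                         time: np.ndarray | None = None) -> SegmentPoses:
    """Segment poses per sample from markers plus the standing calibration.

    The thigh and shank are tracked by their 4-marker clusters: anatomical
    points (epicondyles, malleoli) are expressed in cluster coordinates in
    the standing pose and reconstructed per sample from the cluster's
    rigid-body fit.  Pelvis and foot use anatomical markers directly.
    """
    s = side
    need = [f"{s}_{m}" for m in ("lat_epi", "med_epi", "lat_mall", "med_mall",
                                 "heel", "mt1", "mt5")]
    need += ["r_asis", "l_asis", "r_psis", "l_psis"]
    for name in need:
        if name not in markers or name not in standing:
            raise FrameConstructionError(f"missing marker {name}")

    m = {k: _as_series(markers, k) for k in markers}
    n = next(iter(m.values())).shape[0]
    if time is None:
        time = np.arange(n) / MARKER_RATE

    # pelvis frame and Coda hip centre
    r_asis, l_asis = m["r_asis"], m["l_asis"]
    mid_asis = 0.5 * (r_asis + l_asis)
    mid_psis = 0.5 * (m["r_psis"] + m["l_psis"])
    x_hint = r_asis - l_asis
    y_tmp = mid_asis - mid_psis
    # pelvis: exact X along the ASIS line, Z = X x Y_anterior (up), Y = Z x X
    Xp = x_hint / np.linalg.norm(x_hint, axis=-1, keepdims=True)
    Zp = np.cross(Xp, y_tmp)
    Zp = Zp / np.linalg.norm(Zp, axis=-1, keepdims=True)
    Yp = np.cross(Zp, Xp)
    pelvis_R = np.stack([Xp, Yp, Zp], axis=-1)
    fl, fp, fi = load_coda_fractions()
    d_asis = np.linalg.norm(r_asis - l_asis, axis=-1, keepdims=True)
    lat = fl if s == "r" else -fl
    hip_local = np.concatenate([lat * d_asis, -fp * d_asis, -fi * d_asis],
                               axis=-1)
    hip = mid_asis + np.einsum("nij,nj->ni", pelvis_R, hip_local)

    # cluster-calibrated anatomical points
    def cluster_points(cluster: list[str], anatomical: list[str]):
        ref = np.array([standing[c] for c in cluster])
        anat_ref = np.array([standing[a] for a in anatomical])
        out = {a: np.empty((n, 3)) for a in anatomical}
        for i in range(n):
            cur = np.array([m[c][i] for c in cluster])
            R, t = kabsch(ref, cur)
            rec = anat_ref @ R.T + t
            for j, a in enumerate(anatomical):
                out[a][i] = rec[j]
        return out

    thigh_cluster = [f"{s}_thigh_c{k}" for k in range(1, 5)]
    shank_cluster = [f"{s}_shank_c{k}" for k in range(1, 5)]
    th = cluster_points(thigh_cluster, [f"{s}_lat_epi", f"{s}_med_epi"])
    sh = cluster_points(shank_cluster,
                        [f"{s}_lat_mall", f"{s}_med_mall",
                         f"{s}_lat_epi", f"{s}_med_epi"])

    knee = 0.5 * (th[f"{s}_lat_epi"] + th[f"{s}_med_epi"])
    ankle = 0.5 * (sh[f"{s}_lat_mall"] + sh[f"{s}_med_mall"])
    knee_sh = 0.5 * (sh[f"{s}_lat_epi"] + sh[f"{s}_med_epi"])

    sign = 1.0 if s == "r" else -1.0
    thigh_R = _orthonormal_frame(
        sign * (th[f"{s}_lat_epi"] - th[f"{s}_med_epi"]), hip - knee)
    shank_R = _orthonormal_frame(
        sign * (sh[f"{s}_lat_mall"] - sh[f"{s}_med_mall"]), knee_sh - ankle)

    heel, mt1, mt5 = m[f"{s}_heel"], m[f"{s}_mt1"], m[f"{s}_mt5"]
    toe_mid = 0.5 * (mt1 + mt5)
    foot_y = toe_mid - heel
    foot_z = np.cross(sign * (mt5 - mt1), foot_y)
    foot_R = _orthonormal_frame(sign * (mt5 - mt1), foot_z)

    return SegmentPoses(
        time=time,
        frames={"pelvis": pelvis_R, "thigh": thigh_R, "shank": shank_R,
                "foot": foot_R},
        joints={"hip": hip, "knee": knee, "ankle": ankle},
        points={"heel": heel, "toe_mid": toe_mid},
    )


# -- joint angles ---------------------------------------------------------

_JOINT_PAIRS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"),
                "ankle": ("shank", "foot")}


def _cardan_sagittal(R_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal (about-X) angle of the Cardan X-Y-Z decomposition, radians,
    plus a gimbal-proximity flag per sample."""
    a = np.arctan2(-R_rel[..., 1, 2], R_rel[..., 2, 2])
    b = np.arcsin(np.clip(R_rel[..., 0, 2], -1.0, 1.0))
    flag = np.abs(b) > np.deg2rad(GIMBAL_LIMIT_DEG)
    return a, flag


def joint_angles(poses: SegmentPoses, standing_poses: SegmentPoses
                 ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Sagittal joint angles in degrees, zero at the standing reference.

    Returns ``(angles, gimbal_flags)`` keyed by joint.
    """
    angles, flags = {}, {}
    for joint, (prox, dist) in _JOINT_PAIRS.items():
        R_rel = np.einsum("nji,njk->nik", poses.frames[prox],
                          poses.frames[dist])
        a, flag = _cardan_sagittal(R_rel)
        R_rel_st = np.einsum("nji,njk->nik", standing_poses.frames[prox],
                             standing_poses.frames[dist])
        a_st, _ = _cardan_sagittal(R_rel_st)
        angles[joint] = JOINT_SIGNS[joint] * np.rad2deg(
            np.unwrap(a) - float(np.mean(a_st)))
        flags[joint] = flag
    return angles, flags


# -- inverse dynamics -----------------------------------------------------


def _sagittal_angle_series(prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Orientation angle (about lab X) of the distal->proximal axis."""
    v = prox - dist
    return np.unwrap(np.arctan2(-v[:, 1], v[:, 2]))


def net_moments(poses: SegmentPoses, grf: np.ndarray, cop: np.ndarray,
                body_mass: float,
                segment_params: dict | None = None,
                gravity: float = GRAVITY,
                rate: float = MARKER_RATE) -> dict[str, np.ndarray]:
    """Net internal sagittal joint moments (N m) by bottom-up Newton-Euler.

    ``grf``/``cop`` are (N, 3) at the kinematic rate, already low-pass
    filtered and time-aligned with the poses; during swing the external
    wrench must be zero (CoP may be NaN there).  Returned moments follow
    the plantarflexion/extension-positive conventions.
    """
    params = segment_params or load_segment_parameters()
    n = poses.time.size
    grf = np.asarray(grf, float)
    cop = np.asarray(cop, float).copy()
    if grf.shape != (n, 3) or cop.shape != (n, 3):
        raise DynamicsError("GRF/CoP not aligned with poses")
    loaded = np.linalg.norm(grf, axis=1) > 5.0
    if np.any(loaded & ~np.isfinite(cop).all(axis=1)):
        raise DynamicsError("missing CoP during stance")
    cop[~loaded] = 0.0
    grf = np.where(loaded[:, None], grf, 0.0)

    dt = 1.0 / rate
    g_vec = np.array([0.0, 0.0, -gravity])

    hip, knee, ankle = (poses.joints[j] for j in ("hip", "knee", "ankle"))
    toe = poses.points["toe_mid"]

    chain = {
        "ankle": ("foot", ankle, toe),
        "knee": ("shank", knee, ankle),
        "hip": ("thigh", hip, knee),
    }
    moments: dict[str, np.ndarray] = {}

    def cross_x(arm: np.ndarray, force: np.ndarray) -> np.ndarray:
        return arm[:, 1] * force[:, 2] - arm[:, 2] * force[:, 1]

    # distal-interface load ON the current segment (foot starts with the GRF)
    F_dist = grf
    M_dist = np.zeros(n)
    r_dist = cop

    for joint in ("ankle", "knee", "hip"):
        seg, prox_pt, dist_pt = chain[joint]
        p = params[seg]
        mass = p["mass_fraction"] * body_mass
        length = float(np.mean(np.linalg.norm(prox_pt - dist_pt, axis=1)))
        inertia = mass * (p["gyration_fraction"] * length) ** 2
        com = prox_pt + p["com_fraction"] * (dist_pt - prox_pt)

        acc = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
        theta = _sagittal_angle_series(prox_pt, dist_pt)
        alpha = np.gradient(np.gradient(theta, dt), dt)

        # Newton: proximal joint force on this segment
        F_prox = mass * (acc - g_vec) - F_dist
        # Euler about the CoM, sagittal (lab X) component:
        #   I a = M_prox + M_dist + (r_p - r_c) x F_prox + (r_d - r_c) x F_dist
        M_prox = (inertia * alpha - M_dist
                  - cross_x(prox_pt - com, F_prox)
                  - cross_x(r_dist - com, F_dist))
        moments[joint] = JOINT_SIGNS[joint] * M_prox

        # reactions become the next segment's distal load
        F_dist = -F_prox
        M_dist = -M_prox
        r_dist = prox_pt
    return moments


def joint_powers(moments: dict[str, np.ndarray],
                 angles: dict[str, np.ndarray],
                 rate: float = MARKER_RATE) -> dict[str, np.ndarray]:
    """Joint power = sagittal moment x joint angular velocity (W).

    Both inputs follow the same sign convention, so positive power is
    generation and negative power absorption regardless of the joint.
    """
    out = {}
    dt = 1.0 / rate
    for joint, m in moments.items():
        omega = np.gradient(np.deg2rad(angles[joint]), dt)
        out[joint] = m * omega
    return out
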