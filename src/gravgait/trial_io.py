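"""Read/write walking-trial bundles in a canonical open format.

A trial bundle is a directory holding four text files::

    markers.tsv    time + <marker>_x/_y/_z columns, 100 Hz, metres, lab frame
    forces.tsv     time + per-plate channels, 1000 Hz, newtons / metres
    emg.tsv        time + 8 muscle channels, 1000 Hz, volts
    standing.tsv   one row per marker: neutral-standing reference pose
    meta.json      participant anthropometry and condition metadata

Force plates may be encoded either as force + centre of pressure
(``fp<i>_copx`` ...) or as force + moment about the plate origin
(``fp<i>_mx`` ...); on ingest the CoP is recovered from moments with the
standard plate equations.  Numeric text is written with 17 significant
digits so the write->read round trip is lossless at double precision.

Readers *reject* invariant violations (sampling rates exactly 100/1000 Hz,
complete marker and EMG channel sets, monotonic 0-based time) rather than
silently repairing them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gravgait.constants import (
    ANALOG_RATE,
    EMG_CHANNELS,
    MARKER_NAMES,
    MARKER_RATE,
    N_PLATES,
)
from gravgait.errors import SchemaError

#: Vertical force below which the centre of pressure is undefined, N.
COP_MIN_FZ = 1.0

_FLOAT_FMT = "%.17g"


@dataclass
class TrialMeta:
    """Per-trial metadata: who walked, under what condition."""

    participant_id: str
    body_mass: float        # kg
    leg_length: float       # m
    gravity_level: float    # fraction of 1 G carried by the legs
    target_speed: float     # m s^-1
    gate_speed: float       # timing-gate measured speed, m s^-1

    def validate(self) -> None:
        if not (0.0 < self.gravity_level <= 1.0):
            raise SchemaError(
                f"gravity_level must be in (0, 1], got {self.gravity_level}")
        if self.body_mass <= 0:
            raise SchemaError(f"body_mass must be positive, got {self.body_mass}")
        if self.leg_length <= 0:
            raise SchemaError(f"leg_length must be positive, got {self.leg_length}")

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "body_mass": self.body_mass,
            "leg_length": self.leg_length,
            "gravity_level": self.gravity_level,
            "target_speed": self.target_speed,
            "gate_speed": self.gate_speed,
        }


@dataclass
class TrialRecord:
    """One walking pass: markers, force plates, EMG, and metadata.

    All time vectors share a common origin (t = 0 at trial start) and use
    half-open sample intervals, so the 100 Hz and 1000 Hz streams merge
    unambiguously.
    """

    marker_time: np.ndarray                 # (Nk,) s
    markers: dict[str, np.ndarray]          # name -> (Nk, 3) m
    force_time: np.ndarray                  # (Nf,) s
    plate_forces: list[np.ndarray]          # per plate (Nf, 3) N
    plate_cop: list[np.ndarray]             # per plate (Nf, 3) m, NaN unloaded
    emg_time: np.ndarray                    # (Nf,) s
    emg: dict[str, np.ndarray]              # muscle -> (Nf,) V
    standing: dict[str, np.ndarray]         # name -> (3,) m, neutral pose
    meta: TrialMeta = field(repr=False, default=None)

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise SchemaError on violation."""
        _check_rate(self.marker_time, MARKER_RATE, "marker rate")
        _check_rate(self.force_time, ANALOG_RATE, "forceplate rate")
        _check_rate(self.emg_time, ANALOG_RATE, "EMG rate")
        missing = sorted(set(MARKER_NAMES) - set(self.markers))
        if missing:
            raise SchemaError(f"missing marker(s): {', '.join(missing)}")
        missing_emg = sorted(set(EMG_CHANNELS) - set(self.emg))
        if missing_emg:
            raise SchemaError(f"missing EMG channel(s): {', '.join(missing_emg)}")
        if len(self.plate_forces) != N_PLATES:
            raise SchemaError(
                f"expected {N_PLATES} force plates, got {len(self.plate_forces)}")
        n = self.force_time.size
        for i, (f, c) in enumerate(zip(self.plate_forces, self.plate_cop)):
            if f.shape != (n, 3) or c.shape != (n, 3):
                raise SchemaError(f"plate {i + 1}: channel shape mismatch")
        missing_ref = sorted(set(MARKER_NAMES) - set(self.standing))
        if missing_ref:
            raise SchemaError(
                f"standing pose missing marker(s): {', '.join(missing_ref)}")
        self.meta.validate()

    @property
    def bodyweight(self) -> float:
        """Bodyweight at 1 G, N (the force-normalization constant)."""
        from gravgait.constants import GRAVITY
        return self.meta.body_mass * GRAVITY


def _check_rate(t: np.ndarray, rate: int, what: str) -> None:
    if t.ndim != 1 or t.size < 3:
        raise SchemaError(f"{what}: time vector too short")
    if abs(t[0]) > 1e-9:
        raise SchemaError(f"{what}: time must start at 0, got {t[0]}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SchemaError(f"{what}: non-monotonic time")
    if not math.isclose(float(np.median(dt)), 1.0 / rate, rel_tol=1e-6):
        raise SchemaError(
            f"{what}: expected {rate} Hz, got {1.0 / float(np.median(dt)):.6g} Hz")


# -- writing -------------------------------------------------------------


def write_trial(trial: TrialRecord, path: str | Path) -> Path:
    """Write ``trial`` as a TSV+JSON bundle under ``path`` (a directory)."""
    trial.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    mcols = {"time": trial.marker_time}
    for name in MARKER_NAMES:
        xyz = trial.markers[name]
        for j, ax in enumerate("xyz"):
            mcols[f"{name}_{ax}"] = xyz[:, j]
    pd.DataFrame(mcols).to_csv(path / "markers.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)

    fcols = {"time": trial.force_time}
    for i in range(N_PLATES):
        for j, ax in enumerate(("fx", "fy", "fz")):
            fcols[f"fp{i + 1}_{ax}"] = trial.plate_forces[i][:, j]
        for j, ax in enumerate(("copx", "copy", "copz")):
            fcols[f"fp{i + 1}_{ax}"] = trial.plate_cop[i][:, j]
    pd.DataFrame(fcols).to_csv(path / "forces.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)

    ecols = {"time": trial.emg_time}
    for name in EMG_CHANNELS:
        ecols[name] = trial.emg[name]
    pd.DataFrame(ecols).to_csv(path / "emg.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)

    scols = {"marker": list(MARKER_NAMES)}
    arr = np.array([trial.standing[m] for m in MARKER_NAMES])
    for j, ax in enumerate("xyz"):
        scols[ax] = arr[:, j]
    pd.DataFrame(scols).to_csv(path / "standing.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)

    with open(path / "meta.json", "w") as fh:
        json.dump(trial.meta.to_dict(), fh, indent=2)
    return path


# -- reading -------------------------------------------------------------


def read_trial(path: str | Path) -> TrialRecord:
    """Load and validate a trial bundle written by :func:`write_trial`."""
    path = Path(path)
    for fname in ("markers.tsv", "forces.tsv", "emg.tsv", "standing.tsv",
                  "meta.json"):
        if not (path / fname).exists():
            raise SchemaError(f"bundle incomplete: missing {fname}")

    with open(path / "meta.json") as fh:
        raw = json.load(fh)
    try:
        meta = TrialMeta(**{k: raw[k] for k in (
            "participant_id", "body_mass", "leg_length", "gravity_level",
            "target_speed", "gate_speed")})
    except KeyError as exc:
        raise SchemaError(f"meta.json missing field {exc}") from exc

    mk = pd.read_csv(path / "markers.tsv", sep="\t")
    if "time" not in mk.columns:
        raise SchemaError("markers.tsv: missing time column")
    markers: dict[str, np.ndarray] = {}
    for name in MARKER_NAMES:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if not all(c in mk.columns for c in cols):
            raise SchemaError(f"markers.tsv: missing marker {name}")
        markers[name] = mk[cols].to_numpy(float)

    fc = pd.read_csv(path / "forces.tsv", sep="\t")
    if "time" not in fc.columns:
        raise SchemaError("forces.tsv: missing time column")
    plate_forces, plate_cop = [], []
    for i in range(1, N_PLATES + 1):
        fcols = [f"fp{i}_{ax}" for ax in ("fx", "fy", "fz")]
        if not all(c in fc.columns for c in fcols):
            raise SchemaError(f"forces.tsv: missing force channels for plate {i}")
        force = fc[fcols].to_numpy(float)
        ccols = [f"fp{i}_{ax}" for ax in ("copx", "copy", "copz")]
        mcols_ = [f"fp{i}_{ax}" for ax in ("mx", "my", "mz")]
        if all(c in fc.columns for c in ccols):
            cop = fc[ccols].to_numpy(float)
        elif all(c in fc.columns for c in mcols_):
            cop = cop_from_moments(force, fc[mcols_].to_numpy(float))
        else:
            raise SchemaError(
                f"forces.tsv: plate {i} needs CoP (copx/copy/copz) or "
                f"moment (mx/my/mz) channels")
        plate_forces.append(force)
        plate_cop.append(cop)

    eg = pd.read_csv(path / "emg.tsv", sep="\t")
    if "time" not in eg.columns:
        raise SchemaError("emg.tsv: missing time column")
    emg: dict[str, np.ndarray] = {}
    for name in EMG_CHANNELS:
        if name not in eg.columns:
            raise SchemaError(f"emg.tsv: missing EMG channel {name}")
        emg[name] = eg[name].to_numpy(float)

    st = pd.read_csv(path / "standing.tsv", sep="\t")
    standing = {row["marker"]: np.array([row["x"], row["y"], row["z"]])
                for _, row in st.iterrows()}

    trial = TrialRecord(
        marker_time=mk["time"].to_numpy(float),
        markers=markers,
        force_time=fc["time"].to_numpy(float),
        plate_forces=plate_forces,
        plate_cop=plate_cop,
        emg_time=eg["time"].to_numpy(float),
        emg=emg,
        standing=standing,
        meta=meta,
    )
    trial.validate()
    return trial


def cop_from_moments(force: np.ndarray, moment: np.ndarray,
                     plate_z: float = 0.0) -> np.ndarray:
    """Centre of pressure from plate-origin moments.

    Standard plate equations with the origin in the (horizontal) plate
    surface at height ``plate_z``: CoPx = -My/Fz, CoPy = Mx/Fz.  Samples
    with |Fz| below ``COP_MIN_FZ`` get NaN (plate unloaded).
    """
    fz = force[:, 2]
    loaded = np.abs(fz) >= COP_MIN_FZ
    cop = np.full_like(force, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        cop[loaded, 0] = -moment[loaded, 1] / fz[loaded]
        cop[loaded, 1] = moment[loaded, 0] / fz[loaded]
    cop[loaded, 2] = plate_z
    return cop


def validate_bundle(path: str | Path) -> list[str]:
    """Validate a bundle on disk; return a list of problems (empty if OK)."""
    try:
        read_trial(path)
    except SchemaError as exc:
        return [str(exc)]
    return []
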