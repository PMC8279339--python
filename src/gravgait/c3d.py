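"""Minimal native reader for the C3D motion-capture standard.

Supports the common modern subset of the standard: Intel (little-endian)
byte order with floating-point 3D and analog data, the ``POINT`` and
``ANALOG`` parameter groups, and per-frame interleaved storage.  Vendor
marker/analog labels are mapped onto the canonical trial schema by
caller-supplied dictionaries; sampling rates must natively match the
canonical 100 Hz (points) and 1000 Hz (analog) — resampling is
deliberately disallowed.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from gravgait.constants import ANALOG_RATE, EMG_CHANNELS, MARKER_NAMES, \
    MARKER_RATE, N_PLATES
from gravgait.errors import IngestError
from gravgait.trial_io import TrialMeta, TrialRecord, cop_from_moments

_INTEL = 84


def _read_parameters(buf: bytes, start: int):
    """Parse the parameter section into {group: {param: value}}."""
    if len(buf) < start + 4:
        raise IngestError("truncated parameter section")
    proc = buf[start + 3]
    if proc != _INTEL:
        raise IngestError(f"unsupported processor type {proc} (Intel only)")
    groups_by_id: dict[int, str] = {}
    params: dict[str, dict[str, object]] = {}
    pos = start + 4
    while pos < len(buf) - 1:
        n_name = struct.unpack_from("b", buf, pos)[0]
        group_id = struct.unpack_from("b", buf, pos + 1)[0]
        if n_name == 0 or group_id == 0:
            break
        n_name = abs(n_name)
        name = buf[pos + 2:pos + 2 + n_name].decode("ascii", "replace")
        p = pos + 2 + n_name
        offset = struct.unpack_from("<h", buf, p)[0]
        next_pos = p + offset if offset > 0 else len(buf)
        if group_id < 0:                       # group record
            groups_by_id[-group_id] = name
            params.setdefault(name, {})
        else:                                   # parameter record
            gname = groups_by_id.get(group_id, f"G{group_id}")
            dtype = struct.unpack_from("b", buf, p + 2)[0]
            ndims = buf[p + 3]
            dims = list(buf[p + 4:p + 4 + ndims])
            dstart = p + 4 + ndims
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:                     # characters
                raw = buf[dstart:dstart + count]
                if len(dims) == 2:
                    w = dims[0]
                    value = [raw[i * w:(i + 1) * w].decode("ascii", "replace")
                             .strip() for i in range(dims[1])]
                else:
                    value = raw.decode("ascii", "replace").strip()
            elif dtype == 1:
                value = list(raw_b := buf[dstart:dstart + count])
            elif dtype == 2:
                value = list(struct.unpack_from(f"<{count}h", buf, dstart))
            elif dtype == 4:
                value = list(struct.unpack_from(f"<{count}f", buf, dstart))
            else:
                raise IngestError(f"unknown parameter type {dtype}")
            if isinstance(value, list) and len(value) == 1 and dtype != -1:
                value = value[0]
            params.setdefault(gname, {})[name] = value
        if offset <= 0:
            break
        pos = next_pos
    return params


def read_c3d(path: str | Path, marker_map: dict[str, str],
             analog_map: dict[str, str], *, meta: TrialMeta,
             standing: dict[str, np.ndarray] | None = None) -> TrialRecord:
    """Ingest a C3D file as a :class:`TrialRecord`.

    ``marker_map`` / ``analog_map`` translate vendor labels to canonical
    names (markers; ``fp<i>_<fx|fy|fz|copx|copy|copz|mx|my|mz>`` plate
    channels and muscle names).  ``standing`` defaults to the first marker
    frame (a neutral-pose capture should be supplied when available).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 512:
        raise IngestError("file too short for a C3D header")
    param_block = raw[0]
    if raw[1] != 0x50:
        raise IngestError("not a C3D file (bad magic byte)")
    n_points = struct.unpack_from("<H", raw, 2)[0]
    analog_per_frame_total = struct.unpack_from("<H", raw, 4)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    point_scale = struct.unpack_from("<f", raw, 12)[0]
    data_block = struct.unpack_from("<H", raw, 16)[0]
    analog_per_frame = struct.unpack_from("<H", raw, 18)[0]
    point_rate = struct.unpack_from("<f", raw, 20)[0]
    n_frames = last_frame - first_frame + 1

    if point_scale >= 0:
        raise IngestError("integer C3D data not supported (float only)")

    params = _read_parameters(raw, (param_block - 1) * 512)
    point_labels = params.get("POINT", {}).get("LABELS", [])
    analog_labels = params.get("ANALOG", {}).get("LABELS", [])
    if isinstance(point_labels, str):
        point_labels = [point_labels]
    if isinstance(analog_labels, str):
        analog_labels = [analog_labels]
    point_rate = float(params.get("POINT", {}).get("RATE", point_rate))
    n_channels = (analog_per_frame_total // analog_per_frame
                  if analog_per_frame else 0)
    analog_rate = float(params.get("ANALOG", {}).get(
        "RATE", point_rate * analog_per_frame))

    if abs(point_rate - MARKER_RATE) > 1e-6:
        raise IngestError(
            f"unsupported rate: point rate {point_rate} Hz != {MARKER_RATE} Hz")
    if abs(analog_rate - ANALOG_RATE) > 1e-6:
        raise IngestError(
            f"unsupported rate: analog rate {analog_rate} Hz != "
            f"{ANALOG_RATE} Hz")

    units = params.get("POINT", {}).get("UNITS", "mm")
    to_m = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(str(units).strip().lower())
    if to_m is None:
        raise IngestError(f"unknown POINT:UNITS {units!r}")

    # data: per frame, n_points * 4 floats then analog_per_frame * n_channels
    frame_floats = n_points * 4 + analog_per_frame * n_channels
    data = np.frombuffer(raw, dtype="<f4", count=frame_floats * n_frames,
                         offset=(data_block - 1) * 512)
    data = data.reshape(n_frames, frame_floats)
    points = data[:, :n_points * 4].reshape(n_frames, n_points, 4)
    analog = data[:, n_points * 4:].reshape(
        n_frames, analog_per_frame, n_channels).reshape(-1, n_channels) \
        if n_channels else np.empty((0, 0))

    # map labels
    markers: dict[str, np.ndarray] = {}
    for i, lab in enumerate(point_labels[:n_points]):
        if lab in marker_map:
            markers[marker_map[lab]] = points[:, i, :3].astype(float) * to_m
    missing = sorted(set(MARKER_NAMES) - set(markers))
    if missing:
        raise IngestError(f"unmappable marker label(s); canonical marker(s) "
                          f"missing: {', '.join(missing)}")

    channels: dict[str, np.ndarray] = {}
    for i, lab in enumerate(analog_labels[:n_channels]):
        if lab in analog_map:
            channels[analog_map[lab]] = analog[:, i].astype(float)

    emg = {}
    for muscle in EMG_CHANNELS:
        if muscle not in channels:
            raise IngestError(f"unmappable analog labels: EMG channel "
                              f"{muscle} missing")
        emg[muscle] = channels[muscle]

    na = analog.shape[0]
    plate_forces, plate_cop = [], []
    for p in range(1, N_PLATES + 1):
        try:
            force = np.column_stack([channels[f"fp{p}_{ax}"]
                                     for ax in ("fx", "fy", "fz")])
        except KeyError as exc:
            raise IngestError(f"plate {p} force channel missing: {exc}") from exc
        if all(f"fp{p}_{ax}" in channels for ax in ("copx", "copy", "copz")):
            cop = np.column_stack([channels[f"fp{p}_{ax}"]
                                   for ax in ("copx", "copy", "copz")])
        elif all(f"fp{p}_{ax}" in channels for ax in ("mx", "my", "mz")):
            cop = cop_from_moments(force, np.column_stack(
                [channels[f"fp{p}_{ax}"] for ax in ("mx", "my", "mz")]))
        else:
            raise IngestError(f"plate {p} needs CoP or moment channels")
        plate_forces.append(force)
        plate_cop.append(cop)

    marker_time = np.arange(n_frames) / MARKER_RATE
    analog_time = np.arange(na) / ANALOG_RATE
    if standing is None:
        standing = {name: arr[0].copy() for name, arr in markers.items()}

    trial = TrialRecord(
        marker_time=marker_time, markers=markers,
        force_time=analog_time, plate_forces=plate_forces,
        plate_cop=plate_cop, emg_time=analog_time.copy(), emg=emg,
        standing=standing, meta=meta)
    trial.validate()
    return trial
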