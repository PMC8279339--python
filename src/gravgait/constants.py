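"""Canonical rates, names, and frame conventions shared across the pipeline.

Lab frame: X points rightward, Y anterior (direction of travel), Z vertical
up; right-handed.  Vertical ground reaction force is positive upward and
braking force is negative along Y.
"""

from __future__ import annotations

#: Marker (kinematic) sampling rate, Hz.
MARKER_RATE: int = 100

#: Force-plate and EMG (analog) sampling rate, Hz.
ANALOG_RATE: int = 1000

#: Gravitational acceleration used for bodyweight normalization, m s^-2.
GRAVITY: float = 9.81

#: Surface-EMG channel names (canonical order).
EMG_CHANNELS: tuple[str, ...] = (
    "tibialis_anterior",
    "medial_gastrocnemius",
    "lateral_gastrocnemius",
    "soleus",
    "rectus_femoris",
    "vastus_lateralis",
    "vastus_medialis",
    "biceps_femoris",
)

#: Anatomical markers carried on the pelvis.
PELVIS_MARKERS: tuple[str, ...] = ("r_asis", "l_asis", "r_psis", "l_psis")

#: Per-side anatomical markers (prefix with ``r_`` / ``l_``).
SIDE_ANATOMICAL: tuple[str, ...] = (
    "troch",       # greater trochanter of the femur
    "lat_epi",     # femur lateral epicondyle
    "med_epi",     # femur medial epicondyle
    "lat_mall",    # apex of the lateral malleolus
    "med_mall",    # apex of the medial malleolus
    "heel",        # posterior calcaneus
    "mt1",         # head of the 1st metatarsal
    "mt5",         # head of the 5th metatarsal
    "hallux",
)

#: Per-side tracking-cluster markers (4-marker rigid bodies, thigh and shank).
SIDE_CLUSTER: tuple[str, ...] = (
    "thigh_c1", "thigh_c2", "thigh_c3", "thigh_c4",
    "shank_c1", "shank_c2", "shank_c3", "shank_c4",
)


def _full_marker_set() -> tuple[str, ...]:
    names = list(PELVIS_MARKERS)
    for side in ("r", "l"):
        names += [f"{side}_{m}" for m in SIDE_ANATOMICAL]
        names += [f"{side}_{m}" for m in SIDE_CLUSTER]
    return tuple(names)


#: Complete canonical marker set (38 markers).
MARKER_NAMES: tuple[str, ...] = _full_marker_set()

#: Number of instrumented force plates in the walkway.
N_PLATES: int = 3
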