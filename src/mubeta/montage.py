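"""Electrode geometry for the 32-channel 10-20 cap plus two EOG electrodes.

Scalp positions are unit vectors on a best-fit sphere (x: left->right,
y: back->front, z: down->up). Only the direction matters for spherical-spline
interpolation, so the head radius is normalised away.
"""

from __future__ import annotations

import numpy as np

# 32 scalp channels of the EasyCAP layout (10-20 system), as unit vectors.
SCALP_POSITIONS: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.286926, +0.955434, -0.069417),
    "Fp2": (+0.273108, +0.959442, -0.069886),
    "F7": (-0.761091, +0.636320, -0.125849),
    "F3": (-0.530611, +0.727803, +0.434458),
    "Fz": (-0.005542, +0.752315, +0.658780),
    "F4": (+0.527957, +0.738581, +0.419237),
    "F8": (+0.755201, +0.642646, -0.129139),
    "FT9": (-0.817776, +0.303867, -0.488781),
    "FC5": (-0.875802, +0.399740, +0.270515),
    "FC1": (-0.360029, +0.443276, +0.820905),
    "FC2": (+0.353716, +0.452985, +0.818346),
    "FC6": (+0.872295, +0.409523, +0.267194),
    "FT10": (+0.812310, +0.306022, -0.496491),
    "T7": (-0.993507, +0.011420, -0.113195),
    "C3": (-0.717788, +0.058141, +0.693830),
    "Cz": (-0.004666, +0.078127, +0.996933),
    "C4": (+0.721758, +0.066410, +0.688952),
    "T8": (+0.992984, +0.023297, -0.115933),
    "TP9": (-0.845162, -0.288458, -0.449992),
    "CP5": (-0.884013, -0.324714, +0.336277),
    "CP1": (-0.354751, -0.295410, +0.887065),
    "CP2": (+0.366536, -0.293862, +0.882778),
    "CP6": (+0.889207, -0.313882, +0.332850),
    "TP10": (+0.839900, -0.295803, -0.455048),
    "P7": (-0.791889, -0.609900, -0.030560),
    "P3": (-0.543895, -0.623810, +0.561283),
    "Pz": (-0.005213, -0.614701, +0.788743),
    "P4": (+0.549258, -0.617075, +0.563501),
    "P8": (+0.789349, -0.613136, -0.031512),
    "O1": (-0.301309, -0.949771, +0.084548),
    "Oz": (-0.007690, -0.989448, +0.144685),
    "O2": (+0.290228, -0.953200, +0.084724),
}

# Periocular electrodes: EOGV below the left eye, EOGH at the left outer
# canthus. Not on the scalp sphere in reality; the unit vectors below are
# only used for distance-based artifact projection, never for interpolation.
EOG_POSITIONS: dict[str, tuple[float, float, float]] = {
    "EOGV": (-0.30, +0.92, -0.28),
    "EOGH": (-0.55, +0.80, -0.22),
}

EEG_CHANNELS: list[str] = list(SCALP_POSITIONS)
EOG_CHANNELS: list[str] = list(EOG_POSITIONS)
ALL_CHANNELS: list[str] = EEG_CHANNELS + EOG_CHANNELS

#: Six regions of interest used for ERD/S aggregation and statistics.
DEFAULT_ROIS: dict[str, list[str]] = {
    "FL": ["Fp1", "F3", "F7"],
    "FR": ["Fp2", "F4", "F8"],
    "CL": ["FC1", "FC5", "C3", "CP1", "CP5"],
    "CR": ["FC2", "FC6", "C4", "CP2", "CP6"],
    "PL": ["P3", "P7", "O1"],
    "PR": ["P4", "P8", "O2"],
}


def default_montage() -> dict[str, tuple[float, float, float]]:
    """Full channel->unit-vector mapping (32 scalp + 2 EOG)."""
    return {**SCALP_POSITIONS, **EOG_POSITIONS}


def positions_array(labels: list[str], montage: dict | None = None) -> np.ndarray:
    """Stack montage positions for ``labels`` into an (n, 3) unit-vector array."""
    montage = default_montage() if montage is None else montage
    missing = [ch for ch in labels if ch not in montage]
    if missing:
        raise KeyError(f"channels missing from montage: {missing}")
    pos = np.asarray([montage[ch] for ch in labels], dtype=float)
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def hemisphere_of(label: str) -> str:
    """Classify a 10-20 label as 'left', 'right' or 'mid' by its number.

    Odd electrode numbers lie over the left hemisphere, even numbers over the
    right, and 'z' suffixes on the midline.
    """
    if label.upper().startswith("EOG"):
        return "left"  # both periocular electrodes sit at the left eye
    if label.endswith("z"):
        return "mid"
    digits = "".join(c for c in label if c.isdigit())
    if not digits:
        raise ValueError(f"cannot infer hemisphere for channel {label!r}")
    return "left" if int(digits) % 2 == 1 else "right"
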