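"""Spherical scalp montage and named channel sets.

Positions are generated on a unit sphere from the extended 10-20 grid:
rows (Fp..O) map to an anterior-posterior rotation, columns (z, 1..10) to a
lateral rotation, with the outermost numbered columns (9/10) lying below the
equator (the "neck" row).  Absolute anatomical accuracy is not required by
any consumer; geometric plausibility (vertex at +z, neck row at z<0,
left/right symmetry) is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 64-channel cap labels (online reference FCz kept separate).
STANDARD_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

# A small head-spanning subset used for fast synthetic studies.
STANDARD_16 = [
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "TP10", "P3", "Pz", "P4", "Oz",
]

_ROW_ANGLE = {
    "Fp": 90.0, "AF": 67.5, "F": 45.0, "FT": 33.75, "FC": 22.5,
    "C": 0.0, "T": 0.0, "CP": -22.5, "TP": -33.75, "P": -45.0,
    "PO": -67.5, "O": -90.0,
}
_COL_ANGLE = {0: 0.0, 1: 22.5, 2: 45.0, 3: 67.5, 4: 90.0, 5: 112.5}


def _parse_label(label: str) -> tuple[str, int, int]:
    """Split an extended 10-20 label into (row, column index, side).

    side: -1 left (odd), +1 right (even), 0 midline (z).
    """
    if label.endswith("z"):
        return label[:-1], 0, 0
    i = len(label)
    while i > 0 and label[i - 1].isdigit():
        i -= 1
    row, num = label[:i], int(label[i:])
    side = -1 if num % 2 else 1
    col = (num + 1) // 2
    return row, col, side


def position_for(label: str) -> np.ndarray:
    """Unit-sphere 3D position (x right, y anterior, z up) for a 10-20 label."""
    row, col, side = _parse_label(label)
    if row not in _ROW_ANGLE:
        raise ValueError(f"unknown electrode row in label {label!r}")
    rho = np.deg2rad(_ROW_ANGLE[row])
    # T7/T8 sit on the ear axis regardless of the stated column number.
    lam = np.deg2rad(90.0 if row == "T" else _COL_ANGLE[col]) * side
    if abs(_ROW_ANGLE[row]) == 90.0 and col > 0:
        # Fp1/2, O1/2: the grid degenerates at the front/back poles of the
        # equator; spread these along the equator ring instead.
        az = np.deg2rad(18.0 * col)
        return np.array([side * np.sin(az), np.sign(_ROW_ANGLE[row]) * np.cos(az), 0.0])
    x = np.cos(rho) * np.sin(lam)
    y = np.sin(rho)
    z = np.cos(rho) * np.cos(lam)
    v = np.array([x, y, z])
    return v / np.linalg.norm(v)


@dataclass
class ChannelLayout:
    """Ordered channel names with unit-sphere positions and named sets."""

    names: list[str]
    positions: np.ndarray  # (n_channels, 3)
    reference: str = "FCz"
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions length mismatch")
        if not self.sets:
            self.sets = channel_sets(self.names)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)

    def indices(self, set_name: str) -> np.ndarray:
        return np.array([self.names.index(c) for c in self.sets[set_name]], dtype=int)


def channel_sets(names: list[str]) -> dict[str, list[str]]:
    """Named channel groups used by artifact scoring and footprint features.

    neck    -- lowest electrode row (columns 9/10, below the equator)
    lateral -- temporal/parietal rim (columns 5-8), excluding neck
    medial  -- midline and +-1 columns
    frontal -- Fp/AF/F rows (eye-artifact projection zone)
    """
    sets: dict[str, list[str]] = {"neck": [], "lateral": [], "medial": [], "frontal": []}
    for label in names:
        row, col, _side = _parse_label(label)
        if col == 5:
            sets["neck"].append(label)
        elif col in (3, 4) or row == "T":
            sets["lateral"].append(label)
        if col <= 1:
            sets["medial"].append(label)
        if row in ("Fp", "AF", "F"):
            sets["frontal"].append(label)
    return sets


def make_layout(names: list[str] | None = None, reference: str = "FCz") -> ChannelLayout:
    names = list(STANDARD_64 if names is None else names)
    pos = np.vstack([position_for(n) for n in names])
    return ChannelLayout(names=names, positions=pos, reference=reference)
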