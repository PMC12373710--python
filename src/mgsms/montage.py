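"""The 20-electrode 10-20 montage used throughout the package.

Channel order is canonical: every channels-by-samples array in this package
uses this ordering, and all on-disk CSV headers follow it.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order (anterior to posterior, left to right).
MONTAGE_20: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Schematic 2-D positions on the unit head disc (x: left->right, y: posterior->anterior).
#: Used only to construct template topographies, not for source analysis.
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.48), "Fz": (0.0, 0.50),
    "F4": (0.55, 0.48), "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.81, -0.59), "P3": (-0.55, -0.48), "Pz": (0.0, -0.50),
    "P4": (0.55, -0.48), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.95), "O2": (0.31, -0.95),
}


def montage_xy(channel_names: tuple[str, ...] | list[str] = MONTAGE_20) -> np.ndarray:
    """Return the (C, 2) array of schematic positions for the given channels.

    Raises
    ------
    ValueError
        If a channel label is not part of the 10-20 montage table.
    """
    rows = []
    for name in channel_names:
        if name not in POSITIONS_2D:
            raise ValueError(f"unknown channel label: {name!r}")
        rows.append(POSITIONS_2D[name])
    return np.asarray(rows, dtype=float)
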