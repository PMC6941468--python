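"""Standard 10-20 scalp montage: the 19 channels and idealized positions.

Positions are given on a sphere in a head-shaped frame (+x right, +y
anterior, +z vertex). They are schematic 10-20 placements, adequate for the
spherical forward model used by the synthetic generator; they are not
digitized electrode coordinates.
"""

from __future__ import annotations

import numpy as np

#: The standard 19 channels of the 10-20 system, fixed order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# (inclination from vertex [deg], azimuth from anterior midline [deg],
#  positive azimuth toward the LEFT ear)
_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (90.0, 18.0), "Fp2": (90.0, -18.0),
    "F7": (90.0, 54.0), "F8": (90.0, -54.0),
    "T3": (90.0, 90.0), "T4": (90.0, -90.0),
    "T5": (90.0, 126.0), "T6": (90.0, -126.0),
    "O1": (90.0, 162.0), "O2": (90.0, -162.0),
    "F3": (62.0, 40.0), "F4": (62.0, -40.0),
    "C3": (45.0, 90.0), "C4": (45.0, -90.0),
    "P3": (62.0, 140.0), "P4": (62.0, -140.0),
    "Fz": (45.0, 0.0), "Pz": (45.0, 180.0),
    "Cz": (0.0, 0.0),
}


def _direction(incl_deg: float, azim_deg: float) -> np.ndarray:
    incl = np.deg2rad(incl_deg)
    azim = np.deg2rad(azim_deg)
    return np.array(
        [-np.sin(incl) * np.sin(azim), np.sin(incl) * np.cos(azim), np.cos(incl)]
    )


def electrode_positions(radius: float = 1.2) -> np.ndarray:
    """Positions of the 19 channels, shape (19, 3), at the given sphere radius.

    The electrode sphere sits outside the unit source sphere (default radius
    1.2) so scalp sensors never coincide with cortical sources.
    """
    return radius * np.array([_direction(*_ANGLES[ch]) for ch in CHANNELS_1020])
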