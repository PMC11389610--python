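"""Angle conventions and axial (period-180) helpers.

Pixel coordinates are (x = column, y = row) with rows increasing downward;
every angle is computed after flipping the row axis so that angles follow
the mathematical counter-clockwise, y-up convention.
"""

from __future__ import annotations

import numpy as np


def angle_of_vector(dx: float | np.ndarray, dy_row: float | np.ndarray) -> np.ndarray:
    """Directional angle in [0, 360) of a vector given in pixel coordinates.

    ``dy_row`` is the displacement along image rows (downward positive); it
    is sign-flipped so the result is counter-clockwise from +x, y-up.
    """
    return np.degrees(np.arctan2(-np.asarray(dy_row, dtype=float),
                                 np.asarray(dx, dtype=float))) % 360.0


def fold_axial(angle_deg: float | np.ndarray) -> np.ndarray:
    """Fold an angle into the axial range [0, 180)."""
    return np.asarray(angle_deg, dtype=float) % 180.0


def axial_difference(a_deg, b_deg) -> np.ndarray:
    """Smallest axial (mod-180) separation between two angles, in [0, 90]."""
    d = np.abs(fold_axial(a_deg) - fold_axial(b_deg))
    return np.minimum(d, 180.0 - d)


def axial_deviation_from_90(coo_deg) -> np.ndarray:
    """Axial distance of a corrected orientation from the 90 deg reference."""
    return axial_difference(coo_deg, 90.0)
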