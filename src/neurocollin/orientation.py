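"""Moment-based ellipse fitting and axial orientation extraction.

Each kept segmentation is summarized by the ellipse with the same second
central moments as its pixel set (each pixel treated as a unit square, so
degenerate single-row/column objects still have positive width).  The
angle of the major axis against the +x axis, folded into [0, 180), is the
neuron's uncorrected orientation (UncO).  Near-circular objects carry no
meaningful axis direction; :func:`eccentricity_gate` excludes them from
orientation analyses while keeping them in neuron counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segmentation import LabelMask

#: (major-minor)/major below which an orientation is flagged unstable.
ISOTROPY_EPS = 1e-3


@dataclass
class EllipseFit:
    """Moment-matched ellipse of one segment.

    ``unco`` is axial: the angle of the major axis versus +x (counter-
    clockwise, y-up), in [0, 180).  ``valid`` is False when the orientation
    is undefined (fewer than 3 pixels, zero moment matrix, or isotropic fit
    within :data:`ISOTROPY_EPS`); such records must be excluded from
    collinearity statistics rather than silently assigned an angle.
    """

    center: tuple[float, float]     # (x, y) pixels
    major: float                    # µm, full length
    minor: float                    # µm, full width
    unco: float                     # degrees in [0, 180); NaN if not valid
    valid: bool = True

    @property
    def axis_ratio(self) -> float:
        return self.major / self.minor if self.minor > 0 else np.inf


def fit_ellipse(coords: np.ndarray, pixel_size: float = 1.0) -> EllipseFit:
    """Fit a moment-matched ellipse to a pixel set.

    Parameters
    ----------
    coords
        (N, 2) array of (row, col) pixel coordinates of one object.
    pixel_size
        Micrometres per pixel; axis lengths are returned in µm.

    Notes
    -----
    The covariance of the pixel centres plus the 1/12 unit-square term is
    matched to that of a uniform filled ellipse, whose variance along a
    semi-axis ``a`` is ``a²/4``; full axis lengths are therefore
    ``4·sqrt(eigenvalue)``.  The orientation comes from the principal
    eigenvector after sign-flipping the row axis (y-up convention).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) array of (row, col)")
    n = len(coords)
    # y-up: x = col, y = -row
    xy = np.column_stack([coords[:, 1], -coords[:, 0]])
    cx, cy_up = xy.mean(axis=0)
    center = (float(cx), float(-cy_up))       # back to (x, y=row) pixels

    if n < 3:
        major = minor = float(4.0 * np.sqrt(1.0 / 12.0) * pixel_size)
        return EllipseFit(center=center, major=major, minor=minor,
                          unco=float("nan"), valid=False)

    cov = np.cov(xy, rowvar=False, bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)        # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0:
        return EllipseFit(center=center, major=0.0, minor=0.0,
                          unco=float("nan"), valid=False)
    major = 4.0 * np.sqrt(lam_major) * pixel_size
    minor = 4.0 * np.sqrt(max(lam_minor, 0.0)) * pixel_size
    vx, vy = evecs[:, 1]
    unco = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    if unco >= 180.0:       # guard the exact-180 fold
        unco = 0.0
    valid = (major - minor) / major >= ISOTROPY_EPS
    return EllipseFit(center=center, major=float(major), minor=float(minor),
                      unco=unco if valid else float("nan"), valid=valid)


def eccentricity_gate(fit: EllipseFit, min_ratio: float = 1.05) -> bool:
    """True iff the fit is valid and elongated enough for a meaningful angle."""
    return bool(fit.valid and fit.minor > 0 and fit.major / fit.minor >= min_ratio)


def fit_ellipses(
    mask: LabelMask | np.ndarray,
    pixel_size: float = 1.0,
    min_ratio: float = 1.05,
) -> pd.DataFrame:
    """Fit every labeled object; returns one row per label.

    Columns: label, x, y, major_um, minor_um, unco_deg, ecc_ok.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    rows = []
    for rp in regionprops(labels):
        fit = fit_ellipse(rp.coords, pixel_size=pixel_size)
        rows.append(dict(
            label=int(rp.label), x=fit.center[0], y=fit.center[1],
            major_um=fit.major, minor_um=fit.minor, unco_deg=fit.unco,
            ecc_ok=eccentricity_gate(fit, min_ratio),
        ))
    return pd.DataFrame(rows, columns=["label", "x", "y", "major_um",
                                       "minor_um", "unco_deg", "ecc_ok"])
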