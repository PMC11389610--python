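"""Curvature correction of neuron orientations against a layer centerline.

The pyramidal cell layer is curved, so the raw axial orientation of a
neuron (UncO, versus the image x-axis) is not comparable across the layer.
For each neuron the correction angle (CorrA) is the direction from its
centroid to the closest point on a manually drawn centerline of the layer
— i.e. the local layer normal through that neuron.  The corrected
orientation is

    CoO = (CorrA - UncO + 90)  mod 180

so that a neuron whose major axis is parallel to the local normal scores
exactly 90 deg regardless of where it sits on the curve, and the axial
deviation of CoO from 90 measures departure from perpendicularity to the
layer.  CorrA is directional ([0, 360)); UncO and CoO are axial
([0, 180)).  Folding CoO into [0, 180) makes the correction independent
of which side of the centerline the neuron lies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import angle_of_vector, axial_deviation_from_90


@dataclass
class Centerline:
    """Ordered polyline tracing the middle of the pyramidal layer."""

    vertices: np.ndarray            # (N, 2) of (x, y) pixel coordinates
    partition_ref: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("centerline needs >= 2 (x, y) vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any((seg == 0).all(axis=1)):
            raise ValueError("consecutive centerline vertices must be distinct")

    @classmethod
    def from_csv(cls, path: str | Path, partition_ref: str = "") -> "Centerline":
        """Read ordered x,y vertices from a 2-column CSV (header optional)."""
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            df = pd.read_csv(path, header=None, names=["x", "y"])
        return cls(df[["x", "y"]].to_numpy(float), partition_ref=partition_ref)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


def _project_to_segments(p: np.ndarray, v: np.ndarray):
    """Feet of perpendiculars from p onto every segment of polyline v."""
    a, b = v[:-1], v[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    feet = a + t[:, None] * ab
    dists = np.linalg.norm(feet - p, axis=1)
    return feet, dists, t


def nearest_point_on_polyline(
    p, line: Centerline,
) -> tuple[np.ndarray, float]:
    """Closest point on the centerline to ``p`` and its Euclidean distance.

    Segment interiors are included; exact ties are broken toward the
    segment with the lowest index (deterministic).
    """
    p = np.asarray(p, dtype=float)
    feet, dists, _ = _project_to_segments(p, line.vertices)
    i = int(np.argmin(dists))       # argmin returns the first minimum
    return feet[i], float(dists[i])


def _nearest_with_tangent(p, line: Centerline):
    p = np.asarray(p, dtype=float)
    feet, dists, _ = _project_to_segments(p, line.vertices)
    i = int(np.argmin(dists))
    seg = line.vertices[i + 1] - line.vertices[i]
    tangent = angle_of_vector(seg[0], seg[1])
    return feet[i], float(dists[i]), float(tangent)


def correction_angle(centroid, q, line: Centerline | None = None) -> tuple[float, bool]:
    """Directional angle [0, 360) of the vector centroid -> nearest point.

    Returns ``(corra, flagged)``.  When the centroid lies exactly on the
    centerline (``centroid == q``) the direction is undefined; the local
    centerline normal is substituted and the record flagged — this
    requires ``line``.
    """
    centroid = np.asarray(centroid, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - centroid
    if np.allclose(d, 0.0):
        if line is None:
            raise ValueError("centroid lies on the centerline; pass `line` "
                             "to substitute the local normal")
        _, _, tangent = _nearest_with_tangent(centroid, line)
        return float((tangent + 90.0) % 360.0), True
    return float(angle_of_vector(d[0], d[1])), False


def corrected_orientation(unco, corra) -> np.ndarray | float:
    """CoO = (CorrA - UncO + 90) mod 180, the curvature-corrected orientation.

    90 deg means the neuron's major axis is perpendicular to the layer
    (parallel to the centroid-to-centerline direction).
    """
    coo = (np.asarray(corra, dtype=float) - np.asarray(unco, dtype=float) + 90.0) % 180.0
    return float(coo) if np.isscalar(unco) and np.isscalar(corra) else coo


def correct_records(
    records: pd.DataFrame,
    line: Centerline,
    unco_col: str = "unco_deg",
) -> pd.DataFrame:
    """Apply the curvature correction to a per-neuron table.

    ``records`` must carry centroid columns ``x``/``y`` and an axial
    orientation column.  Adds ``corra_deg``, ``coo_deg``, ``dev_deg``
    (axial deviation of CoO from 90) and ``on_centerline`` (True where the
    centroid fell exactly on the line and the local normal was
    substituted).  Rows with NaN orientation keep NaN through all derived
    columns.
    """
    out = records.copy()
    corra = np.empty(len(out))
    flagged = np.zeros(len(out), dtype=bool)
    for i, (x, y) in enumerate(zip(out["x"].to_numpy(), out["y"].to_numpy())):
        q, _ = nearest_point_on_polyline((x, y), line)
        corra[i], flagged[i] = correction_angle((x, y), q, line)
    out["corra_deg"] = corra
    out["on_centerline"] = flagged
    out["coo_deg"] = corrected_orientation(out[unco_col].to_numpy(), corra)
    out["dev_deg"] = axial_deviation_from_90(out["coo_deg"].to_numpy())
    return out
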