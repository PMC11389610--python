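"""Image preparation and partition extraction.

Digitized Nissl sections enter the pipeline as 8-bit grey or RGB images in
which somata are dark on a light background. :func:`prepare_image` converts
them to the normalized form every downstream step consumes: single-channel
8-bit, *inverted* (somata bright) and auto-contrast stretched.
:func:`extract_partition` crops one subregion partition out of a section
using a closed polygon ROI, keeping a labeled object iff its centroid lies
inside the polygon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

SUBREGIONS = frozenset({
    "CA1", "CA2", "CA3", "CA3prox", "CA3dist", "Sub",
    "CA1u", "CA2u", "CA3u", "Subu",
})

#: ITU-R BT.709 luminance weights for RGB-to-grey conversion.
DEFAULT_GREY_WEIGHTS = (0.2126, 0.7152, 0.0722)

#: Fraction of pixels saturated at each tail by the automatic contrast stretch.
DEFAULT_SATURATION = 0.0035


@dataclass
class SectionImage:
    """A prepared (8-bit, inverted, contrast-stretched) section image."""

    pixels: np.ndarray          # 2-D uint8
    pixel_size: float           # micrometres per pixel, > 0
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SectionImage.pixels must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class PartitionROI:
    """Closed polygon delimiting one subregion partition on one slide.

    ``slide_id`` indexes the anterior-posterior sampling level (1-5 in the
    standard protocol); ``subregion`` must come from the closed vocabulary
    of hippocampal subfield labels.
    """

    polygon: np.ndarray         # (N, 2) vertices, (x, y) pixel coordinates
    subregion: str
    case_id: str
    slide_id: str | int
    name: str = ""

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (N>=3, 2) vertex array")
        if self.subregion not in SUBREGIONS:
            raise ValueError(
                f"unknown subregion {self.subregion!r}; expected one of {sorted(SUBREGIONS)}")
        poly = self.shapely
        if not poly.is_simple or not poly.is_valid:
            raise ValueError("ROI polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("ROI polygon must have positive area")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


def _to_grey(raw: np.ndarray, weights=DEFAULT_GREY_WEIGHTS) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(raw)):
        raise ValueError("image contains non-finite values")
    if raw.ndim == 2:
        grey = raw.astype(float)
    elif raw.ndim == 3 and raw.shape[2] in (3, 4):
        grey = raw[..., :3].astype(float) @ np.asarray(weights, dtype=float)
    else:
        raise ValueError(f"unsupported image shape {raw.shape}")
    if grey.max() <= 1.0 and np.issubdtype(raw.dtype, np.floating):
        grey = grey * 255.0
    return np.clip(grey, 0, 255)


def prepare_image(
    raw: np.ndarray,
    pixel_size: float = 1.0,
    id: str = "",
    saturation: float = DEFAULT_SATURATION,
    grey_weights=DEFAULT_GREY_WEIGHTS,
) -> SectionImage:
    """Convert a raw section image to normalized 8-bit inverted grey values.

    The image is reduced to a single luminance channel, inverted so that
    dark Nissl-stained somata become bright, and linearly stretched so that
    the ``saturation`` / ``1 - saturation`` intensity percentiles map to
    0 / 255.  A constant image is returned inverted but unstretched (with a
    warning), since a stretch is undefined there.

    Parameters
    ----------
    raw
        2-D grey or 3-D RGB(A) array; uint8 or float.
    pixel_size
        Calibration in micrometres per pixel.
    saturation
        Fraction of pixels saturated at each tail of the contrast stretch.
    """
    grey = _to_grey(raw, grey_weights)
    inverted = 255.0 - grey
    lo, hi = np.percentile(inverted, [100.0 * saturation, 100.0 * (1.0 - saturation)])
    if hi <= lo:
        warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
        out = inverted
    else:
        out = (np.clip(inverted, lo, hi) - lo) / (hi - lo) * 255.0
    return SectionImage(np.rint(out).astype(np.uint8), pixel_size=pixel_size, id=id)


def load_rois(path: str | Path) -> list[PartitionROI]:
    """Read partition ROIs from a JSON file.

    The file holds a list of objects with fields ``subregion``, ``case_id``,
    ``slide_id`` and ``vertices`` (list of [x, y] pixel coordinates).
    """
    records = json.loads(Path(path).read_text())
    return [
        PartitionROI(
            polygon=np.asarray(r["vertices"], dtype=float),
            subregion=r["subregion"],
            case_id=str(r["case_id"]),
            slide_id=r["slide_id"],
            name=r.get("name", ""),
        )
        for r in records
    ]


def extract_partition(
    image: SectionImage,
    mask: np.ndarray,
    roi: PartitionROI,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Crop one partition from a section image and its label mask.

    Returns ``(image_crop, mask_crop, offset)`` where ``offset`` is the
    ``(x0, y0)`` pixel origin of the crop in the section frame.  A labeled
    object is retained iff its centroid falls inside the ROI polygon, which
    prevents objects straddling a partition boundary from being counted in
    two adjacent partitions.  An ROI containing no objects yields an empty
    (all-zero) mask crop.
    """
    pixels = image.pixels
    mask = np.asarray(mask)
    if mask.shape != pixels.shape:
        raise ValueError("image and mask dimensions differ")
    h, w = pixels.shape
    poly = roi.shapely
    x0f, y0f, x1f, y1f = poly.bounds
    if x1f < 0 or y1f < 0 or x0f > w - 1 or y0f > h - 1:
        raise ValueError("ROI lies fully outside the image")
    x0 = max(int(np.floor(x0f)), 0)
    y0 = max(int(np.floor(y0f)), 0)
    x1 = min(int(np.ceil(x1f)), w - 1)
    y1 = min(int(np.ceil(y1f)), h - 1)

    img_crop = pixels[y0:y1 + 1, x0:x1 + 1].copy()
    mask_crop = mask[y0:y1 + 1, x0:x1 + 1].copy()

    labels = np.unique(mask_crop)
    labels = labels[labels > 0]
    if labels.size:
        # keep an object iff its (full-mask) centroid is inside the polygon
        cents = ndimage.center_of_mass(mask > 0, mask, labels)  # (row, col)
        cy = np.array([c[0] for c in cents])
        cx = np.array([c[1] for c in cents])
        inside = shapely.contains_xy(poly, cx, cy)
        drop = set(labels[~inside].tolist())
        if drop:
            mask_crop[np.isin(mask_crop, list(drop))] = 0
    return img_crop, mask_crop, (x0, y0)
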