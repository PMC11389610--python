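"""End-to-end analysis: mask + image + centerline -> per-neuron records.

Chains the pipeline stages in their canonical order: preparation, object
measurement, false-positive filtering, moment ellipse fitting, and
curvature correction against the layer centerline.  The result is one
table with a row per segmented object carrying its measurements, filter
status, uncorrected (UncO) and corrected (CoO) orientation, and the axial
deviation from perpendicularity used by the group statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curvature import Centerline, correct_records
from .filtering import FilterConfig, FilterResult, apply_filters, grey_threshold, measure_segments
from .orientation import fit_ellipses
from .preprocess import PartitionROI, SectionImage, extract_partition, prepare_image
from .segmentation import LabelMask


def analyze_scene(
    image,
    mask: LabelMask | np.ndarray,
    centerline: Centerline,
    pixel_size: float | None = None,
    filter_config: FilterConfig | None = None,
    min_ratio: float = 1.05,
    prepared: bool = False,
    metadata: dict | None = None,
) -> tuple[pd.DataFrame, FilterResult]:
    """Run the full per-partition pipeline on one image/mask/centerline.

    Parameters
    ----------
    image
        Raw image array, or a prepared :class:`SectionImage` (set
        ``prepared=True`` or pass a SectionImage directly).
    mask
        Integer label mask aligned with the image.
    centerline
        Pyramidal-layer centerline in the same pixel frame.
    metadata
        Optional constant columns (e.g. subregion, case_id, slide_id)
        appended to every record.

    Returns
    -------
    (records, filter_result)
        ``records`` has one row per labeled object with measurement,
        filter, orientation and curvature-correction columns; ``coo_deg``
        and ``dev_deg`` are NaN for excluded or orientation-gated objects,
        which therefore drop out of collinearity statistics.
    """
    if isinstance(image, SectionImage):
        section = image
    elif prepared:
        section = SectionImage(np.asarray(image), pixel_size=pixel_size or 1.0)
    else:
        section = prepare_image(np.asarray(image), pixel_size=pixel_size or 1.0)
    px = pixel_size or section.pixel_size

    segments = measure_segments(mask, section, pixel_size=px)
    if not segments:
        empty = pd.DataFrame(columns=["label", "x", "y", "area_um2", "diameter_um",
                                      "mean_grey", "status", "reason", "major_um",
                                      "minor_um", "unco_deg", "ecc_ok", "corra_deg",
                                      "coo_deg", "dev_deg"])
        return empty, FilterResult(kept=[], excluded=[], thresholds_used={})

    config = filter_config or FilterConfig()
    threshold = None
    if config.grey_rule == "auto_midpoint":
        threshold = grey_threshold(segments, section, mask)
    fres = apply_filters(segments, config, threshold)

    records = fres.to_frame()
    fits = fit_ellipses(mask, pixel_size=px, min_ratio=min_ratio)
    records = records.merge(
        fits.drop(columns=["x", "y"]), on="label", how="left")

    # curvature-correct only kept, orientation-stable objects
    use = (records["status"] == "kept") & records["ecc_ok"].fillna(False)
    corrected = correct_records(records.loc[use], centerline)
    for col in ("corra_deg", "coo_deg", "dev_deg"):
        records[col] = np.nan
        records.loc[use, col] = corrected[col].to_numpy()
    records["on_centerline"] = False
    records.loc[use, "on_centerline"] = corrected["on_centerline"].to_numpy()

    for key, value in (metadata or {}).items():
        records[key] = value
    return records, fres


def analyze_partition(
    section: SectionImage,
    mask: LabelMask | np.ndarray,
    roi: PartitionROI,
    centerline: Centerline,
    filter_config: FilterConfig | None = None,
    min_ratio: float = 1.05,
) -> tuple[pd.DataFrame, FilterResult]:
    """Crop one partition ROI from a prepared section and analyze it.

    The centerline is given in section coordinates and is shifted into
    the crop frame; output centroids are mapped back to the section
    frame.  Partition metadata (subregion, case, slide) is attached to
    every record.
    """
    img_crop, mask_crop, (x0, y0) = extract_partition(section, np.asarray(
        mask.labels if isinstance(mask, LabelMask) else mask), roi)
    local_line = Centerline(centerline.vertices - np.array([x0, y0]),
                            partition_ref=centerline.partition_ref)
    records, fres = analyze_scene(
        SectionImage(img_crop, pixel_size=section.pixel_size, id=section.id),
        mask_crop, local_line, filter_config=filter_config, min_ratio=min_ratio,
        metadata={"subregion": roi.subregion, "case_id": roi.case_id,
                  "slide_id": roi.slide_id},
    )
    if len(records):
        records["x"] = records["x"] + x0
        records["y"] = records["y"] + y0
    return records, fres
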