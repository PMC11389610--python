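"""False-positive removal from neuron label masks.

Instance segmenters applied to Nissl sections produce four characteristic
classes of false positives: patches of extracellular space (lighter than
somata on the stained section), glial cells and partial neuron profiles
(both smaller than pyramidal somata), and merged/overlapping neurons
(larger than one soma).  This module measures every labeled object and
removes these classes with auditable per-object reason codes:

1. ``extracellular`` — mean grey value below the midpoint of the average
   segmented-pixel and average background-pixel grey values (computed on
   the prepared, inverted image, where neurons are bright);
2. ``too_small`` — equivalent diameter below ``mean - 0.75 SD`` of the
   partition's surviving objects;
3. ``too_large_diameter`` — equivalent diameter above ``mean + 1.75 SD``;
4. ``too_large_area`` — area above ``mean + 1.75 SD`` of areas.

Size statistics use the survivors of rule 1 within the partition, since
extracellular speckle would otherwise corrupt the mean and SD.  Objects
landing exactly on a threshold are kept.  Each excluded object carries the
first rule that triggered, in the order above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

from .preprocess import SectionImage
from .segmentation import LabelMask

REASONS = ("extracellular", "too_small", "too_large_diameter", "too_large_area")


@dataclass
class NeuronSegment:
    """Measurements of one labeled object."""

    label: int
    pixel_count: int
    area: float                 # µm²
    equiv_diameter: float       # µm, diameter of the circle of equal area
    centroid: tuple[float, float]   # (x, y) pixel coordinates
    mean_grey: float            # on the prepared (inverted) image, 0-255


@dataclass
class FilterConfig:
    """SD multipliers and grey-rule mode for false-positive filtering."""

    lower_diam_sd: float = 0.75
    upper_diam_sd: float = 1.75
    upper_area_sd: float = 1.75
    grey_rule: str = "auto_midpoint"    # "auto_midpoint" | "fixed" | "off"
    grey_value: float | None = None     # used when grey_rule == "fixed"

    def __post_init__(self) -> None:
        if min(self.lower_diam_sd, self.upper_diam_sd, self.upper_area_sd) < 0:
            raise ValueError("SD multipliers must be >= 0")
        if self.grey_rule not in ("auto_midpoint", "fixed", "off"):
            raise ValueError(f"unknown grey_rule {self.grey_rule!r}")
        if self.grey_rule == "fixed" and self.grey_value is None:
            raise ValueError("grey_rule='fixed' requires grey_value")


@dataclass
class FilterResult:
    kept: list[NeuronSegment]
    excluded: list[tuple[NeuronSegment, str]]
    thresholds_used: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = [
            dict(label=s.label, x=s.centroid[0], y=s.centroid[1],
                 area_um2=s.area, diameter_um=s.equiv_diameter,
                 mean_grey=s.mean_grey, status="kept", reason="")
            for s in self.kept
        ] + [
            dict(label=s.label, x=s.centroid[0], y=s.centroid[1],
                 area_um2=s.area, diameter_um=s.equiv_diameter,
                 mean_grey=s.mean_grey, status="excluded", reason=r)
            for s, r in self.excluded
        ]
        return pd.DataFrame(rows).sort_values("label", ignore_index=True)


def _as_arrays(mask, image):
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    return labels, pixels


def measure_segments(
    mask: LabelMask | np.ndarray,
    image: SectionImage | np.ndarray,
    pixel_size: float | None = None,
) -> list[NeuronSegment]:
    """Measure pixel count, area, equivalent diameter, centroid and mean grey.

    ``pixel_size`` defaults to the image's calibration when a
    :class:`~neurocollin.preprocess.SectionImage` is given.
    """
    labels, pixels = _as_arrays(mask, image)
    if labels.shape != pixels.shape:
        raise ValueError("mask and image dimensions differ")
    if pixel_size is None:
        pixel_size = image.pixel_size if isinstance(image, SectionImage) else 1.0
    out = []
    for rp in regionprops(labels, intensity_image=pixels):
        area = rp.num_pixels * pixel_size ** 2
        out.append(NeuronSegment(
            label=int(rp.label),
            pixel_count=int(rp.num_pixels),
            area=float(area),
            equiv_diameter=float(2.0 * np.sqrt(area / np.pi)),
            centroid=(float(rp.centroid[1]), float(rp.centroid[0])),
            mean_grey=float(rp.intensity_mean),
        ))
    return out


def grey_threshold(
    segments: list[NeuronSegment],
    image: SectionImage | np.ndarray,
    mask: LabelMask | np.ndarray,
) -> float:
    """Midpoint of mean segmented-pixel and mean background-pixel grey values.

    Computed on the prepared (inverted) image, where neurons are bright and
    extracellular space is dark; objects whose mean grey falls strictly
    below the returned threshold are later flagged ``extracellular``.
    """
    if not segments:
        raise ValueError("need at least one segment")
    labels, pixels = _as_arrays(mask, image)
    fg = labels > 0
    if not fg.any():
        raise ValueError("mask holds no segmented pixels")
    if fg.all():
        raise ValueError("no background pixels in partition (mask fully covered)")
    return float((pixels[fg].mean() + pixels[~fg].mean()) / 2.0)


def apply_filters(
    segments: list[NeuronSegment],
    config: FilterConfig | None = None,
    threshold: float | None = None,
) -> FilterResult:
    """Partition segments into kept neurons and excluded false positives.

    ``threshold`` is the extracellular grey cutoff from
    :func:`grey_threshold`; it is required when ``config.grey_rule`` is
    ``auto_midpoint`` and ignored when the rule is ``fixed`` or ``off``.
    Size statistics (sample SD, ddof=1) are computed per partition over the
    survivors of the grey rule; if fewer than two objects survive, the size
    rules are skipped with a warning.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    config = config or FilterConfig()

    if config.grey_rule == "off":
        cutoff = None
    elif config.grey_rule == "fixed":
        cutoff = float(config.grey_value)
    else:
        if threshold is None:
            raise ValueError("grey_rule='auto_midpoint' requires a threshold "
                             "(see grey_threshold)")
        cutoff = float(threshold)

    reasons: dict[int, str] = {}
    survivors = []
    for s in segments:
        if cutoff is not None and s.mean_grey < cutoff:
            reasons[s.label] = "extracellular"
        else:
            survivors.append(s)

    thresholds = {"grey": cutoff}
    if len(survivors) < 2:
        if survivors:
            warnings.warn("fewer than 2 objects survive the grey rule; "
                          "size statistics undefined, size rules skipped",
                          stacklevel=2)
        thresholds.update(diam_lo=None, diam_hi=None, area_hi=None)
    else:
        diams = np.array([s.equiv_diameter for s in survivors])
        areas = np.array([s.area for s in survivors])
        d_mean, d_sd = diams.mean(), diams.std(ddof=1)
        a_mean, a_sd = areas.mean(), areas.std(ddof=1)
        diam_lo = d_mean - config.lower_diam_sd * d_sd
        diam_hi = d_mean + config.upper_diam_sd * d_sd
        area_hi = a_mean + config.upper_area_sd * a_sd
        thresholds.update(diam_lo=float(diam_lo), diam_hi=float(diam_hi),
                          area_hi=float(area_hi),
                          diam_mean=float(d_mean), diam_sd=float(d_sd),
                          area_mean=float(a_mean), area_sd=float(a_sd))
        for s in survivors:
            if s.equiv_diameter < diam_lo:
                reasons[s.label] = "too_small"
            elif s.equiv_diameter > diam_hi:
                reasons[s.label] = "too_large_diameter"
            elif s.area > area_hi:
                reasons[s.label] = "too_large_area"

    kept = [s for s in segments if s.label not in reasons]
    excluded = [(s, reasons[s.label]) for s in segments if s.label in reasons]
    return FilterResult(kept=kept, excluded=excluded, thresholds_used=thresholds)
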