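"""Collinearity measures and orientation-field summaries.

Two scalar measures summarize how collinear a population of corrected
orientations (CoOs) is:

* ``dev`` — mean angular deviation: the mean axial distance of the CoOs
  from the 90 deg perpendicularity reference, in [0, 90] deg.  0 means
  every neuron is exactly perpendicular to the layer.
* ``var`` — circular variance: ``1 - R̄`` where ``R̄`` is the mean
  resultant length of the angle-doubled CoOs (axial data have period 180,
  so angles are doubled before vector averaging).  0 = perfectly aligned,
  1 = axially uniform.

Rose-histogram binning and grid-sampled orientation-line segments support
the standard graphical displays of the orientation field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import axial_deviation_from_90, fold_axial


def mean_angular_deviation(coos) -> float:
    """Mean axial deviation of corrected orientations from 90 deg."""
    coos = np.asarray(coos, dtype=float)
    if coos.size == 0:
        raise ValueError("empty angle set")
    return float(axial_deviation_from_90(coos).mean())


def circular_variance(coos, axial: bool = True) -> float:
    """Circular variance 1 - R̄ of an angle sample, in [0, 1].

    With ``axial=True`` (default) angles are doubled before computing the
    mean resultant length, the standard treatment for orientation
    (period-180) data.  ``axial=False`` treats the inputs as directional
    (period-360) angles for strict replication of tools that skip the
    doubling.
    """
    coos = np.radians(np.asarray(coos, dtype=float))
    if coos.size == 0:
        raise ValueError("empty angle set")
    theta = 2.0 * coos if axial else coos
    rbar = float(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()))
    # rbar can exceed 1 by one ulp for identical angles; keep var in [0, 1]
    return float(min(max(1.0 - rbar, 0.0), 1.0))


def rose_histogram(coos, bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Counts of axial angles over half-open bins covering [0, 180).

    Returns ``(counts, edges)``; ``180 / bin_width`` must be an integer.
    The input may be empty (all-zero counts).
    """
    nbins = 180.0 / bin_width
    if bin_width <= 0 or abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide 180")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    coos = fold_axial(np.asarray(coos, dtype=float).ravel())
    counts, _ = np.histogram(coos, bins=edges)
    return counts, edges


def orientation_line_plot_data(
    records: pd.DataFrame,
    grid_size_um: float = 220.0,
    pixel_size: float = 1.0,
    angle_col: str = "coo_deg",
    segment_length_um: float = 110.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sample one neuron per occupied grid square and emit display segments.

    The section is tiled with squares of ``grid_size_um``; from every
    square containing at least one neuron, one is drawn uniformly at
    random (seeded via ``rng``) and a line segment of fixed display length
    is centered on its centroid along the requested angle column.

    Returns a frame with columns label, x, y, angle_deg, x0, y0, x1, y1
    (pixel coordinates).
    """
    rng = np.random.default_rng(rng)
    df = records.dropna(subset=[angle_col])
    if df.empty:
        return pd.DataFrame(columns=["label", "x", "y", "angle_deg",
                                     "x0", "y0", "x1", "y1"])
    g = grid_size_um / pixel_size
    cells = (np.floor(df["x"].to_numpy() / g).astype(int),
             np.floor(df["y"].to_numpy() / g).astype(int))
    keys = pd.DataFrame({"cx": cells[0], "cy": cells[1]}, index=df.index)
    picks = []
    for _, idx in keys.groupby(["cx", "cy"]).groups.items():
        picks.append(rng.choice(np.asarray(idx)))
    sampled = df.loc[sorted(picks)]
    half = segment_length_um / pixel_size / 2.0
    ang = np.radians(sampled[angle_col].to_numpy())
    dx, dy = np.cos(ang) * half, -np.sin(ang) * half   # y-up convention
    return pd.DataFrame({
        "label": sampled["label"].to_numpy(),
        "x": sampled["x"].to_numpy(), "y": sampled["y"].to_numpy(),
        "angle_deg": sampled[angle_col].to_numpy(),
        "x0": sampled["x"].to_numpy() - dx, "y0": sampled["y"].to_numpy() - dy,
        "x1": sampled["x"].to_numpy() + dx, "y1": sampled["y"].to_numpy() + dy,
    })


def summarize(
    records: pd.DataFrame,
    by=("subregion",),
    coo_col: str = "coo_deg",
    axial: bool = True,
) -> pd.DataFrame:
    """Per-group n, dev and var of corrected orientations.

    Rows with NaN orientation (undefined or gated-out fits) are dropped
    before aggregation.
    """
    df = records.dropna(subset=[coo_col])
    rows = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        coos = grp[coo_col].to_numpy()
        rows.append({**dict(zip(by, key)),
                     "n": len(coos),
                     "dev": mean_angular_deviation(coos),
                     "var": circular_variance(coos, axial=axial)})
    return pd.DataFrame(rows)


def pool_subregions(
    partition_summaries: pd.DataFrame,
    weighting: str = "neurons",
) -> pd.DataFrame:
    """Pool per-partition summaries to the subregion level.

    ``weighting='neurons'`` weights each partition's dev/var by its neuron
    count (equivalent to pooling all neurons); ``'partitions'`` averages
    partitions with equal weight.  Both reductions are legitimate; results
    are labeled with the mode used.
    """
    if weighting not in ("neurons", "partitions"):
        raise ValueError("weighting must be 'neurons' or 'partitions'")
    rows = []
    for sub, grp in partition_summaries.groupby("subregion"):
        w = grp["n"].to_numpy(float) if weighting == "neurons" else np.ones(len(grp))
        w = w / w.sum()
        rows.append(dict(subregion=sub, n=int(grp["n"].sum()),
                         dev=float((grp["dev"] * w).sum()),
                         var=float((grp["var"] * w).sum()),
                         weighting=weighting))
    return pd.DataFrame(rows)
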