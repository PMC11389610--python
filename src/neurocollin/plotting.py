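"""Rose histograms and orientation-line plots."""

from __future__ import annotations

import numpy as np

from .collinearity import rose_histogram


def rose_plot(coos, bin_width: float = 10.0, ax=None, mirror: bool = True,
              color="tab:blue"):
    """Polar rose histogram of axial angles over [0, 180).

    With ``mirror=True`` each bin is drawn twice (at theta and
    theta + 180), the usual display for axial data.
    """
    import matplotlib.pyplot as plt

    counts, edges = rose_histogram(coos, bin_width)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians((edges[:-1] + edges[1:]) / 2.0)
    width = np.radians(bin_width)
    ax.bar(centers, counts, width=width, color=color, edgecolor="k",
           linewidth=0.3, alpha=0.85)
    if mirror:
        ax.bar(centers + np.pi, counts, width=width, color=color,
               edgecolor="k", linewidth=0.3, alpha=0.85)
    ax.set_theta_zero_location("E")
    return ax


def orientation_line_plot(segments, ax=None, image=None, color="tab:orange",
                          linewidth=1.2):
    """Draw grid-sampled orientation line segments, optionally over an image.

    ``segments`` is the frame returned by
    :func:`neurocollin.collinearity.orientation_line_plot_data`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if image is not None:
        ax.imshow(image, cmap="gray")
    for _, row in segments.iterrows():
        ax.plot([row.x0, row.x1], [row.y0, row.y1], color=color,
                linewidth=linewidth)
    ax.set_aspect("equal")
    if image is None:
        ax.invert_yaxis()       # pixel rows increase downward
    return ax
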