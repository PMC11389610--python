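"""Summarize an orientation field: rose histogram and orientation lines.

The rose histogram shows the frequency distribution of corrected
orientations over [0, 180); the orientation-line plot samples one neuron
per 220 x 220 um grid square and draws a short segment along its
corrected orientation, the standard visual check of an orientation
field. Figures are written next to this script.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from neurocollin import (
    ArcCurve,
    SceneSpec,
    analyze_scene,
    generate_scene,
    orientation_line_plot_data,
    rose_histogram,
)
from neurocollin.plotting import orientation_line_plot, rose_plot

scene = generate_scene(SceneSpec(
    curve=ArcCurve((0.0, 0.0), 500.0, (10.0, 170.0)),
    n_neurons=150, kappa=4.0, seed=11))
records, _ = analyze_scene(scene.image, scene.mask, scene.centerline)

counts, edges = rose_histogram(records["coo_deg"].dropna(), bin_width=10)
print("rose bins [lo, hi): counts")
for lo, hi, c in zip(edges[:-1], edges[1:], counts):
    print(f"  [{lo:5.1f}, {hi:5.1f}): {'#' * int(c)} {c}")
# Counts concentrate around the [80,100) bins: most somata are near-
# perpendicular to the layer.

segments = orientation_line_plot_data(records, grid_size_um=220.0, rng=0)
print(f"\n{len(segments)} occupied grid squares -> {len(segments)} line segments")

out = Path(__file__).parent
fig, (ax1, ax2) = plt.subplots(
    1, 2, figsize=(10, 4),
    subplot_kw=None, gridspec_kw={"width_ratios": [1, 1.6]})
ax1.remove()
ax1 = fig.add_subplot(1, 2, 1, projection="polar")
rose_plot(records["coo_deg"].dropna(), ax=ax1)
orientation_line_plot(segments, ax=ax2, image=scene.image)
fig.savefig(out / "04_orientation_field.png", dpi=120)
print(f"wrote {out / '04_orientation_field.png'}")
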