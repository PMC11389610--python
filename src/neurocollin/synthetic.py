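"""Ground-truthed synthetic scenes and statistical datasets.

Real validation data for this pipeline are curved laminae of elongated
Nissl-stained somata oriented near-perpendicular to the lamina, plus the
contaminants an instance segmenter picks up: small glia-like discs, merged
doublets and faint extracellular speckle.  This module renders such scenes
with exact bookkeeping — every object's class, true centroid, true axial
orientation and area are recorded — so that each pipeline stage can be
tested against known truth without tissue data.

Scenes are rendered as raw Nissl-like images (dark objects, light
background) together with an exact label mask (hard edges, no
antialiasing), the generating-curve centerline, and a truth table.  A
seed fixes the full scene deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .angles import fold_axial
from .curvature import Centerline
from .segmentation import LabelMask


# ---------------------------------------------------------------------------
# layer curves

class _Curve:
    def point(self, t: float) -> np.ndarray:        # (x, y) pixel coords
        raise NotImplementedError

    def normal_angle(self, t: float) -> float:      # directional, degrees
        raise NotImplementedError

    def polyline(self, n: int = 200) -> np.ndarray:
        return np.array([self.point(t) for t in np.linspace(0.0, 1.0, n)])


@dataclass
class ArcCurve(_Curve):
    """Circular arc: a curved lamina of constant curvature."""

    center: tuple[float, float]
    radius: float
    span_deg: tuple[float, float] = (20.0, 160.0)

    def _phi(self, t):
        a, b = self.span_deg
        return np.radians(a + t * (b - a))

    def point(self, t):
        phi = self._phi(t)
        cx, cy = self.center
        return np.array([cx + self.radius * np.cos(phi),
                         cy - self.radius * np.sin(phi)])

    def normal_angle(self, t):
        return float(np.degrees(self._phi(t)) % 360.0)   # outward radial


@dataclass
class LineCurve(_Curve):
    """Straight lamina between two endpoints."""

    start: tuple[float, float]
    end: tuple[float, float]

    def point(self, t):
        s, e = np.asarray(self.start, float), np.asarray(self.end, float)
        return s + t * (e - s)

    def normal_angle(self, t):
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        tangent = np.degrees(np.arctan2(-dy, dx))
        return float((tangent + 90.0) % 360.0)


@dataclass
class SineCurve(_Curve):
    """Sinusoidal lamina: curvature that changes sign along the layer."""

    start: tuple[float, float]
    length: float
    amplitude: float
    period: float

    def point(self, t):
        x = self.start[0] + t * self.length
        row = self.start[1] - self.amplitude * np.sin(2 * np.pi * t * self.length / self.period)
        return np.array([x, row])

    def normal_angle(self, t):
        slope = self.amplitude * 2 * np.pi / self.period * np.cos(
            2 * np.pi * t * self.length / self.period)   # d(y_up)/dx
        tangent = np.degrees(np.arctan2(slope, 1.0))
        return float((tangent + 90.0) % 360.0)


# ---------------------------------------------------------------------------
# scene specification

@dataclass
class SceneSpec:
    """Parameters of one synthetic curved-lamina scene.

    Defaults emulate a typical human-hippocampus partition at 1 µm/px:
    somata ~30 µm long with 2:1 axis ratio in a 60 µm-wide layer,
    orientation noise of axial von Mises concentration ``kappa = 8``
    around the local layer normal (``kappa=None`` disables noise), dark
    somata (~40) on a light background (~220) as in an inverted-before-
    preparation Nissl photograph.
    """

    curve: _Curve
    n_neurons: int = 120
    layer_width_um: float = 80.0
    shape: Literal["ellipse", "triangle"] = "ellipse"
    axis_ratio: float = 2.0
    length_um: float = 30.0
    length_jitter: float = 0.10
    kappa: float | None = 8.0
    n_glia: int = 0
    glia_diameter_um: float = 8.0
    n_doublets: int = 0
    n_speckle: int = 0
    speckle_intensity: float = 200.0
    speckle_diameter_um: float = 18.0
    neuron_grey: float = 40.0
    background_grey: float = 220.0
    noise_sd: float = 2.0
    pixel_size: float = 1.0
    margin_px: int = 40
    min_gap_px: int = 1
    seed: int = 0


@dataclass
class Scene:
    image: np.ndarray           # raw uint8, dark objects on light background
    mask: LabelMask
    centerline: Centerline
    truth: pd.DataFrame         # label, cls, x, y, angle_true_deg, area_px, t
    spec: SceneSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# rasterization (hard masks, no antialiasing)

def _ellipse_pixels(cx, cy, length, width, theta_deg, shape_hw):
    """Pixel (rows, cols) of a filled rotated ellipse; y-up angle convention."""
    h, w = shape_hw
    r_out = length / 2.0 + 1.5
    r0, r1 = int(np.floor(cy - r_out)), int(np.ceil(cy + r_out))
    c0, c1 = int(np.floor(cx - r_out)), int(np.ceil(cx + r_out))
    if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
        return None                                   # out of bounds
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    u = cc - cx
    v = -(rr - cy)                                    # y-up
    th = np.radians(theta_deg)
    a = u * np.cos(th) + v * np.sin(th)
    b = -u * np.sin(th) + v * np.cos(th)
    inside = (a / (length / 2.0)) ** 2 + (b / (width / 2.0)) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _triangle_pixels(cx, cy, length, base, theta_deg, shape_hw):
    """Filled isoceles triangle; axis = apex to base midpoint (axial truth)."""
    h, w = shape_hw
    th = np.radians(theta_deg)
    d = np.array([np.cos(th), -np.sin(th)])           # pixel coords, y-up flip
    p = np.array([d[1], -d[0]])                       # perpendicular
    apex = np.array([cx, cy]) + d * length / 2.0
    b1 = np.array([cx, cy]) - d * length / 2.0 + p * base / 2.0
    b2 = np.array([cx, cy]) - d * length / 2.0 - p * base / 2.0
    verts = np.array([apex, b1, b2])
    if verts.min() < 1 or verts[:, 0].max() >= w - 1 or verts[:, 1].max() >= h - 1:
        return None
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=shape_hw)
    if len(rr) == 0:
        return None
    return rr, cc


def _too_close(labels, rr, cc, gap):
    """True if the footprint overlaps or comes within ``gap`` px of a label."""
    h, w = labels.shape
    for dr in range(-gap, gap + 1):
        for dc in range(-gap, gap + 1):
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            if labels[r, c].any():
                return True
    return False


def _axial_noise(rng, kappa):
    """One axial von Mises deviation from 0, in (-90, 90] degrees."""
    if kappa is None or np.isinf(kappa):
        return 0.0
    if kappa == 0:
        a = rng.uniform(0.0, 180.0)
    else:
        a = np.degrees(rng.vonmises(0.0, kappa)) / 2.0 % 180.0
    return a - 180.0 if a > 90.0 else a


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a curved-lamina scene with exact per-object ground truth.

    Neurons are placed at uniform random arc positions within
    ``layer_width_um`` of the curve, oriented along the local curve normal
    plus axial von Mises noise of concentration ``spec.kappa``.
    Contaminants are added per their class counts: glia (small dark
    discs), doublets (two merged somata under one label) and speckle
    (objects at near-background intensity).  Objects never overlap; if an
    object cannot be placed after bounded retries a ``RuntimeError``
    advises lowering the density.  The same spec (including seed) always
    yields bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size

    poly = spec.curve.polyline(200)
    pad = spec.margin_px + (spec.layer_width_um + spec.length_um) / px
    x0, y0 = poly.min(axis=0) - pad
    shift = np.array([np.floor(x0), np.floor(y0)])
    poly = poly - shift
    w = int(np.ceil(poly[:, 0].max() + pad)) + 1
    h = int(np.ceil(poly[:, 1].max() + pad)) + 1

    labels = np.zeros((h, w), dtype=np.int32)
    paint: list[tuple[np.ndarray, np.ndarray, float]] = []   # (rr, cc, grey)
    truth_rows = []
    next_label = 1
    max_tries = 400

    def place(cls: str, make_candidate, grey: float):
        """Draw fresh candidates until one fits without overlap."""
        nonlocal next_label
        for _ in range(max_tries):
            pix, angle_true, t_par = make_candidate()
            if pix is None:
                continue
            rr, cc = pix
            if len(rr) == 0 or _too_close(labels, rr, cc, spec.min_gap_px):
                continue
            labels[rr, cc] = next_label
            paint.append((rr, cc, grey))
            truth_rows.append(dict(
                label=next_label, cls=cls,
                x=float(cc.mean()), y=float(rr.mean()),
                angle_true_deg=angle_true, area_px=int(len(rr)), t=t_par))
            next_label += 1
            return
        raise RuntimeError(
            f"could not place {cls!r} object without overlap after "
            f"{max_tries} tries; lower the object density")

    def _layer_center(t):
        u = rng.uniform(-spec.layer_width_um / 2, spec.layer_width_um / 2) / px
        phi_n = spec.curve.normal_angle(t)
        nvec = np.array([np.cos(np.radians(phi_n)), -np.sin(np.radians(phi_n))])
        return spec.curve.point(t) - shift + u * nvec, phi_n

    length_px = spec.length_um / px
    width_px = length_px / spec.axis_ratio

    def neuron_candidate(slot=None):
        # stratified along the curve: somata pack the layer like a real
        # stratum pyramidale rather than landing uniformly at random
        if slot is None:
            t = rng.uniform()
        else:
            i, n = slot
            t = (i + rng.uniform()) / n
        center, phi_n = _layer_center(t)
        theta = float(fold_axial(phi_n + _axial_noise(rng, spec.kappa)))
        ln = length_px * (1.0 + spec.length_jitter * rng.uniform(-1, 1))
        wd = ln / spec.axis_ratio
        if spec.shape == "ellipse":
            pix = _ellipse_pixels(center[0], center[1], ln, wd, theta, (h, w))
        else:
            pix = _triangle_pixels(center[0], center[1], ln, wd * 1.4, theta, (h, w))
        return pix, theta, t

    def glia_candidate():
        t = rng.uniform()
        center, _ = _layer_center(t)
        g = spec.glia_diameter_um / px
        return _ellipse_pixels(center[0], center[1], g, g, 0.0, (h, w)), np.nan, t

    def doublet_candidate():
        t = rng.uniform()
        center, phi_n = _layer_center(t)
        theta = float(fold_axial(phi_n + _axial_noise(rng, spec.kappa)))
        off_dir = np.radians(theta + 90.0)
        off = np.array([np.cos(off_dir), -np.sin(off_dir)]) * width_px * 0.8
        p1 = _ellipse_pixels(center[0] - off[0] / 2, center[1] - off[1] / 2,
                             length_px, width_px, theta, (h, w))
        p2 = _ellipse_pixels(center[0] + off[0] / 2, center[1] + off[1] / 2,
                             length_px, width_px, theta, (h, w))
        if p1 is None or p2 is None:
            return None, np.nan, t
        flat = np.unique(np.concatenate([p1[0], p2[0]]).astype(np.int64) * w
                         + np.concatenate([p1[1], p2[1]]))
        return ((flat // w).astype(np.intp), (flat % w).astype(np.intp)), np.nan, t

    def speckle_candidate():
        t = rng.uniform()
        center, _ = _layer_center(t)
        s = spec.speckle_diameter_um / px
        pix = _ellipse_pixels(center[0], center[1], s, s * 0.8,
                              rng.uniform(0, 180), (h, w))
        return pix, np.nan, t

    for i in range(spec.n_neurons):
        place("neuron",
              lambda i=i: neuron_candidate(slot=(i, spec.n_neurons)),
              spec.neuron_grey)
    for _ in range(spec.n_glia):
        place("glia", glia_candidate, spec.neuron_grey)
    for _ in range(spec.n_doublets):
        place("doublet", doublet_candidate, spec.neuron_grey)
    for _ in range(spec.n_speckle):
        place("speckle", speckle_candidate, spec.speckle_intensity)

    image = spec.background_grey + rng.normal(0.0, spec.noise_sd, size=(h, w))
    for rr, cc, grey in paint:
        image[rr, cc] = grey + rng.normal(0.0, spec.noise_sd, size=len(rr))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(truth_rows, columns=["label", "cls", "x", "y",
                                              "angle_true_deg", "area_px", "t"])
    return Scene(
        image=image,
        mask=LabelMask(labels=labels, provenance=f"neurocollin synthetic seed={spec.seed}"),
        centerline=Centerline(poly, partition_ref="synthetic"),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# angle and multilevel-dataset samplers

def generate_angle_sample(n: int, mu_deg: float, kappa: float,
                          seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Axial von Mises sample: n angles in [0, 180) concentrated at ``mu_deg``.

    Directional angles are drawn at ``2·mu`` with concentration ``kappa``
    and halved back, the standard construction for axial data.
    ``kappa = 0`` gives the axially uniform distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    theta = rng.vonmises(np.radians(2.0 * mu_deg), kappa, size=n)
    return np.degrees(theta) / 2.0 % 180.0


def generate_multilevel_dataset(
    k_subregions: int = 8,
    n_cases: int = 5,
    n_slides: int = 5,
    effect_sizes=None,
    sigma_case: float = 3.0,
    sigma_slide: float = 3.0,
    sigma_resid: float = 10.0,
    n_per_cell: int = 2,
    baseline: float = 25.0,
    truncate: bool = True,
    value_col: str = "dev_deg",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Response values with a crossed multilevel structure.

    ``value = baseline + effect[subregion] + u_case + u_slide + eps``,
    truncated to the angular-deviation range [0, 90] unless
    ``truncate=False`` (use that to simulate directly on an unbounded,
    already-normalized scale); every subregion × case × slide cell holds
    ``n_per_cell`` observations (case and slide intercepts are crossed).
    Truth parameters are recorded in ``DataFrame.attrs['params']``.
    """
    if min(k_subregions, n_cases, n_slides, n_per_cell) < 1:
        raise ValueError("design dimensions must be >= 1")
    if min(sigma_case, sigma_slide, sigma_resid) < 0:
        raise ValueError("variance components must be >= 0")
    effects = np.zeros(k_subregions) if effect_sizes is None else np.asarray(effect_sizes, float)
    if len(effects) != k_subregions:
        raise ValueError("effect_sizes length must equal k_subregions")
    rng = np.random.default_rng(seed)
    u_case = rng.normal(0.0, sigma_case, n_cases)
    u_slide = rng.normal(0.0, sigma_slide, n_slides)
    rows = []
    for s in range(k_subregions):
        for c in range(n_cases):
            for l in range(n_slides):
                eps = rng.normal(0.0, sigma_resid, n_per_cell)
                dev = baseline + effects[s] + u_case[c] + u_slide[l] + eps
                if truncate:
                    dev = np.clip(dev, 0.0, 90.0)
                for d in dev:
                    rows.append({"subregion": f"sub{s + 1}",
                                 "case_id": f"case{c + 1}",
                                 "slide_id": f"slide{l + 1}",
                                 value_col: float(d)})
    df = pd.DataFrame(rows)
    df.attrs["params"] = dict(effects=effects.tolist(), sigma_case=sigma_case,
                              sigma_slide=sigma_slide, sigma_resid=sigma_resid,
                              baseline=baseline, n_per_cell=n_per_cell)
    return df


# ---------------------------------------------------------------------------
# rigid rotation of a scene (exact for vertices, nearest-neighbour for labels)

def rotate_label_scene(
    mask: LabelMask | np.ndarray,
    vertices: np.ndarray,
    phi_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly rotate a label mask and polyline by ``phi_deg`` (math CCW, y-up).

    The canvas expands to hold the rotated content; labels are resampled
    nearest-neighbour (identities preserved), vertices are mapped exactly
    with the same transform.  Used to test rotation invariance of the
    curvature correction.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    h, w = labels.shape
    phi = np.radians(phi_deg)
    # math CCW rotation by phi expressed in pixel (x right, y down) coords
    M = np.array([[np.cos(phi), np.sin(phi)],
                  [-np.sin(phi), np.cos(phi)]])
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    mapped = (corners - c) @ M.T + c
    shift = -np.floor(mapped.min(axis=0))
    if np.allclose(M, np.rint(M), atol=1e-12):
        # quarter-turn: snap the translation so the pixel lattice maps to
        # itself and the resampling is exact
        b = c - c @ M.T + shift
        shift = shift + (np.rint(b) - b)
    out_w = int(np.ceil((mapped[:, 0] + shift[0]).max())) + 1
    out_h = int(np.ceil((mapped[:, 1] + shift[1]).max())) + 1

    xx, yy = np.meshgrid(np.arange(out_w), np.arange(out_h))
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    src = (pts - c - shift) @ M + c               # inverse: M^T applied, (p')M == M.T p'
    sx = np.rint(src[:, 0]).astype(int)
    sy = np.rint(src[:, 1]).astype(int)
    valid = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    out = np.zeros(out_h * out_w, dtype=labels.dtype)
    out[valid] = labels[sy[valid], sx[valid]]
    out = out.reshape(out_h, out_w)

    verts = (np.asarray(vertices, float) - c) @ M.T + c + shift
    return out, verts
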