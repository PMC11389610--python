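"""Label-mask acquisition.

Downstream modules consume only :class:`LabelMask`; masks may come from a
precomputed file (:func:`load_label_mask`) or from an external pretrained
instance segmenter invoked as a subprocess (:func:`run_external_segmenter`).
The pipeline is fully exercisable without the external tool.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


class SegmenterNotAvailableError(RuntimeError):
    pass


@dataclass
class LabelMask:
    """Integer instance-label image: 0 = background, k = object k."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def relabel_consecutive(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel positive labels to 1..K in order of first appearance (row-major)."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    pos = uniq > 0
    order = np.argsort(first[pos])          # order of first appearance
    old = uniq[pos][order]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[old] = np.arange(1, len(old) + 1, dtype=np.int32)
    return lut[labels], len(old)


def load_label_mask(path: str | Path, relabel: bool = True) -> LabelMask:
    """Read a label mask from a TIFF file, validating and relabeling it.

    Labels are relabeled to consecutive integers 1..K preserving the order
    of first appearance, which gives stable join keys for per-neuron tables.
    A JSON sidecar ``<path>.json`` with a ``provenance`` field is honored if
    present.  Float-valued masks are rejected.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(
            f"{path} holds float pixels; label masks must be integer images "
            "(re-export the mask with an integer dtype, e.g. uint16/int32)")
    if relabel:
        arr, _ = relabel_consecutive(arr)
    provenance = ""
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", "")
    return LabelMask(labels=arr.astype(np.int32), provenance=provenance)


def save_label_mask(mask: LabelMask, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.int32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"provenance": mask.provenance}))


def run_external_segmenter(
    image,
    params: dict,
    executable: str = "cellpose",
) -> LabelMask:
    """Segment a prepared section image with an external pretrained tool.

    The tool (by default the ``cellpose`` command-line interface) is invoked
    as a subprocess on a temporary TIFF of the prepared image; ``params``
    must include at least ``diameter`` (expected object diameter in pixels)
    and is passed through opaquely as ``--key value`` flags.  The tool name,
    version and parameters are recorded in the returned mask's provenance.

    Raises
    ------
    SegmenterNotAvailableError
        If the executable is not on PATH.  Precomputed masks loaded with
        :func:`load_label_mask` are the supported alternative; every
        downstream step depends only on :class:`LabelMask`.
    """
    if "diameter" not in params:
        raise ValueError("params must include the expected object 'diameter'")
    exe = shutil.which(executable)
    if exe is None:
        raise SegmenterNotAvailableError(
            f"external segmenter {executable!r} not found on PATH; "
            "use load_label_mask() with a precomputed mask instead")
    version = subprocess.run([exe, "--version"], capture_output=True,
                             text=True, check=False).stdout.strip()
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        img_path = tmp / "input.tif"
        tifffile.imwrite(img_path, image.pixels)
        cmd = [exe, "--image_path", str(img_path), "--save_tif", "--no_npy"]
        for key, value in params.items():
            cmd += [f"--{key}", str(value)]
        subprocess.run(cmd, check=True, capture_output=True)
        out = tmp / "input_cp_masks.tif"
        if not out.exists():
            raise RuntimeError(f"{executable} produced no mask file at {out}")
        arr = tifffile.imread(out)
    arr, _ = relabel_consecutive(arr.astype(np.int64))
    prov = json.dumps({"tool": executable, "version": version, "params": params})
    return LabelMask(labels=arr.astype(np.int32), provenance=prov)
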