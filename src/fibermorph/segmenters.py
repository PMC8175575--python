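"""Segmentation front-ends: an intensity-based baseline and a pluggable
external-segmenter contract.

The baseline (threshold + seeded watershed) represents classic
membrane-intensity segmentation: it works well on uniformly stained
(snap-frozen) sections and degrades as staining heterogeneity grows —
which is precisely why shape-aware deep segmenters such as Cellpose are
preferred for fixed tissue. It is a documented stand-in for ImageJ-style
thresholding, not a reimplementation of any specific plugin.

External segmenters plug in through a shell-command template; the package
never bundles a neural network.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .label_core import Calibration, LabelImage, read_label_image

__all__ = ["SegmenterParams", "threshold_watershed_segment", "external_segmenter"]


@dataclass(frozen=True)
class SegmenterParams:
    """Baseline-segmenter knobs.

    ``diameter_px`` is the approximate mean fiber diameter — the same
    hint an external segmenter takes; here it sets the minimum separation
    of watershed seeds (diameter / 2).
    """

    method: str = "threshold_watershed"
    diameter_px: float = 40.0
    threshold_mode: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 0
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_mode='fixed'")
        if self.method not in ("threshold_watershed", "external"):
            raise ValueError(f"unknown method {self.method!r}")


def threshold_watershed_segment(
    membrane: np.ndarray,
    params: SegmenterParams,
    cal: Calibration | None = None,
) -> LabelImage:
    """Threshold the membrane channel and flood fiber interiors.

    The membrane is binarized (Otsu or fixed threshold), interiors are
    distance-transformed, watershed seeds are placed at regional maxima of
    the distance map at least ``diameter_px / 2`` apart, and basins are
    flooded out to the membrane. Objects smaller than ``min_area_px`` and
    (optionally) border-touching objects are dropped. Deterministic for a
    given input.
    """
    membrane = np.asarray(membrane, dtype=float)
    if membrane.ndim != 2:
        raise ValueError(f"expected a single 2-D channel, got shape {membrane.shape}")
    cal = cal or Calibration()
    import warnings as _warnings

    if params.threshold_mode == "fixed":
        thr = float(params.fixed_threshold)
    else:
        if np.ptp(membrane) == 0:
            _warnings.warn("flat image: no membrane detected, empty segmentation")
            return LabelImage(np.zeros(membrane.shape, dtype=np.uint16), cal)
        thr = float(threshold_otsu(membrane))
    interiors = membrane < thr
    if not interiors.any() or interiors.all():
        _warnings.warn("threshold left no segmentable interiors; empty segmentation")
        return LabelImage(np.zeros(membrane.shape, dtype=np.uint16), cal)

    edt = ndimage.distance_transform_edt(interiors)
    min_sep = max(1, int(round(params.diameter_px / 2)))
    # seed suppression is per interior component: two small adjacent
    # fibers must not silence each other's maxima
    comp, _ = ndimage.label(interiors)
    peaks = peak_local_max(edt, min_distance=min_sep, labels=comp, exclude_border=False)
    markers = np.zeros(membrane.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if not peaks.size:
        _warnings.warn("no watershed seeds found; empty segmentation")
        return LabelImage(np.zeros(membrane.shape, dtype=np.uint16), cal)
    labels = watershed(-edt, markers, mask=interiors)

    if params.min_area_px > 0:
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[(ids > 0) & (counts < params.min_area_px)]
        labels[np.isin(labels, small)] = 0
    if params.exclude_border:
        border_ids = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border_ids[border_ids > 0])] = 0
    # renumber consecutively
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.uint32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.uint32)
    out = remap[labels]
    dtype = np.uint16 if ids.size <= 65535 else np.uint32
    return LabelImage(out.astype(dtype), cal)


def external_segmenter(
    command_template: str,
    image_path: str | Path,
    diameter_px: float,
    output_path: str | Path | None = None,
    calibration: Calibration | None = None,
    timeout: float | None = None,
) -> LabelImage:
    """Run an external instance segmenter and load its label image.

    ``command_template`` must contain the placeholders ``{input}``,
    ``{output}`` and ``{diameter}``; e.g.::

        python -m cellpose --image {input} --diameter {diameter} --save {output}

    The template is validated before anything is executed; a nonzero exit
    status or missing output file raises with the program's diagnostics.
    """
    for ph in ("{input}", "{output}", "{diameter}"):
        if ph not in command_template:
            raise ValueError(f"command template missing placeholder {ph}")
    image_path = Path(image_path)
    if output_path is None:
        output_path = image_path.with_name(image_path.stem + "_labels.tif")
    output_path = Path(output_path)
    cmd = command_template.format(
        input=str(image_path), output=str(output_path), diameter=diameter_px
    )
    proc = subprocess.run(
        shlex.split(cmd), capture_output=True, text=True, timeout=timeout
    )
    if proc.returncode != 0:
        raise RuntimeError(
            f"external segmenter failed (exit {proc.returncode}): {cmd}\n"
            f"stdout: {proc.stdout.strip()}\nstderr: {proc.stderr.strip()}"
        )
    if not output_path.exists():
        raise RuntimeError(
            f"external segmenter produced no output at {output_path}\n"
            f"stdout: {proc.stdout.strip()}\nstderr: {proc.stderr.strip()}"
        )
    return read_label_image(output_path, calibration)
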