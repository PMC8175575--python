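"""Per-label morphological erosion by a fixed pixel radius.

Instance segmenters trained on membrane stains tend to place object
boundaries on the bright membrane itself, inflating each fiber's apparent
cross-sectional area. Shrinking every label by a few pixels before
measuring excludes the membrane from the measured area; the radius is a
user parameter chosen by visual inspection of the stain (4 px is a typical
value for Laminin at ~0.3 um/px).

Erosion is defined on the raster via the exact Euclidean distance
transform, per object independently: a pixel survives iff its distance to
the nearest non-object pixel (image border included) strictly exceeds the
radius. This is reproducible, testable against a brute-force disk oracle,
and guarantees that objects never gain pixels, never merge, and are nested
across increasing radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .label_core import LabelImage
from .roi_geometry import PolygonROI, labels_to_rois, rasterize_rois

__all__ = ["ErosionSpec", "erode_labels", "erode_rois", "split_disconnected_labels"]


@dataclass(frozen=True)
class ErosionSpec:
    """Erosion radius in pixels; vanished objects are dropped by default."""

    radius_px: int = 4
    drop_vanished: bool = True

    def __post_init__(self) -> None:
        if self.radius_px < 0:
            raise ValueError(f"radius_px must be >= 0, got {self.radius_px}")


def erode_labels(img: LabelImage, spec: ErosionSpec) -> tuple[LabelImage, pd.DataFrame]:
    """Erode every object by ``spec.radius_px`` via EDT thresholding.

    Returns the eroded label image and a report with one row per input
    object: ``original_id``, ``original_area_px``, ``status`` ("kept" or
    "vanished"). Objects eroded to nothing are removed from the image when
    ``drop_vanished`` (always listed in the report). Surviving objects keep
    their original IDs.
    """
    r = spec.radius_px
    pixels = img.pixels
    rows: list[dict] = []
    if r == 0 or not pixels.any():
        for oid, area in img.areas_px().items():
            rows.append({"original_id": oid, "original_area_px": area, "status": "kept"})
        return img, _report(rows)

    out = np.zeros_like(pixels)
    slices = ndimage.find_objects(pixels)
    for label_id in img.ids:
        label_id = int(label_id)
        sl = slices[label_id - 1] if label_id - 1 < len(slices) else None
        if sl is None:
            continue
        mask = pixels[sl] == label_id
        area = int(mask.sum())
        # pad with background so the image border erodes like any other edge
        padded = np.pad(mask, 1)
        edt = ndimage.distance_transform_edt(padded)
        kept = edt[1:-1, 1:-1] > r
        n_kept = int(kept.sum())
        if n_kept == 0:
            rows.append(
                {"original_id": label_id, "original_area_px": area, "status": "vanished"}
            )
            if not spec.drop_vanished:
                pass  # vanished means no pixels either way
            continue
        out[sl][kept] = label_id
        rows.append({"original_id": label_id, "original_area_px": area, "status": "kept"})
    return img.with_pixels(out), _report(rows)


def erode_rois(
    rois: list[PolygonROI],
    image_size: tuple[int, int],
    spec: ErosionSpec,
) -> tuple[list[PolygonROI], pd.DataFrame]:
    """Erode polygon ROIs: rasterize, erode the labels, re-trace.

    ROI names and label IDs are preserved for surviving objects.
    """
    labels = rasterize_rois(rois, image_size)
    eroded, report = erode_labels(labels, spec)
    names = {roi.label_id: roi.name for roi in rois}
    out = [
        PolygonROI(r.label_id, r.vertices, name=names.get(r.label_id, r.name))
        for r in labels_to_rois(eroded)
    ]
    return out, report


def split_disconnected_labels(img: LabelImage) -> LabelImage:
    """Give fresh IDs to extra components of any ID that erosion split at
    a thin neck.

    Unlike :func:`~fibermorph.label_core.relabel_connected` this keeps the
    original ID on each object's largest component, preserving
    traceability to the input labels; new IDs start above the current
    maximum.
    """
    from .label_core import FOUR_CONNECTED

    pixels = img.pixels
    out = None
    next_id = int(pixels.max(initial=0)) + 1
    for oid in img.ids:
        comp, n = ndimage.label(pixels == oid, structure=FOUR_CONNECTED)
        if n <= 1:
            continue
        if out is None:
            out = pixels.astype(np.int64)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for c in range(1, n + 1):
            if c == keep:
                continue
            out[comp == c] = next_id
            next_id += 1
    if out is None:
        return img
    dtype = np.uint16 if next_id <= 65535 else np.uint32
    return img.with_pixels(out.astype(dtype))


def _report(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["original_id", "original_area_px", "status"])
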