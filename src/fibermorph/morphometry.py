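"""Per-object morphometry: CSA, Feret diameter, channel intensities,
fiber typing, and color-coded CSA maps.

The central readout is the myofiber cross-sectional area (CSA) in um^2:
``csa_um2 = area_px * pixel_size_um**2`` exactly. Feret diameter comes
from the traced outer-boundary polygon; channel means are taken over the
object's (possibly eroded) pixel set, which is how fiber typing by
myosin-heavy-chain staining is done — erosion first, so the membrane
signal does not bleed into the per-fiber intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib
from matplotlib import colors as mpl_colors
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .label_core import IntensityStack, LabelImage
from .roi_geometry import feret_max, labels_to_rois

__all__ = [
    "ObjectMeasurement",
    "CsaSummary",
    "measure_objects",
    "csa_summary",
    "assign_fiber_types",
    "render_csa_map",
    "write_measurements_csv",
    "read_measurements_csv",
]

FIBER_TYPES = ("I", "IIa", "hybrid", "unclassified", "")


@dataclass(frozen=True)
class ObjectMeasurement:
    """One morphometry row: one object in one image."""

    image_id: str
    label_id: int
    area_px: int
    csa_um2: float
    feret_um: float
    centroid: tuple[float, float]  # (x, y) in px
    channel_means: dict[str, float] = field(default_factory=dict)
    fiber_type: str = ""

    def __post_init__(self) -> None:
        if self.fiber_type not in FIBER_TYPES:
            raise ValueError(f"unknown fiber type {self.fiber_type!r}")


@dataclass(frozen=True)
class CsaSummary:
    n_objects: int
    mean_csa_um2: float  # NaN when n_objects == 0
    histogram: tuple[tuple[float, float, float], ...]  # (low, high, count-or-fraction)
    bin_width_um2: float


def measure_objects(
    img: LabelImage,
    stack: IntensityStack | None = None,
    image_id: str = "",
) -> list[ObjectMeasurement]:
    """Measure every object: area, calibrated CSA, Feret, centroid, and —
    when an intensity stack is supplied — the mean of each channel over
    the object's pixels."""
    if stack is not None and stack.shape != img.shape:
        raise ValueError(f"dimension mismatch: labels {img.shape} vs stack {stack.shape}")
    ids = img.ids
    if ids.size == 0:
        return []
    pixels = img.pixels
    areas = ndimage.sum_labels(np.ones_like(pixels), pixels, index=ids)
    # centroid: center of mass of the mask; ndimage returns (row, col) = (y, x)
    centroids = ndimage.center_of_mass(np.ones_like(pixels), pixels, index=ids)
    means: dict[str, np.ndarray] = {}
    if stack is not None:
        for name in stack.channel_names:
            means[name] = ndimage.mean(stack[name].astype(float), pixels, index=ids)
    ferets = {roi.label_id: feret_max(roi, img.calibration) for roi in labels_to_rois(img)}
    f = img.calibration.area_factor
    out = []
    for i, oid in enumerate(ids):
        oid = int(oid)
        cy, cx = centroids[i]
        out.append(
            ObjectMeasurement(
                image_id=image_id,
                label_id=oid,
                area_px=int(areas[i]),
                csa_um2=float(areas[i]) * f,
                feret_um=ferets[oid],
                centroid=(float(cx), float(cy)),
                channel_means={n: float(v[i]) for n, v in means.items()},
            )
        )
    return out


def csa_summary(
    ms: list[ObjectMeasurement],
    bin_width_um2: float = 500.0,
    normalize: bool = False,
) -> CsaSummary:
    """Mean CSA and a half-open histogram ``[0, w), [w, 2w), ...``.

    With ``normalize`` the histogram holds per-image fractions instead of
    counts, the form needed when averaging distributions across animals.
    """
    if bin_width_um2 <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width_um2}")
    n = len(ms)
    if n == 0:
        return CsaSummary(0, float("nan"), (), bin_width_um2)
    areas = np.array([m.csa_um2 for m in ms], dtype=float)
    n_bins = int(np.floor(areas.max() / bin_width_um2)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um2
    counts, _ = np.histogram(areas, bins=edges)
    # np.histogram closes the last bin; areas.max() < edges[-1] by construction
    vals = counts / n if normalize else counts.astype(float)
    hist = tuple(
        (float(edges[i]), float(edges[i + 1]), float(vals[i])) for i in range(n_bins)
    )
    return CsaSummary(n, float(areas.mean()), hist, bin_width_um2)


def assign_fiber_types(
    ms: list[ObjectMeasurement],
    thresholds: dict[str, float] | None = None,
    *,
    type_i_channel: str = "typeI",
    type_iia_channel: str = "typeIIa",
) -> list[ObjectMeasurement]:
    """Classify fibers from myosin-heavy-chain channel means.

    "I" if only the type-I channel mean exceeds its threshold, "IIa" if
    only the type-IIa channel does, "hybrid" if both, "unclassified" if
    neither. Thresholds may be supplied per channel; otherwise each is
    derived by Otsu's method on the per-object mean distribution.
    """
    if not ms:
        return []
    for ch in (type_i_channel, type_iia_channel):
        missing = [m for m in ms if ch not in m.channel_means]
        if missing:
            raise ValueError(f"channel {ch!r} missing from measurements")
    if thresholds is None:
        thresholds = {}
    thr = dict(thresholds)
    for ch in (type_i_channel, type_iia_channel):
        if ch not in thr:
            vals = np.array([m.channel_means[ch] for m in ms], dtype=float)
            thr[ch] = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else float(vals[0])
    out = []
    for m in ms:
        is_i = m.channel_means[type_i_channel] > thr[type_i_channel]
        is_iia = m.channel_means[type_iia_channel] > thr[type_iia_channel]
        ftype = "hybrid" if (is_i and is_iia) else "I" if is_i else "IIa" if is_iia else "unclassified"
        out.append(replace(m, fiber_type=ftype))
    return out


def render_csa_map(
    img: LabelImage,
    ms: list[ObjectMeasurement],
    colormap: str = "viridis",
    mode: str = "linear",
) -> tuple[np.ndarray, list[tuple[float, float, str]]]:
    """Fill each object with the colormap color of its CSA; background black.

    ``mode`` is "linear" (min..max of CSA maps to 0..1) or "quantile"
    (empirical CDF position). Returns the RGB uint8 image (same
    dimensions as the input) and a legend of ``(value_low, value_high,
    hex_color)`` rows over 8 equal value bands.
    """
    if mode not in ("linear", "quantile"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = {m.label_id: m.csa_um2 for m in ms}
    missing = [int(i) for i in img.ids if int(i) not in by_id]
    if missing:
        raise ValueError(f"objects missing from measurements: {missing[:10]}")
    cmap = matplotlib.colormaps[colormap]
    rgb = np.zeros((*img.shape, 3), dtype=np.uint8)
    legend: list[tuple[float, float, str]] = []
    if not by_id:
        return rgb, legend
    vals = np.array(sorted(by_id.values()))
    lo, hi = float(vals[0]), float(vals[-1])

    def to_unit(v: float) -> float:
        if mode == "quantile":
            return float(np.searchsorted(vals, v, side="right")) / len(vals)
        return 0.0 if hi == lo else (v - lo) / (hi - lo)

    lut: dict[int, np.ndarray] = {}
    for oid, v in by_id.items():
        color = np.array(cmap(to_unit(v))[:3]) * 255
        lut[oid] = color.astype(np.uint8)
    for oid, color in lut.items():
        rgb[img.pixels == oid] = color
    n_bands = 8
    for k in range(n_bands):
        v0 = lo + (hi - lo) * k / n_bands
        v1 = lo + (hi - lo) * (k + 1) / n_bands
        c = cmap(to_unit((v0 + v1) / 2))
        legend.append((v0, v1, mpl_colors.to_hex(c)))
    return rgb, legend


_CSV_COLUMNS = ["image_id", "label_id", "area_px", "csa_um2", "feret_um", "centroid_x", "centroid_y", "fiber_type"]


def write_measurements_csv(ms: list[ObjectMeasurement], path: str | Path) -> Path:
    """One tidy row per (image_id, label_id); channel means become one
    column per channel (``mean_<channel>``)."""
    path = Path(path)
    channels: list[str] = []
    for m in ms:
        for c in m.channel_means:
            if c not in channels:
                channels.append(c)
    rows = []
    for m in ms:
        row = {
            "image_id": m.image_id,
            "label_id": m.label_id,
            "area_px": m.area_px,
            "csa_um2": m.csa_um2,
            "feret_um": m.feret_um,
            "centroid_x": m.centroid[0],
            "centroid_y": m.centroid[1],
            "fiber_type": m.fiber_type,
        }
        for c in channels:
            row[f"mean_{c}"] = m.channel_means.get(c, np.nan)
        rows.append(row)
    cols = _CSV_COLUMNS + [f"mean_{c}" for c in channels]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_measurements_csv(path: str | Path) -> list[ObjectMeasurement]:
    """Inverse of :func:`write_measurements_csv`."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    chan_cols = [c for c in df.columns if c.startswith("mean_")]
    for _, r in df.iterrows():
        ftype = r["fiber_type"]
        ftype = str(ftype) if isinstance(ftype, str) and ftype else ""
        out.append(
            ObjectMeasurement(
                image_id=str(r["image_id"]),
                label_id=int(r["label_id"]),
                area_px=int(r["area_px"]),
                csa_um2=float(r["csa_um2"]),
                feret_um=float(r["feret_um"]),
                centroid=(float(r["centroid_x"]), float(r["centroid_y"])),
                channel_means={c[5:]: float(r[c]) for c in chan_cols},
                fiber_type=ftype,
            )
        )
    return out
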