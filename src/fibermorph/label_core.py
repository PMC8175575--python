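"""Domain types and I/O for label images and intensity stacks.

A *label image* is the lingua franca of instance segmenters (Cellpose and
friends): a 2-D raster of non-negative integers where 0 is background and
each positive value identifies one object, here one myofiber cross-section.
Everything downstream (ROI conversion, erosion, morphometry, Dice
evaluation) consumes these types.

Coordinate convention: 0-based, x rightward, y downward; pixel (x, y)
covers the half-open unit square [x, x+1) x [y, y+1), so polygon areas on
pixel corners equal pixel counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from imageio.v3 import imread as _imread
from scipy import ndimage

__all__ = [
    "Calibration",
    "LabelImage",
    "IntensityStack",
    "read_label_image",
    "write_label_image",
    "read_intensity_stack",
    "relabel_connected",
]

_ALLOWED_LABEL_DTYPES = (np.uint8, np.uint16, np.uint32, np.int8, np.int16, np.int32, np.int64, np.uint64)

# 4-connectivity: fibers are separated by membrane, and a single shared
# diagonal corner must not merge two distinct fibers.
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel size in micrometers per pixel.

    With the default of 1.0, all calibrated measurements are effectively in
    pixel units.
    """

    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def area_factor(self) -> float:
        """Conversion factor from px^2 to um^2."""
        return self.pixel_size_um**2


@dataclass(frozen=True)
class LabelImage:
    """2-D grid of non-negative integer object IDs plus calibration.

    IDs need not be consecutive; all operations key on the actual ID set.
    """

    pixels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"label image must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"label image must be integer-valued, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ValueError("label image contains negative values")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of distinct positive object IDs."""
        u = np.unique(self.pixels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def areas_px(self) -> dict[int, int]:
        """Pixel count per object ID."""
        ids, counts = np.unique(self.pixels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}

    def mask(self, label_id: int) -> np.ndarray:
        return self.pixels == label_id

    def with_pixels(self, pixels: np.ndarray) -> "LabelImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class IntensityStack:
    """Ordered, named single- or multi-channel intensity image.

    All channels share dimensions; integer data are retained at their
    native scale (no rescaling to [0, 1]).
    """

    channels: dict[str, np.ndarray]
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("IntensityStack needs at least one channel")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if len(shp) != 2:
                raise ValueError(f"channel {name!r} must be 2-D, got shape {shp}")
            if shp != first:
                raise ValueError(f"channel dimension mismatch: {first} vs {name!r} with {shp}")
        object.__setattr__(
            self, "channels", {n: np.asarray(c) for n, c in self.channels.items()}
        )

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _read_plane(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return _imread(path)


def read_label_image(path: str | Path, calibration: Calibration | None = None) -> LabelImage:
    """Read a single-plane unsigned-integer label image (TIFF or PNG).

    Pixel values are preserved exactly; no relabeling is performed. RGB or
    floating-point data are rejected: a label image stores object IDs, not
    colors or intensities.
    """
    arr = _read_plane(path)
    if arr.ndim == 3:
        raise ValueError(
            f"unsupported label format: {path} has {arr.shape[-1] if arr.shape[-1] <= 4 else arr.shape[0]}"
            f" channels (shape {arr.shape}); label images must be single-plane"
        )
    if arr.ndim != 2:
        raise ValueError(f"unsupported label format: expected 2-D data, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"unsupported label format: dtype {arr.dtype} is not integer")
    if np.issubdtype(arr.dtype, np.signedinteger):
        if arr.size and arr.min() < 0:
            raise ValueError("unsupported label format: negative pixel values")
        arr = arr.astype(np.uint32 if arr.max(initial=0) > 65535 else np.uint16)
    return LabelImage(arr, calibration or Calibration())


def write_label_image(img: LabelImage, path: str | Path) -> Path:
    """Write a label image as 16-bit TIFF/PNG, promoting to 32-bit if needed.

    ``read_label_image(write_label_image(img))`` reproduces the pixel grid
    exactly.
    """
    path = Path(path)
    max_id = int(img.pixels.max(initial=0))
    dtype = np.uint16 if max_id <= 65535 else np.uint32
    arr = img.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        if dtype == np.uint32:
            raise ValueError(f"max ID {max_id} exceeds 16-bit PNG range; use TIFF")
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}; use .tif/.tiff/.png")
    return path


def read_intensity_stack(
    paths: str | Path | list[str | Path],
    channel_names: list[str] | None = None,
    calibration: Calibration | None = None,
) -> IntensityStack:
    """Read one or more single-channel planes, or one multipage TIFF.

    Channels are ordered as given; names default to ``ch0, ch1, ...``.
    """
    planes: list[np.ndarray] = []
    if isinstance(paths, (str, Path)):
        arr = _read_plane(paths)
        if arr.ndim == 2:
            planes = [arr]
        elif arr.ndim == 3:
            # multipage TIFF: planes along the smallest leading axis
            axis = int(np.argmin(arr.shape))
            planes = [np.take(arr, i, axis=axis) for i in range(arr.shape[axis])]
        else:
            raise ValueError(f"cannot interpret shape {arr.shape} as channel planes")
    else:
        planes = [_read_plane(p) for p in paths]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(len(planes))]
    if len(channel_names) != len(planes):
        raise ValueError(f"{len(channel_names)} channel names for {len(planes)} planes")
    if len(set(channel_names)) != len(channel_names):
        raise ValueError(f"duplicate channel names: {channel_names}")
    shapes = [p.shape for p in planes]
    if len(set(shapes)) > 1:
        raise ValueError(f"channel dimension mismatch: {shapes}")
    return IntensityStack(dict(zip(channel_names, planes)), calibration or Calibration())


def relabel_connected(img: LabelImage) -> LabelImage:
    """Split every label into its 4-connected components and renumber 1..N.

    An input ID spanning k disconnected regions yields k output IDs; the
    background mask and the foreground pixel partition are preserved. The
    operation is idempotent up to ID renumbering.
    """
    pixels = img.pixels
    if not pixels.any():
        return img
    out = np.zeros(pixels.shape, dtype=np.int64)
    next_id = 0
    for label_id in np.unique(pixels):
        if label_id == 0:
            continue
        comp, n = ndimage.label(pixels == label_id, structure=FOUR_CONNECTED)
        out[comp > 0] = comp[comp > 0] + next_id
        next_id += n
    dtype = np.uint16 if next_id <= 65535 else np.uint32
    return img.with_pixels(out.astype(dtype))
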