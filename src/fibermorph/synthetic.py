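"""Synthetic muscle cross-sections with ground-truth labels.

Real transverse muscle sections are space-filling mosaics of convex-ish
polygonal fibers whose areas are approximately lognormal, outlined by a
bright membrane stain (Laminin/WGA-like). The generator emulates exactly
that, in two staining regimes:

* ``"uniform"`` — the snap-frozen case: membrane intensity is constant,
  fiber interiors are dark; simple intensity thresholding works.
* ``"heterogeneous"`` — the PFA-fixed case: a smooth multiplicative field
  modulates membrane brightness across the section and fiber interiors
  carry an unspecific background haze; thresholding degrades while
  shape-aware segmenters keep working.

Fibers are laid out as a multiplicatively weighted Voronoi (Apollonius)
tessellation: seed points are placed by radius-aware dart throwing, pixels
are assigned to the seed minimizing distance/radius, seeds optionally move
to their cell centroids (centroidal relaxation), and the per-cell radii
are iteratively rebalanced so realized cell areas track the sampled
lognormal targets. Target cell areas are inflated by the expected
membrane loss so that the *ground-truth label* areas (cells minus
membrane, membrane pixels carry label 0) follow the requested area
distribution.

All randomness flows through the spec's single seed; output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import expand_labels

from .label_core import Calibration, IntensityStack, LabelImage

__all__ = [
    "SyntheticMuscleSpec",
    "sample_fiber_areas",
    "generate_muscle_section",
    "phenotype_preset",
    "random_label_image",
    "random_vessel_mask",
    "absorb_membrane",
    "write_section",
]

# hexagon-ish perimeter coefficient: P ~ _PERIM_COEF * sqrt(A)
_PERIM_COEF = 3.7


@dataclass(frozen=True)
class SyntheticMuscleSpec:
    """All parameters of one simulated section.

    ``area_lognormal`` is ``(mu_log, sigma_log)`` of the fiber areas in
    um^2 (so ``exp(mu_log)`` is the median CSA). ``width``/``height`` of
    None lets the generator size the frame to fit ``n_fibers`` fibers of
    the requested size distribution; fixing them instead rescales all
    fiber areas to fill the frame.
    """

    n_fibers: int = 200
    area_lognormal: tuple[float, float] = (7.2, 0.35)
    width: int | None = None
    height: int | None = None
    pixel_size_um: float = 1.0
    membrane_thickness_px: int = 3
    staining_regime: str = "uniform"
    heterogeneity_amplitude: float = 0.3
    heterogeneity_scale_px: float = 80.0
    interior_haze: float = 30.0
    noise_sigma: float = 0.0
    membrane_intensity: float = 200.0
    relaxation_iters: int = 2
    seed: int = 0
    area_mixture: tuple[float, float, float] | None = None  # (mu2, sigma2, weight2)

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be positive")
        if self.staining_regime not in ("uniform", "heterogeneous"):
            raise ValueError(f"unknown staining regime {self.staining_regime!r}")
        if not (0 <= self.heterogeneity_amplitude < 1):
            raise ValueError("heterogeneity_amplitude must be in [0, 1)")
        if self.membrane_thickness_px < 1:
            raise ValueError("membrane_thickness_px must be >= 1")
        if self.relaxation_iters < 0:
            raise ValueError("relaxation_iters must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um)


def sample_fiber_areas(
    n: int,
    area_lognormal: tuple[float, float],
    seed: int,
    mixture: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Draw n i.i.d. (optionally bimodal) lognormal fiber areas in um^2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sigma = area_lognormal
    if mixture is None:
        return rng.lognormal(mu, sigma, size=n)
    mu2, sigma2, w2 = mixture
    if not (0 <= w2 <= 1):
        raise ValueError("mixture weight must be in [0, 1]")
    pick = rng.random(n) < w2
    out = rng.lognormal(mu, sigma, size=n)
    out[pick] = rng.lognormal(mu2, sigma2, size=int(pick.sum()))
    return out


def _membrane_loss_per_side(thickness_px: int) -> int:
    """Pixel layers each cell loses to the membrane band on one side."""
    if thickness_px <= 1:
        return 1
    return 1 + max(0, (thickness_px - 2) // 2)


def _place_seeds(rng, radii: np.ndarray, w: int, h: int) -> np.ndarray:
    """Radius-aware dart throwing: big fibers claim big spacing."""
    n = len(radii)
    order = np.argsort(-radii)
    seeds = np.empty((n, 2))
    placed: list[int] = []
    # adjacent-hexagon center spacing ~ 1.07 * (sqrt(A_i)+sqrt(A_j))/2
    spacing = 0.95 * np.sqrt(np.pi) * radii  # ~ 1.68 * r = 0.95*sqrt(A)
    for idx in order:
        margin = min(0.8 * radii[idx], w / 4, h / 4)
        best, best_score = None, -np.inf
        for _ in range(40):
            cand = np.array(
                [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
            )
            if not placed:
                best = cand
                break
            pts = seeds[placed]
            req = 0.5 * (spacing[idx] + spacing[placed])
            score = float(np.min(np.linalg.norm(pts - cand, axis=1) / req))
            if score >= 1.0:
                best = cand
                break
            if score > best_score:
                best, best_score = cand, score
        seeds[idx] = best
        placed.append(int(idx))
    return seeds


def _assign(seeds: np.ndarray, radii: np.ndarray, w: int, h: int) -> np.ndarray:
    """Weighted-Voronoi pixel assignment via k-nearest candidate seeds.

    Returns a full partition with cell IDs 1..n (0 is reserved for the
    membrane later)."""
    n = len(seeds)
    k = min(n, 16)
    tree = cKDTree(seeds)
    owners = np.empty(h * w, dtype=np.int32)
    xs = (np.arange(w) + 0.5)[None, :].repeat(h, axis=0).ravel()
    ys = (np.arange(h) + 0.5)[:, None].repeat(w, axis=1).ravel()
    pts = np.column_stack([xs, ys])
    chunk = 400_000
    for lo in range(0, len(pts), chunk):
        sl = slice(lo, min(lo + chunk, len(pts)))
        dist, idx = tree.query(pts[sl], k=k)
        if k == 1:
            owners[sl] = np.ravel(idx)
            continue
        weighted = dist / radii[idx]
        owners[sl] = idx[np.arange(len(dist)), np.argmin(weighted, axis=1)]
    return owners.reshape(h, w) + 1


def _connect_cells(cells: np.ndarray) -> np.ndarray:
    """Make every cell (IDs 1..n) one 4-connected region: stray fragments
    are released and refilled from the nearest surviving cell."""
    four = ndimage.generate_binary_structure(2, 1)
    for _ in range(3):
        changed = False
        cells = cells.copy()
        for cid in np.unique(cells):
            if cid == 0:
                continue
            comp, ncomp = ndimage.label(cells == cid, structure=four)
            if ncomp <= 1:
                continue
            changed = True
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            cells[(comp > 0) & (comp != keep)] = 0
        if not changed:
            return cells
        cells = expand_labels(cells, distance=max(cells.shape))
    return cells


def _membrane_mask(cells: np.ndarray, thickness_px: int) -> np.ndarray:
    """Pixels within the membrane band centered on inter-cell cracks and
    the image border."""
    h, w = cells.shape
    diff = np.zeros((h, w), dtype=bool)
    diff[:, :-1] |= cells[:, :-1] != cells[:, 1:]
    diff[:, 1:] |= cells[:, :-1] != cells[:, 1:]
    diff[:-1, :] |= cells[:-1, :] != cells[1:, :]
    diff[1:, :] |= cells[:-1, :] != cells[1:, :]
    diff[0, :] = diff[-1, :] = diff[:, 0] = diff[:, -1] = True
    if thickness_px <= 2:
        if thickness_px == 1:
            # one-sided thin membrane: the higher-ID side of each crack
            thin = np.zeros_like(diff)
            thin[:, :-1] |= cells[:, :-1] < cells[:, 1:]
            thin[:, 1:] |= cells[:, 1:] < cells[:, :-1]
            thin[:-1, :] |= cells[:-1, :] < cells[1:, :]
            thin[1:, :] |= cells[1:, :] < cells[:-1, :]
            thin[0, :] = thin[-1, :] = thin[:, 0] = thin[:, -1] = True
            return thin
        return diff
    extra = (thickness_px - 2) / 2
    dist = ndimage.distance_transform_edt(~diff)
    return dist <= extra


def _heterogeneity_field(rng, shape, amplitude: float, scale_px: float) -> np.ndarray:
    if amplitude <= 0:
        return np.ones(shape)
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale_px)
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        return np.ones(shape)
    return 1 - amplitude + 2 * amplitude * (smooth - lo) / (hi - lo)


def generate_muscle_section(spec: SyntheticMuscleSpec) -> tuple[IntensityStack, LabelImage]:
    """Generate one section: a "membrane" intensity channel plus
    ground-truth labels (membrane pixels carry label 0, fibers 1..N)."""
    rng = np.random.default_rng(spec.seed)
    areas_um2 = sample_fiber_areas(
        spec.n_fibers, spec.area_lognormal, int(rng.integers(2**31)), spec.area_mixture
    )
    areas_px = areas_um2 / spec.calibration.area_factor

    mu, sigma = spec.area_lognormal
    mean_diam_px = np.sqrt(4 * np.exp(mu + sigma**2 / 2) / np.pi) / spec.pixel_size_um
    if mean_diam_px < 2 * spec.membrane_thickness_px:
        raise ValueError(
            f"infeasible density: mean fiber diameter {mean_diam_px:.1f} px < "
            f"2 x membrane thickness {spec.membrane_thickness_px} px"
        )

    # inflate target cell areas by the expected membrane loss so that the
    # post-membrane label areas follow the sampled distribution
    loss = _membrane_loss_per_side(spec.membrane_thickness_px)
    c = _PERIM_COEF * loss
    targets = ((c + np.sqrt(c * c + 4 * areas_px)) / 2) ** 2

    if spec.width is None or spec.height is None:
        side = int(np.ceil(np.sqrt(targets.sum())))
        w = spec.width or side
        h = spec.height or side
    else:
        w, h = spec.width, spec.height
    targets = targets * (w * h) / targets.sum()

    radii = np.sqrt(targets / np.pi)
    seeds = _place_seeds(rng, radii, w, h)

    n_iters = spec.relaxation_iters + 6
    cells = _assign(seeds, radii, w, h)
    ids = np.arange(1, spec.n_fibers + 1)
    for it in range(n_iters):
        counts = np.bincount(cells.ravel(), minlength=spec.n_fibers + 1)[1:].astype(float)
        ok = counts > 0
        if it < spec.relaxation_iters and ok.any():
            coms = np.asarray(
                ndimage.center_of_mass(np.ones_like(cells), cells, index=ids[ok])
            )  # rows are (y, x)
            seeds[ok, 0] = coms[:, 1]
            seeds[ok, 1] = coms[:, 0]
        # capacity rebalancing: grow under-filled cells, shrink over-filled
        ratio = np.where(ok, targets / np.maximum(counts, 1), 1.6)
        radii = radii * np.clip(ratio**0.35, 0.75, 1.3)
        cells = _assign(seeds, radii, w, h)
    cells = _connect_cells(cells)

    membrane = _membrane_mask(cells, spec.membrane_thickness_px)
    labels = cells.astype(np.int64)
    labels[membrane] = 0
    # membrane removal may disconnect a cell at a thin neck: keep the
    # largest component per label, then renumber 1..N
    four = ndimage.generate_binary_structure(2, 1)
    out = np.zeros_like(labels)
    next_id = 0
    for cid in np.unique(labels):
        if cid == 0:
            continue
        comp, ncomp = ndimage.label(labels == cid, structure=four)
        if ncomp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, ncomp + 1))
        keep = int(np.argmax(sizes)) + 1
        next_id += 1
        out[comp == keep] = next_id
    dtype = np.uint16 if next_id <= 65535 else np.uint32
    label_img = LabelImage(out.astype(dtype), spec.calibration)

    field = (
        _heterogeneity_field(
            rng, (h, w), spec.heterogeneity_amplitude, spec.heterogeneity_scale_px
        )
        if spec.staining_regime == "heterogeneous"
        else np.ones((h, w))
    )
    intensity = np.zeros((h, w))
    intensity[membrane] = (spec.membrane_intensity * field)[membrane]
    # the unspecific interior background of fixed tissue is independent of
    # local membrane immunoreactivity: where the field dips, membrane
    # brightness approaches the haze and local contrast collapses
    if spec.staining_regime == "heterogeneous" and spec.interior_haze > 0:
        intensity[~membrane] = spec.interior_haze
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0, spec.noise_sigma, size=(h, w))
    intensity = np.clip(intensity, 0, None).astype(np.float32)
    stack = IntensityStack({"membrane": intensity}, spec.calibration)
    return stack, label_img


_PRESETS: dict[str, dict] = {
    # healthy adult muscle: large fibers, moderate spread
    "control": {"area_lognormal": (7.5, 0.35), "area_mixture": None},
    # early regeneration: most fibers remain small, wider spread
    "regenerating_small": {"area_lognormal": (6.2, 0.5), "area_mixture": None},
    # dystrophic mosaic: large surviving fibers plus a small regenerating
    # population (bimodal mixture)
    "dystrophic_mixed": {
        "area_lognormal": (7.5, 0.35),
        "area_mixture": (6.0, 0.45, 0.4),
    },
}


def phenotype_preset(name: str) -> dict:
    """Documented parameter bundles for typical muscle phenotypes.

    Returns a pure-data spec fragment usable as
    ``SyntheticMuscleSpec(**phenotype_preset(name), ...)``.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return dict(_PRESETS[name])


def random_label_image(
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    density: float = 0.5,
    smooth_px: float = 2.0,
) -> LabelImage:
    """Random blobby label image: thresholded smoothed noise, 4-connected
    components labeled 1..N. Handy for property tests and quick demos."""
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.normal(size=shape), smooth_px)
    mask = noise > np.quantile(noise, 1 - density)
    four = ndimage.generate_binary_structure(2, 1)
    labels, _ = ndimage.label(mask, structure=four)
    return LabelImage(labels.astype(np.uint16))


def random_vessel_mask(
    shape: tuple[int, int],
    n_vessels: int = 5,
    radius_range: tuple[float, float] = (4.0, 12.0),
    seed: int = 0,
) -> np.ndarray:
    """Binary mask of small round blobs standing in for blood vessels."""
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_vessels):
        r = rng.uniform(*radius_range)
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return mask


def absorb_membrane(img: LabelImage, offset_px: float) -> LabelImage:
    """Grow every label into the surrounding membrane/background by up to
    ``offset_px`` without letting labels overlap.

    Emulates a segmenter that places boundaries on the bright membrane
    instead of the fiber edge — the very bias label erosion corrects.
    """
    grown = expand_labels(img.pixels, distance=offset_px)
    return img.with_pixels(grown.astype(img.pixels.dtype))


def write_section(
    stack: IntensityStack,
    labels: LabelImage,
    spec: SyntheticMuscleSpec,
    directory: str | Path,
    stem: str = "section",
) -> dict[str, Path]:
    """Write intensity TIFF + label TIFF + spec JSON side-car, so every
    generated fixture is self-describing."""
    import tifffile

    from .label_core import write_label_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": directory / f"{stem}.tif",
        "labels": directory / f"{stem}_labels.tif",
        "spec": directory / f"{stem}_spec.json",
    }
    tifffile.imwrite(
        paths["intensity"],
        np.stack([stack[n] for n in stack.channel_names]),
        metadata={"channels": stack.channel_names},
    )
    write_label_image(labels, paths["labels"])
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()}
    paths["spec"].write_text(json.dumps(d, indent=2))
    return paths
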