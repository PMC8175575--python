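"""Batch pipeline: many (image, label) pairs in, one tidy CSV out.

For every matched pair the pipeline runs relabel_connected ->
erode_labels(radius) -> labels_to_rois -> measure_objects, appends the
measurements to one combined CSV, and saves per-image ROI zips, eroded
label images and erosion reports — everything needed to audit a run.
Floating-point CSV output is fixed to 6 significant digits so identical
inputs and configuration produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .erosion import ErosionSpec, erode_labels, split_disconnected_labels
from .label_core import Calibration, read_intensity_stack, read_label_image, relabel_connected, write_label_image
from .morphometry import measure_objects
from .roi_geometry import labels_to_rois, write_roi_zip

__all__ = ["BatchConfig", "run_batch"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class BatchConfig:
    """Configuration for one batch run.

    Label and intensity files are paired by shared filename stem:
    ``<stem><label_suffix>.<ext>`` matches ``<stem><image_suffix>.<ext>``
    (Cellpose writes e.g. ``_cp_masks``; the suffix is configuration, not
    convention). ``exclude_ids`` drops specific label IDs per image stem —
    the non-interactive substitute for manual ROI deletion.
    """

    input_dir: str | Path
    output_dir: str | Path
    label_suffix: str = "_labels"
    image_suffix: str = ""
    erosion_radius_px: int = 4
    pixel_size_um: float = 1.0
    channels: tuple[str, ...] = ()
    bin_width_um2: float = 500.0
    save_roi_zips: bool = True
    strict: bool = False
    exclude_ids: dict[str, tuple[int, ...]] = field(default_factory=dict)
    log_level: str = "INFO"


def _find_pairs(cfg: BatchConfig) -> tuple[list[tuple[str, Path, Path | None]], list[Path]]:
    """Match label files to intensity images by stem; returns (pairs,
    orphan intensity images)."""
    input_dir = Path(cfg.input_dir)
    exts = (".tif", ".tiff", ".png")
    labels = {}
    images = {}
    for p in sorted(input_dir.iterdir()):
        if p.suffix.lower() not in exts:
            continue
        if p.stem.endswith(cfg.label_suffix) and cfg.label_suffix:
            labels[p.stem[: -len(cfg.label_suffix)]] = p
        elif cfg.image_suffix and p.stem.endswith(cfg.image_suffix):
            images[p.stem[: -len(cfg.image_suffix)] if cfg.image_suffix else p.stem] = p
        elif not cfg.image_suffix:
            images[p.stem] = p
    pairs = []
    for stem, lp in sorted(labels.items()):
        pairs.append((stem, lp, images.get(stem)))
    orphans = [p for stem, p in sorted(images.items()) if stem not in labels]
    return pairs, orphans


def run_batch(cfg: BatchConfig) -> pd.DataFrame:
    """Process every (label, image) pair under ``cfg.input_dir``.

    Returns the combined measurement table; writes ``measurements.csv``,
    per-image ROI zips, eroded labels, erosion reports, the resolved
    configuration and a timestamped run log under ``cfg.output_dir``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level)
    t0 = time.time()
    try:
        logger.info("fibermorph %s batch run", __version__)
        cfg_json = {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        }
        cfg_json["exclude_ids"] = {k: list(v) for k, v in cfg.exclude_ids.items()}
        (out_dir / "config.json").write_text(json.dumps(cfg_json, indent=2, sort_keys=True))
        logger.info("config: %s", json.dumps(cfg_json, sort_keys=True))

        pairs, orphans = _find_pairs(cfg)
        for orphan in orphans:
            msg = f"image without matching label file: {orphan.name}"
            if cfg.strict:
                raise FileNotFoundError(msg)
            logger.warning("skipping %s", msg)
        if not pairs:
            raise FileNotFoundError(
                f"no (label, image) pairs with label suffix {cfg.label_suffix!r} "
                f"found in {cfg.input_dir}"
            )

        cal = Calibration(cfg.pixel_size_um)
        spec = ErosionSpec(radius_px=cfg.erosion_radius_px)
        all_rows = []
        for stem, label_path, image_path in pairs:
            labels = relabel_connected(read_label_image(label_path, cal))
            excluded = cfg.exclude_ids.get(stem, ())
            if excluded:
                px = labels.pixels.copy()
                import numpy as np

                px[np.isin(px, excluded)] = 0
                labels = labels.with_pixels(px)
            stack = None
            if image_path is not None:
                names = list(cfg.channels) or None
                stack = read_intensity_stack(image_path, names, cal)
            eroded, report = erode_labels(labels, spec)
            # erosion can split an object at a thin neck; split such IDs
            # (originals kept on the largest component) so every measured
            # object is one 4-connected region
            eroded = split_disconnected_labels(eroded)
            report.to_csv(out_dir / f"{stem}_erosion_report.csv", index=False)
            write_label_image(eroded, out_dir / f"{stem}_eroded_labels.tif")
            if cfg.save_roi_zips:
                write_roi_zip(labels_to_rois(eroded), out_dir / f"{stem}_rois.zip")
            ms = measure_objects(eroded, stack, image_id=stem)
            all_rows.extend(ms)
            logger.info(
                "%s: %d objects in, %d measured, %d vanished in erosion",
                stem,
                labels.n_objects,
                len(ms),
                int((report["status"] == "vanished").sum()),
            )

        from .morphometry import write_measurements_csv

        csv_path = out_dir / "measurements.csv"
        write_measurements_csv(all_rows, csv_path)
        # rewrite with fixed float formatting for byte-stable output
        df = pd.read_csv(csv_path)
        df.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
        logger.info("wrote %d rows to %s in %.1f s", len(df), csv_path, time.time() - t0)
        return df
    finally:
        logger.removeHandler(handler)
        handler.close()
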